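"""Single-document configuration for the margin-assessment pipeline.

Every tunable default of the pipeline lives here, so a run is fully
described by one YAML/JSON document (echoed into each report).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mosaic import DEFAULT_OVERLAP_FRACTION, OCT_FOV_MM
from .texture import TextureParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs.

    Either ``phantom`` describes a synthetic specimen to generate, or
    ``inputs`` points at a TIFF OCT volume (and optional label volume)
    on disk.
    """

    # -- input -----------------------------------------------------------
    phantom: dict = field(default_factory=lambda: {
        "layout_pattern": "infiltrating_boundary",
        "grid_shape": [64, 64, 220],
        "seed": 0,
    })
    inputs: dict | None = None  # {"oct": path, "labels": path|None, ...}

    # -- fluorescence ROI selection --------------------------------------
    fl_threshold: float = 0.5        # fraction of image max
    fl_min_area_px: int = 16

    # -- strip acquisition ------------------------------------------------
    fov_mm: float = OCT_FOV_MM
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION
    registration_jitter_px: int = 0  # emulated acquisition jitter

    # -- surfaces ----------------------------------------------------------
    top_rel_threshold: float = 0.5
    bottom_histogram_bins: int = 64
    profile_smooth_span: int = 7

    # -- texture -----------------------------------------------------------
    texture: dict = field(default_factory=lambda: asdict(TextureParams()))

    # -- training ----------------------------------------------------------
    # list of {"layout_pattern": ..., "seed": ...} phantoms supplying
    # ground-truth-labeled training ROIs; "self" uses the run's own specimen
    training_phantoms: list | str = field(default_factory=lambda: [
        {"layout_pattern": "infiltrating_boundary", "seed": 1000},
        {"layout_pattern": "adipose_only", "seed": 1001},
        {"layout_pattern": "uniform_tumor", "seed": 1002},
    ])
    rois_per_class: int = 5          # guided review collects 3-5 per type
    roi_size_px: int = 24
    training_depths_px: list = field(default_factory=lambda: [6, 30, 60, 90, 120, 170])

    # -- classification ----------------------------------------------------
    pool_window: int = 15
    majority_smooth: bool = True

    # -- margin ------------------------------------------------------------
    projection_depth_mm: float = 1.0
    min_component_mm2: float = 0.04  # margin components below this are noise
    call_min_area_mm2: float = 0.01  # specimen call threshold
    overlay_alpha: float = 0.45

    # -- output ------------------------------------------------------------
    out_dir: str | None = None

    def texture_params(self) -> TextureParams:
        return TextureParams(**self.texture)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON — YAML superset) config document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(doc)
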