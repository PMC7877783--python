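"""End-to-end pipeline driver, overlays, and specimen-level evaluation.

The pipeline mirrors the acquisition-and-processing workflow of the
multimodal margin instrument: fluorescence imaging selects a suspicious
region; the region is covered by overlapping OCT line strips which are
registered and stitched; B-scans are surface-segmented and
depth-compensated; texture features trained from confocal-labeled ROIs
classify every voxel; tumor labels within a clinical depth of the
surface project to a positive-margin mask and a specimen-level call.

Specimen-level evaluation reports both metric conventions: the headline
"predictive values" convention (PPV = TP/(TP+FN), NPV = TN/(TN+FP) —
algebraically the sensitivity and specificity of the counts) and the
standard epidemiological PPV/NPV, named explicitly to avoid ambiguity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import classify as cl
from . import mosaic as mo
from . import phantom as ph
from . import probe as pr
from . import surfaces as sf
from . import texture as tx
from .config import PipelineConfig

__all__ = [
    "EvalTable", "MarginReport", "evaluate", "overlay",
    "run_pipeline", "run_cohort", "training_rois_from_phantom",
    "build_shared_model", "default_cohort_specs",
]

logger = logging.getLogger("octmargin")


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalTable:
    """Specimen-level confusion counts and both metric conventions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def ppv_paper(self) -> float:
        """Headline 'positive predictive value' convention: TP/(TP+FN).
        Algebraically identical to sensitivity."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def npv_paper(self) -> float:
        """Headline 'negative predictive value' convention: TN/(TN+FP).
        Algebraically identical to specificity."""
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.ppv_paper

    @property
    def specificity(self) -> float:
        return self.npv_paper

    @property
    def ppv_std(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv_std(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "PPV_paper": self.ppv_paper, "NPV_paper": self.npv_paper,
            "PPV_std": self.ppv_std, "NPV_std": self.npv_std,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def evaluate(calls: list[str], truth: list[str]) -> EvalTable:
    """Confusion counts and metrics from paired specimen calls.

    Both lists contain 'positive' / 'negative' strings.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must have equal length")
    for v in list(calls) + list(truth):
        if v not in ("positive", "negative"):
            raise ValueError(f"labels must be 'positive' or 'negative', got {v!r}")
    tp = sum(c == "positive" and t == "positive" for c, t in zip(calls, truth))
    fp = sum(c == "positive" and t == "negative" for c, t in zip(calls, truth))
    tn = sum(c == "negative" and t == "negative" for c, t in zip(calls, truth))
    fn = sum(c == "negative" and t == "positive" for c, t in zip(calls, truth))
    return EvalTable(tp=tp, fp=fp, tn=tn, fn=fn)


def overlay(photo: np.ndarray, mask: cl.MarginMask,
            alpha: float = 0.45) -> np.ndarray:
    """Tint margin-positive pixels red over the specimen photo (RGBA)."""
    img = np.asarray(photo, dtype=float)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[:2] != mask.mask.shape:
        raise ValueError("photo and mask must share the lateral grid")
    out = np.concatenate([img, np.ones(img.shape[:2] + (1,))], axis=-1)
    m = mask.mask
    red = np.array([1.0, 0.0, 0.0])
    out[m, :3] = (1.0 - alpha) * out[m, :3] + alpha * red
    return out


# --------------------------------------------------------------------------
# training-set construction (emulating confocal-guided ROI labeling)
# --------------------------------------------------------------------------

_CLASS_BY_NAME = {"tumor": ph.TUMOR, "adipose": ph.ADIPOSE, "benign": ph.BENIGN}


def segment_foreground(oct_vol: np.ndarray,
                       top_rel_threshold: float = 0.5,
                       histogram_bins: int = 64,
                       smooth_span: int = 7,
                       surface_exclusion_vox: int = 2
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface-segment every B-scan of a volume.

    Returns (mask, top_map, bottom_map): the 3-D foreground mask between
    the top surface and the maximum-signal depth, and the per-lateral-
    position depth index maps.  The first ``surface_exclusion_vox``
    voxels below the top surface are excluded from the mask: the
    specular window/tissue reflection there is not tissue texture.
    """
    nz, ny, nx = oct_vol.shape
    top_map = np.zeros((ny, nx), dtype=int)
    bottom_map = np.zeros((ny, nx), dtype=int)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for y in range(ny):
        bscan = oct_vol[:, y, :]
        top = sf.top_surface(bscan, rel_threshold=top_rel_threshold,
                             smooth_span=smooth_span)
        bottom = sf.bottom_depth(bscan, histogram_bins=histogram_bins,
                                 smooth_span=smooth_span)
        mask[:, y, :] = sf.mask_between(top, bottom, (nz, nx))
        top_map[y] = top.filled()
        bottom_map[y] = bottom.filled()
    if surface_exclusion_vox > 0:
        zz = np.arange(nz)[:, None, None]
        mask &= zz >= top_map[None] + surface_exclusion_vox
    return mask, top_map, bottom_map


def training_rois_from_phantom(phantom: ph.SpecimenPhantom,
                               rois_per_class: int = 5,
                               roi_size: int = 24,
                               depths: tuple[int, ...] = (6, 60, 120, 170),
                               texture_params: tx.TextureParams | None = None,
                               stride: int | None = None,
                               mask: np.ndarray | None = None,
                               with_depths: bool = False):
    """Labeled ROI features from a phantom's ground truth.

    Emulates the confocal-review step: rectangular ROIs that lie
    entirely inside one tissue class (checked against the ground-truth
    labels, standing in for the reviewer) and inside the segmented
    foreground are summarized on the log-scaled en-face planes at the
    given depths.  Up to ``rois_per_class`` ROIs per class are taken at
    EACH depth, so deep planes are represented in training.

    Returns a list of ROIFeatures, or of (depth, ROIFeatures) pairs when
    ``with_depths`` is set.
    """
    params = texture_params or tx.TextureParams()
    stride = stride or max(4, roi_size // 3)
    if mask is None:
        mask, _, _ = segment_foreground(phantom.oct)
    pairs: list[tuple[int, tx.ROIFeatures]] = []
    nz, ny, nx = phantom.oct.shape
    for z in depths:
        if z >= nz:
            continue
        plane = cl.log_scale(phantom.oct[z])
        stack = tx.compute_feature_stack(plane, params)
        lbl = phantom.labels[z]
        for name, code in _CLASS_BY_NAME.items():
            n_found = 0
            for r0 in range(0, ny - roi_size + 1, stride):
                if n_found >= rois_per_class:
                    break
                for c0 in range(0, nx - roi_size + 1, stride):
                    if n_found >= rois_per_class:
                        break
                    sl = (slice(r0, r0 + roi_size), slice(c0, c0 + roi_size))
                    if not (lbl[sl] == code).all() or mask[z][sl].mean() < 0.6:
                        continue
                    pairs.append((z, tx.roi_features(
                        stack, (r0, c0, roi_size, roi_size), label=name)))
                    n_found += 1
    return pairs if with_depths else [f for _, f in pairs]


def build_shared_model(config: PipelineConfig) -> cl.ClassifierModel:
    """Train one depth-adjusted classifier from the config's training
    phantoms."""
    pairs: list[tuple[int, tx.ROIFeatures]] = []
    for entry in config.training_phantoms:
        spec = ph.PhantomSpec(layout_pattern=entry["layout_pattern"],
                              seed=entry["seed"],
                              grid_shape=tuple(config.phantom.get(
                                  "grid_shape", [64, 64, 220])))
        p = ph.generate_phantom(spec)
        pairs.extend(training_rois_from_phantom(
            p, rois_per_class=config.rois_per_class,
            roi_size=config.roi_size_px,
            depths=tuple(config.training_depths_px),
            texture_params=config.texture_params(),
            with_depths=True))
    return cl.train_depth_resolved(pairs, pool_window=config.pool_window)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class MarginReport:
    """Everything one pipeline run produced."""

    specimen_id: str
    margin: cl.MarginMask
    overlay_image: np.ndarray
    surface_class_fractions: dict
    call: str
    config: dict
    stages: dict = field(default_factory=dict)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "call": self.call,
            "margin_area_mm2": self.margin.area_mm2,
            "projection_depth_mm": self.margin.projection_depth_mm,
            "surface_class_fractions": self.surface_class_fractions,
            "stages": self.stages,
            "config": self.config,
        }


def _stage(stages: dict, name: str, **info):
    stages[name] = info
    logger.info("stage %s: %s", name, info)


def run_pipeline(config: PipelineConfig,
                 model: cl.ClassifierModel | None = None,
                 specimen_id: str = "specimen") -> MarginReport:
    """Run the full margin-assessment pipeline for one specimen.

    Stage errors propagate with the stage name attached; outputs of the
    stages completed so far are retained in the report's ``stages``.
    """
    stages: dict = {}
    try:
        return _run_pipeline_inner(config, model, specimen_id, stages)
    except Exception as err:
        done = list(stages)
        failed = f"after stages {done}" if done else "at the first stage"
        raise RuntimeError(f"pipeline for {specimen_id} failed {failed}: {err}") from err


def _run_pipeline_inner(config, model, specimen_id, stages) -> MarginReport:
    # ---- input ----------------------------------------------------------
    if config.inputs:
        oct_vol = tifffile.imread(config.inputs["oct"]).astype(float)
        labels_true = (tifffile.imread(config.inputs["labels"]).astype(np.uint8)
                       if config.inputs.get("labels") else None)
        spec = ph.PhantomSpec(grid_shape=oct_vol.shape[::-1])
        phant = None
        fl_img = (tifffile.imread(config.inputs["fl"]).astype(float)
                  if config.inputs.get("fl") else None)
        photo = np.full(oct_vol.shape[1:] + (3,), 0.5)
    else:
        spec_kwargs = dict(config.phantom)
        spec_kwargs["grid_shape"] = tuple(spec_kwargs.get("grid_shape", [64, 64, 220]))
        spec = ph.PhantomSpec(**spec_kwargs)
        phant = ph.generate_phantom(spec)
        oct_vol, labels_true = phant.oct, phant.labels
        fl_img, photo = phant.fl, phant.photo
    nz, ny, nx = oct_vol.shape
    _stage(stages, "input", shape=[nz, ny, nx], source="phantom" if phant else "files")

    # ---- fluorescence ROI selection -------------------------------------
    if fl_img is not None:
        rois = pr.fl_threshold_rois(fl_img, threshold=config.fl_threshold,
                                    min_area=config.fl_min_area_px)
        if rois:
            bbox = rois[0]["bbox"]
            roi_extent_mm = max(bbox[2] - bbox[0], bbox[3] - bbox[1]) \
                * spec.lateral_voxel_um / 1000.0
        else:
            roi_extent_mm = max(ny, nx) * spec.lateral_voxel_um / 1000.0
        _stage(stages, "fl_roi", n_rois=len(rois), roi_extent_mm=roi_extent_mm)
    else:
        roi_extent_mm = max(ny, nx) * spec.lateral_voxel_um / 1000.0
        _stage(stages, "fl_roi", n_rois=0, roi_extent_mm=roi_extent_mm)

    # ---- strip planning and stitching -----------------------------------
    layout = mo.plan_strips(roi_extent_mm, fov_mm=config.fov_mm,
                            overlap_fraction=config.overlap_fraction)
    stitch_mad = 0.0
    if layout.n_strips > 1:
        # emulate the strip acquisition on the surface-slab projection,
        # register adjacent strips and verify the mosaic round-trips
        enface = cl.log_scale(oct_vol[: max(4, nz // 20)].mean(axis=0))
        overlap_px = max(2, int(round(layout.overlap_mm * 1000.0
                                      / spec.lateral_voxel_um)))
        rng = np.random.default_rng(spec.seed + 17)
        strips, true_offsets, ov = mo.cut_strips(
            enface, layout.n_strips, overlap_px,
            jitter_px=config.registration_jitter_px, rng=rng)
        search = max(1, min(ov - 1, max(1, int(0.25 * ov))))
        offsets = [mo.register_pair(a, b, ov, search)[0]
                   for a, b in zip(strips[:-1], strips[1:])]
        mosaic_img = mo.stitch(strips, offsets, nominal_overlap=ov)
        h = min(mosaic_img.shape[0], enface.shape[0])
        w = min(mosaic_img.shape[1], enface.shape[1])
        jit = config.registration_jitter_px
        ref = enface[jit:jit + h, :w]
        stitch_mad = float(np.mean(np.abs(mosaic_img[:ref.shape[0], :w] - ref)))
        _stage(stages, "mosaic", n_strips=layout.n_strips,
               offsets=offsets, true_offsets=true_offsets,
               stitch_mad=stitch_mad)
    else:
        _stage(stages, "mosaic", n_strips=1)

    # ---- surface segmentation -------------------------------------------
    mask, top_map, bottom_map = segment_foreground(
        oct_vol, top_rel_threshold=config.top_rel_threshold,
        histogram_bins=config.bottom_histogram_bins,
        smooth_span=config.profile_smooth_span)
    _stage(stages, "surfaces", mean_top=float(top_map.mean()),
           mean_bottom=float(bottom_map.mean()),
           foreground_voxels=int(mask.sum()))

    # ---- depth compensation ---------------------------------------------
    gain, compensated = tx.depth_compensate(oct_vol, mask,
                                            axial_voxel_um=spec.axial_voxel_um)
    _stage(stages, "depth_compensation", rate_per_mm=gain.rate_per_mm)

    # ---- training --------------------------------------------------------
    if model is None:
        if config.training_phantoms == "self":
            if phant is None:
                raise ValueError("'self' training requires a phantom input")
            pairs = training_rois_from_phantom(
                phant, rois_per_class=config.rois_per_class,
                roi_size=config.roi_size_px,
                depths=tuple(config.training_depths_px),
                texture_params=config.texture_params(),
                mask=mask, with_depths=True)
            model = cl.train_depth_resolved(pairs,
                                            pool_window=config.pool_window)
        else:
            model = build_shared_model(config)
    _stage(stages, "training",
           slope_threshold=model.slope_threshold,
           roughness_threshold=model.roughness_threshold,
           n_training_rois=model.n_training_rois)

    # ---- 3-D classification ---------------------------------------------
    labels_pred = cl.classify_voxels(compensated, model, mask,
                                     texture_params=config.texture_params(),
                                     majority_smooth=config.majority_smooth)
    _stage(stages, "classification", **{
        name: int((labels_pred == code).sum())
        for name, code in _CLASS_BY_NAME.items()})

    # ---- margin projection and call --------------------------------------
    margin = cl.project_margin(labels_pred, top_map,
                               depth_mm=config.projection_depth_mm,
                               axial_voxel_um=spec.axial_voxel_um,
                               lateral_voxel_um=spec.lateral_voxel_um,
                               min_area_mm2=config.min_component_mm2)
    call = cl.specimen_call(margin, min_area_mm2=config.call_min_area_mm2)
    _stage(stages, "margin", area_mm2=margin.area_mm2, call=call)

    # ---- surface class fractions and overlay -----------------------------
    # first classified (non-background) voxel per lateral position
    any_fg = (labels_pred != ph.BACKGROUND).any(axis=0)
    first_fg = (labels_pred != ph.BACKGROUND).argmax(axis=0)
    surf_labels = np.take_along_axis(labels_pred, first_fg[None], axis=0)[0]
    surf_labels[~any_fg] = ph.BACKGROUND
    fg = surf_labels != ph.BACKGROUND
    fractions = {name: float((surf_labels[fg] == code).mean()) if fg.any() else 0.0
                 for name, code in _CLASS_BY_NAME.items()}
    ov_img = overlay(photo, margin, alpha=config.overlay_alpha)

    report = MarginReport(
        specimen_id=specimen_id, margin=margin, overlay_image=ov_img,
        surface_class_fractions=fractions, call=call,
        config=config.to_dict(), stages=stages,
        out_dir=config.out_dir,
    )
    if config.out_dir:
        _write_report(report, labels_pred, top_map, bottom_map, config)
    return report


def _write_report(report: MarginReport, labels_pred, top_map, bottom_map,
                  config: PipelineConfig) -> None:
    import imageio.v3 as iio
    import pandas as pd
    from skimage.measure import label as cc_label, regionprops

    out = Path(config.out_dir) / report.specimen_id
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.ome.tif", labels_pred, metadata={"axes": "ZYX"})
    (out / "palette.json").write_text(json.dumps(
        {"tumor": "red", "adipose": "green", "benign": "blue",
         "background": "black"}, indent=2))
    iio.imwrite(out / "margin_mask.png",
                (report.margin.mask * 255).astype(np.uint8))
    iio.imwrite(out / "overlay.png",
                (np.clip(report.overlay_image, 0, 1) * 255).astype(np.uint8))
    comps = regionprops(cc_label(report.margin.mask))
    pd.DataFrame({
        "component": [c.label for c in comps],
        "area_mm2": [c.area * report.margin.pixel_area_mm2 for c in comps],
    }).to_csv(out / "margin_components.csv", index=False)
    pd.DataFrame({
        "column": np.arange(top_map.size),
        "top": top_map.ravel(),
        "bottom": bottom_map.ravel(),
    }).to_csv(out / "surfaces.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))


# --------------------------------------------------------------------------
# cohort experiments
# --------------------------------------------------------------------------

#: truth per layout: does tumor reach within ~1 mm of the surface?
LAYOUT_TRUTH = {
    "uniform_tumor": "positive",
    "infiltrating_boundary": "positive",
    "deep_focus": "positive",       # focus at 0.5 mm, inside the 1 mm band
    "adipose_only": "negative",
    "lobule_insert": "negative",    # benign truth; known false-positive risk
}


def default_cohort_specs(base_seed: int = 0,
                         n_positive: int = 8,
                         n_negative: int = 12) -> list[dict]:
    """Layout/seed plan for a specimen cohort: ``n_positive`` specimens
    with tumor within the projection depth and ``n_negative`` without
    (two of the negatives carry the lobule texture confounder)."""
    pos_layouts = ["uniform_tumor", "infiltrating_boundary", "deep_focus"]
    specs = []
    for i in range(n_positive):
        specs.append({"layout_pattern": pos_layouts[i % len(pos_layouts)],
                      "seed": base_seed + 100 + i})
    for i in range(n_negative):
        pattern = "lobule_insert" if i < 2 else "adipose_only"
        specs.append({"layout_pattern": pattern, "seed": base_seed + 200 + i})
    return specs


def run_cohort(specs: list[dict], config: PipelineConfig | None = None
               ) -> tuple[EvalTable, list[MarginReport]]:
    """Run the pipeline over a cohort with one shared trained model."""
    config = config or PipelineConfig()
    model = build_shared_model(config)
    calls, truth, reports = [], [], []
    for i, entry in enumerate(specs):
        c = PipelineConfig.from_dict({**config.to_dict(),
                                      "phantom": {**config.phantom, **entry}})
        rep = run_pipeline(c, model=model, specimen_id=f"specimen_{i:02d}")
        reports.append(rep)
        calls.append(rep.call)
        truth.append(LAYOUT_TRUTH[entry["layout_pattern"]])
    return evaluate(calls, truth), reports
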