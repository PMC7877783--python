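"""Synthetic breast-specimen phantoms with co-registered OCT, RCM,
fluorescence and brightfield channels plus per-voxel ground truth.

A phantom emulates the statistical structure the segmentation relies on,
not histology-realistic appearance:

* **tumor** — densely scattering tissue with high local intensity
  variance at a short correlation length;
* **adipose** — a honeycomb cell lattice of dark lumens bounded by
  bright septa (strong edges, smooth interiors);
* **benign stroma** — smooth, mildly anisotropic low-contrast texture;
* multiplicative gamma-distributed speckle, exponential depth
  attenuation ``exp(-2 mu z)``, and additive detector noise.

Volumes are indexed ``[z, y, x]`` with z = 0 at the imaging window
(specimens are pressed flat against it), increasing into tissue.
Lateral voxels default to 10 µm (OCT), axial to 5 µm; the RCM channel
is a 1 µm en-face snapshot of the same lateral field.

Five lateral layout templates mirror the representative specimen types
of a margin study: fully positive margins, infiltrating tumor boundary,
adipose-only, a benign-lobule insert that scatters like tumor (the
documented false-positive mode), and a small tumor focus buried below
the surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree

from .probe import (DEFAULT_INCUBATION_MIN, KineticsParams, es_ratio,
                    fluorescence_trace)

__all__ = [
    "TUMOR", "ADIPOSE", "BENIGN", "BACKGROUND", "LOBULE",
    "CLASS_NAMES", "LAYOUT_PATTERNS",
    "ClassParams", "PhantomSpec", "SpecimenPhantom",
    "build_layout", "render_oct", "render_fl", "render_rcm",
    "render_photo", "generate_phantom", "write_phantom",
]

# ground-truth label codes
BACKGROUND = 0
TUMOR = 1
ADIPOSE = 2
BENIGN = 3
#: rendering-only code: ground truth benign, texture tumor-like
LOBULE = 4

CLASS_NAMES = {BACKGROUND: "background", TUMOR: "tumor",
               ADIPOSE: "adipose", BENIGN: "benign"}

LAYOUT_PATTERNS = ("uniform_tumor", "adipose_only", "lobule_insert",
                   "infiltrating_boundary", "deep_focus")

#: uPA levels (ng per mg protein) per rendering class; the lobule shares
#: benign enzyme levels — its false positives are an OCT texture effect.
UPA_LEVELS = {TUMOR: 8.0, ADIPOSE: 1.0, BENIGN: 1.0, LOBULE: 1.0}


@dataclass(frozen=True)
class ClassParams:
    """Optical/texture parameters of one tissue class.

    Attributes
    ----------
    reflectivity : float
        Mean backscattered intensity, arbitrary units.
    contrast : float
        Texture contrast (SD of the unit-mean texture field).
    mu_per_mm : float
        Attenuation coefficient mu, 1/mm (round-trip decay is 2 mu).
    scale_um : float
        Texture correlation length / cell size, micrometres.
    """

    reflectivity: float
    contrast: float
    mu_per_mm: float
    scale_um: float


def default_class_params() -> dict[int, ClassParams]:
    """Free parameters of the renderer; no measured per-class optical
    constants are available, so these are chosen to reproduce the
    qualitative contrasts the segmentation exploits (see docs)."""
    return {
        TUMOR: ClassParams(reflectivity=1.0, contrast=1.0, mu_per_mm=2.0, scale_um=24.0),
        ADIPOSE: ClassParams(reflectivity=0.5, contrast=1.0, mu_per_mm=0.8, scale_um=120.0),
        BENIGN: ClassParams(reflectivity=0.8, contrast=0.15, mu_per_mm=1.2, scale_um=150.0),
        LOBULE: ClassParams(reflectivity=1.0, contrast=1.0, mu_per_mm=2.0, scale_um=24.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one synthetic specimen."""

    grid_shape: tuple[int, int, int] = (64, 64, 220)  # (nx, ny, nz)
    lateral_voxel_um: float = 10.0
    axial_voxel_um: float = 5.0
    layout_pattern: str = "infiltrating_boundary"
    class_params: dict[int, ClassParams] = field(default_factory=default_class_params)
    speckle_shape: float = 4.0  # gamma shape; 0 disables speckle
    noise_sd: float = 0.02
    surface_amp_vox: int = 2  # smooth top-surface height variation
    #: specular reflection at the imaging-window/tissue interface; makes
    #: the top surface bright in every column (0 disables)
    surface_reflectivity: float = 2.0
    tumor_fraction: float = 0.40  # infiltrating_boundary template
    focus_depth_um: float = 500.0  # deep_focus template
    seed: int = 0

    def __post_init__(self):
        if self.lateral_voxel_um <= 0 or self.axial_voxel_um <= 0:
            raise ValueError("voxel spacings must be positive")
        if any(p.mu_per_mm < 0 for p in self.class_params.values()):
            raise ValueError("attenuation coefficients must be non-negative")
        if self.layout_pattern not in LAYOUT_PATTERNS:
            raise ValueError(f"unknown layout pattern {self.layout_pattern!r}")


@dataclass
class SpecimenPhantom:
    """Co-registered multimodal snapshot of one synthetic specimen."""

    oct: np.ndarray          # (nz, ny, nx) intensity
    rcm: np.ndarray          # (ny*r, nx*r) en-face at stated depth
    fl: np.ndarray           # (ny, nx) fluorescence
    photo: np.ndarray        # (ny, nx, 3) flat-shaded brightfield
    labels: np.ndarray       # (nz, ny, nx) ground-truth class codes
    spec: PhantomSpec
    rcm_depth_um: float = 100.0

    def __post_init__(self):
        if self.oct.shape != self.labels.shape:
            raise ValueError("oct and labels must share shape")


def build_layout(pattern: str, shape: tuple[int, int], seed: int,
                 tumor_fraction: float = 0.40, focus_depth_um: float = 500.0
                 ) -> tuple[np.ndarray, float | None]:
    """Lateral (ny, nx) class map for one scenario template.

    Returns the map and, for the ``deep_focus`` template, the depth
    offset (µm) at which the tumor focus begins (None otherwise).  Codes
    may include the rendering-only LOBULE class (ground truth benign).
    """
    if pattern not in LAYOUT_PATTERNS:
        raise ValueError(f"unknown layout pattern {pattern!r}; "
                         f"choose one of {LAYOUT_PATTERNS}")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]

    if pattern == "uniform_tumor":
        return np.full(shape, TUMOR, dtype=np.uint8), None

    if pattern == "adipose_only":
        return np.full(shape, ADIPOSE, dtype=np.uint8), None

    if pattern == "lobule_insert":
        layout = np.full(shape, BENIGN, dtype=np.uint8)
        cy = ny * (0.3 + 0.4 * rng.random())
        cx = nx * (0.3 + 0.4 * rng.random())
        radius = 0.14 * min(ny, nx)
        layout[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = LOBULE
        # adipose rim along one edge for heterogeneity
        layout[:, : max(3, nx // 8)] = ADIPOSE
        return layout, None

    if pattern == "infiltrating_boundary":
        # tumor advances from the left across a noisy front placed so the
        # configured tumor fraction is met
        front = gaussian_filter(rng.standard_normal(ny), 4, mode="wrap")
        front = front - front.mean()  # centered: expected fraction is exact
        front = front / (front.std() + 1e-12) * 0.08 * nx
        boundary = tumor_fraction * nx + front
        layout = np.where(xx < boundary[:, None], TUMOR, BENIGN).astype(np.uint8)
        return layout, None

    # deep_focus: benign surface with a buried tumor focus
    layout = np.full(shape, BENIGN, dtype=np.uint8)
    cy = ny * (0.35 + 0.3 * rng.random())
    cx = nx * (0.35 + 0.3 * rng.random())
    radius = 0.25 * min(ny, nx)
    layout[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = TUMOR
    return layout, focus_depth_um


def _texture_field(cls: int, params: ClassParams, shape: tuple[int, int],
                   lateral_voxel_um: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lateral texture for one class."""
    ny, nx = shape
    scale_px = max(1.0, params.scale_um / lateral_voxel_um)
    if cls in (TUMOR, LOBULE):
        # short-correlation, heavy-tailed scatterer field
        g = gaussian_filter(rng.standard_normal(shape), scale_px / 3.0, mode="wrap")
        g = g / (g.std() + 1e-12)
        field = np.exp(params.contrast * g)
        return field / field.mean()
    if cls == ADIPOSE:
        # Worley-style honeycomb: bright septa at Voronoi boundaries of a
        # jittered cell lattice (adipocytes pack tightly — a jittered grid
        # avoids the unrealistic voids of Poisson-placed centers),
        # near-transparent lipid lumens
        gy = np.arange(0.0, ny, scale_px)
        gx = np.arange(0.0, nx, scale_px)
        pts = np.stack(np.meshgrid(gy, gx, indexing="ij"), -1).reshape(-1, 2)
        pts = pts + rng.uniform(-0.35 * scale_px, 0.35 * scale_px, pts.shape)
        # wrap copies for periodic-ish boundaries
        shifts = np.array([[0, 0], [ny, 0], [-ny, 0], [0, nx], [0, -nx]])
        tree = cKDTree(np.concatenate([pts + s for s in shifts]))
        grid = np.stack(np.mgrid[0:ny, 0:nx], axis=-1).reshape(-1, 2)
        d, _ = tree.query(grid, k=2)
        edge = (d[:, 1] - d[:, 0]).reshape(ny, nx)  # ~0 at cell boundaries
        septa_width = max(1.0, scale_px * 0.08)
        septa = np.exp(-0.5 * (edge / septa_width) ** 2)
        lumen = 0.05  # dark cell interiors
        field = lumen + (8.0 * params.contrast) * septa
        return field / field.mean()
    # benign stroma: smooth, mildly anisotropic
    g = gaussian_filter(rng.standard_normal(shape),
                        (scale_px / 2.0, scale_px / 4.0), mode="wrap")
    g = g / (g.std() + 1e-12)
    field = 1.0 + params.contrast * g
    return np.clip(field, 0.05, None) / max(np.clip(field, 0.05, None).mean(), 1e-12)


def render_oct(layout: np.ndarray, spec: PhantomSpec,
               depth_offset_um: float | None = None) -> SpecimenPhantom:
    """Render the OCT volume and ground-truth labels for a lateral layout.

    Voxel intensity is class reflectivity x lateral texture x
    exp(-2 mu z) x speckle x (1 + additive noise), with a smooth tilted
    top surface (air above is background) and, for ``deep_focus``
    layouts, tumor texture only below ``depth_offset_um`` (benign above).
    """
    nx, ny, nz = spec.grid_shape
    if layout.shape != (ny, nx):
        raise ValueError(f"layout shape {layout.shape} does not match "
                         f"spec lateral grid {(ny, nx)}")
    rng = np.random.default_rng(spec.seed)
    dz_mm = spec.axial_voxel_um / 1000.0

    # per-class texture fields and lateral property maps
    reflect = np.zeros((ny, nx))
    mu = np.zeros((ny, nx))
    texture = np.zeros((ny, nx))
    for cls in (TUMOR, ADIPOSE, BENIGN, LOBULE):
        sel = layout == cls
        if not sel.any():
            continue
        p = spec.class_params[cls]
        tex = _texture_field(cls, p, (ny, nx), spec.lateral_voxel_um, rng)
        reflect[sel] = p.reflectivity
        mu[sel] = p.mu_per_mm
        texture[sel] = tex[sel]

    base = reflect * texture  # (ny, nx)
    base3 = np.broadcast_to(base, (nz, ny, nx)).copy()
    mu3 = np.broadcast_to(mu, (nz, ny, nx)).copy()

    # labels: LOBULE renders tumor-like but is ground-truth benign
    lateral_labels = np.where(layout == LOBULE, BENIGN, layout).astype(np.uint8)
    labels = np.broadcast_to(lateral_labels, (nz, ny, nx)).copy()

    if depth_offset_um is not None:
        # deep_focus: the focus footprint is benign above the offset depth
        focus = layout == TUMOR
        above = np.arange(nz) * spec.axial_voxel_um < depth_offset_um
        p_ben = spec.class_params[BENIGN]
        tex_ben = _texture_field(BENIGN, p_ben, (ny, nx), spec.lateral_voxel_um, rng)
        region = above[:, None, None] & focus[None, :, :]
        base3 = np.where(region, (p_ben.reflectivity * tex_ben)[None], base3)
        mu3 = np.where(region, p_ben.mu_per_mm, mu3)
        labels[region] = BENIGN

    # round-trip attenuation accumulated along each column (exclusive
    # cumulative sum: unit transmission at the first voxel)
    optical_depth = np.cumsum(mu3, axis=0) - mu3
    volume = base3 * np.exp(-2.0 * optical_depth * dz_mm)

    # tilted / gently wavy top surface with air (background) above
    if spec.surface_amp_vox > 0:
        h = gaussian_filter(rng.standard_normal((ny, nx)), 8, mode="wrap")
        h = h - h.min()
        h = (h / max(h.max(), 1e-12) * spec.surface_amp_vox).round().astype(int)
    else:
        h = np.zeros((ny, nx), dtype=int)
    zz = np.arange(nz)[:, None, None]
    air = zz < h[None, :, :]
    volume = np.where(air, 0.0, volume)
    labels[air] = BACKGROUND
    if spec.surface_reflectivity > 0:
        # specular window/tissue interface: bright in every column
        volume = np.where(zz == h[None, :, :], spec.surface_reflectivity, volume)

    if spec.speckle_shape > 0:
        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape,
                            size=volume.shape)
        volume = volume * speckle
    if spec.noise_sd > 0:
        volume = volume + spec.noise_sd * rng.standard_normal(volume.shape)
        volume = np.clip(volume, 0.0, None)

    return SpecimenPhantom(
        oct=volume, rcm=np.zeros((0, 0)), fl=np.zeros((ny, nx)),
        photo=render_photo(layout), labels=labels, spec=spec,
    )


def render_fl(layout: np.ndarray, kinetics: KineticsParams | None = None,
              incubation_min: float = DEFAULT_INCUBATION_MIN,
              psf_sigma_px: float = 2.0, noise_sd: float = 0.02,
              seed: int = 0) -> np.ndarray:
    """Fluorescence image of a layout after probe incubation.

    Each pixel carries the activation-kinetics trace evaluated at its
    class's E:S condition (from the class uPA level), convolved with a
    Gaussian point-spread of ``psf_sigma_px`` and degraded by additive
    noise.  At zero incubation every class sits at the quenched baseline.
    """
    if incubation_min < 0:
        raise ValueError("incubation time must be non-negative")
    kinetics = kinetics or KineticsParams()
    rng = np.random.default_rng(seed)
    out = np.zeros(layout.shape, dtype=float)
    grid = np.array([0.0, incubation_min]) if incubation_min > 0 else np.array([0.0])
    for cls, level in UPA_LEVELS.items():
        sel = layout == cls
        if not sel.any():
            continue
        params = KineticsParams(q=kinetics.q, s0_um=kinetics.s0_um,
                                es=es_ratio(level), rate=kinetics.rate,
                                incubation_limit_min=kinetics.incubation_limit_min)
        out[sel] = fluorescence_trace(params, grid).fluorescence[-1]
    out[layout == BACKGROUND] = 0.0
    if psf_sigma_px > 0:
        out = gaussian_filter(out, psf_sigma_px, mode="reflect")
    if noise_sd > 0:
        out = np.clip(out + noise_sd * rng.standard_normal(out.shape), 0.0, None)
    return out


def render_rcm(layout: np.ndarray, spec: PhantomSpec, upsample: int = 10,
               depth_um: float = 100.0) -> np.ndarray:
    """High-resolution en-face reflectance snapshot (1 µm-scale pixels).

    The RCM channel exists to emulate the human-interpreted labeling
    step, so it renders the same class texture statistics at
    ``upsample``-times finer lateral sampling.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ny, nx = layout.shape
    hi_shape = (ny * upsample, nx * upsample)
    hi_layout = np.kron(layout, np.ones((upsample, upsample), dtype=layout.dtype))
    out = np.zeros(hi_shape)
    voxel = spec.lateral_voxel_um / upsample
    for cls in (TUMOR, ADIPOSE, BENIGN, LOBULE):
        sel = hi_layout == cls
        if not sel.any():
            continue
        p = spec.class_params[cls]
        tex = _texture_field(cls, p, hi_shape, voxel, rng)
        out[sel] = (p.reflectivity * tex)[sel]
    return out


#: flat-shade colors for the brightfield mock: tissue is pinkish/yellowish
_PHOTO_COLORS = {
    BACKGROUND: (0.1, 0.1, 0.12),
    TUMOR: (0.85, 0.75, 0.7),
    ADIPOSE: (0.95, 0.88, 0.6),
    BENIGN: (0.9, 0.78, 0.75),
    LOBULE: (0.9, 0.78, 0.75),
}


def render_photo(layout: np.ndarray) -> np.ndarray:
    """Flat-shaded brightfield mock (exists to exercise overlays)."""
    out = np.zeros(layout.shape + (3,))
    for cls, rgb in _PHOTO_COLORS.items():
        out[layout == cls] = rgb
    return out


def generate_phantom(spec: PhantomSpec) -> SpecimenPhantom:
    """Build the full co-registered specimen from a PhantomSpec."""
    layout, depth_offset = build_layout(
        spec.layout_pattern, (spec.grid_shape[1], spec.grid_shape[0]), spec.seed,
        tumor_fraction=spec.tumor_fraction, focus_depth_um=spec.focus_depth_um)
    phantom = render_oct(layout, spec, depth_offset_um=depth_offset)
    phantom.fl = render_fl(layout, seed=spec.seed + 2)
    phantom.rcm = render_rcm(layout, spec)
    return phantom


def write_phantom(phantom: SpecimenPhantom, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom to disk: OME-TIFF z-stacks for the OCT volume and
    labels, plain TIFF for the 2-D channels, and a JSON sidecar with the
    generating spec (including the seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["oct"] = out / "oct.ome.tif"
    tifffile.imwrite(paths["oct"], phantom.oct.astype(np.float32),
                     metadata={"axes": "ZYX"})
    paths["labels"] = out / "labels.ome.tif"
    tifffile.imwrite(paths["labels"], phantom.labels.astype(np.uint8),
                     metadata={"axes": "ZYX"})
    for name in ("rcm", "fl"):
        arr = getattr(phantom, name)
        if arr.size:
            paths[name] = out / f"{name}.tif"
            tifffile.imwrite(paths[name], arr.astype(np.float32))
    paths["photo"] = out / "photo.tif"
    tifffile.imwrite(paths["photo"], (phantom.photo * 255).astype(np.uint8))
    sidecar = asdict(phantom.spec)
    sidecar["class_params"] = {CLASS_NAMES.get(k, "lobule"): asdict(v)
                               for k, v in phantom.spec.class_params.items()}
    paths["spec"] = out / "phantom_spec.json"
    paths["spec"].write_text(json.dumps(sidecar, indent=2))
    return paths
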