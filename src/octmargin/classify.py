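"""Tissue-type classification and margin projection.

Training follows the guided workflow: a handful of regions of interest
per tissue type, labeled from high-resolution confocal review, provide
feature values from which one-dimensional decision thresholds are
trained by exhaustive midpoint search.  The decision list is

    adipose  if slope > slope threshold   (septa membrane edges)
    tumor    elif roughness SD > roughness threshold
    benign   otherwise

Voxel classification applies the same rule to per-plane texture maps of
the depth-compensated, log-scaled volume; the two feature maps are
pooled over a lateral window first, since tissue type is a regional
property and the per-pixel maps carry residual speckle variance.

Positive-margin projection collapses the label volume laterally: a
surface pixel is margin-positive when any tumor voxel lies within a
clinical depth (default 1 mm) below the local tissue surface; small
connected components are discarded before the specimen-level call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.morphology import remove_small_objects

from . import phantom as ph
from .surfaces import SurfaceProfile
from .texture import FEATURE_NAMES, ROIFeatures, TextureParams, compute_feature_stack

__all__ = [
    "ClassifierModel", "PCAReport", "MarginMask",
    "train", "pca_report", "classify_voxels", "project_margin",
    "specimen_call", "LOG_FLOOR",
]

#: additive floor before log-scaling an intensity image; matches the
#: detector noise level so empty regions do not blow up in log space
LOG_FLOOR = 0.01

#: lateral pooling window (px) for the per-voxel feature maps
DEFAULT_POOL_WINDOW = 21


def log_scale(volume: np.ndarray, floor: float = LOG_FLOOR) -> np.ndarray:
    """Log-transform intensities with a noise floor.

    OCT tissue contrast is multiplicative (reflectivity x speckle x
    attenuation), so all texture analysis operates on log intensities,
    where speckle becomes additive and independent of brightness.
    """
    return np.log(np.clip(volume, 0.0, None) + floor)


@dataclass(frozen=True)
class ClassifierModel:
    """Trained two-feature decision list with provenance.

    ``depth_thresholds``, when present, carries depth-resolved threshold
    samples ``(depths, slope_thrs, rough_thrs)`` trained per depth bin:
    feature contrast in log-scaled OCT decays as the signal approaches
    the noise floor, so the assignment thresholds must account for depth.
    """

    slope_threshold: float
    roughness_threshold: float
    class_stats: dict  # class name -> {feature -> (mean, sd)}
    n_training_rois: dict  # class name -> count
    tie_break: tuple[str, ...] = ("adipose", "tumor", "benign")
    pool_window: int = DEFAULT_POOL_WINDOW
    depth_thresholds: tuple | None = None

    def thresholds_at(self, z: int) -> tuple[float, float]:
        """(slope, roughness) thresholds for depth index z, linearly
        interpolated between trained depth bins (constant beyond)."""
        if self.depth_thresholds is None:
            return self.slope_threshold, self.roughness_threshold
        depths, slope_thrs, rough_thrs = self.depth_thresholds
        s = float(np.interp(z, depths, slope_thrs)) if len(slope_thrs) \
            else self.slope_threshold
        r = float(np.interp(z, depths, rough_thrs)) if len(rough_thrs) \
            else self.roughness_threshold
        return s, r

    def predict_roi(self, features: ROIFeatures, depth: int | None = None) -> str:
        """Classify one ROI from its summary features."""
        s_thr, r_thr = (self.thresholds_at(depth) if depth is not None
                        else (self.slope_threshold, self.roughness_threshold))
        if features.mean_slope > s_thr:
            return "adipose"
        if features.mean_roughness_sd > r_thr:
            return "tumor"
        return "benign"


def _best_midpoint(pos: np.ndarray, neg: np.ndarray, feature: str) -> float:
    """1-D threshold minimizing misclassification of pos (above) vs neg
    (below), searched over midpoints of consecutive sorted values.

    Ties are broken towards the midpoint with the widest separating gap.
    """
    values = np.concatenate([pos, neg])
    if np.ptp(values) == 0:
        raise ValueError(
            f"feature {feature!r} is identical across classes — "
            "threshold is degenerate")
    uniq = np.unique(values)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    gaps = uniq[1:] - uniq[:-1]
    best_thr, best_err, best_gap = None, None, -1.0
    for thr, gap in zip(candidates, gaps):
        err = int((pos <= thr).sum() + (neg > thr).sum())
        if best_err is None or err < best_err or (err == best_err and gap > best_gap):
            best_thr, best_err, best_gap = thr, err, gap
    return float(best_thr)


def train(labeled_features: list[ROIFeatures]) -> ClassifierModel:
    """Train decision thresholds from labeled training ROIs.

    Requires at least two represented classes.  The slope threshold
    separates adipose (above) from everything else; the roughness-SD
    threshold separates tumor (above) from benign, using only non-adipose
    ROIs.  When a class is absent its branch is disabled (threshold at
    infinity), which is permitted as long as two classes remain.
    """
    by_class: dict[str, list[ROIFeatures]] = {}
    for f in labeled_features:
        if f.label is None:
            raise ValueError("training ROIs must carry a class label")
        by_class.setdefault(f.label, []).append(f)
    if len(by_class) < 2:
        raise ValueError("training requires at least two represented classes")

    def col(cls: str, feat: str) -> np.ndarray:
        return np.array([getattr(f, feat) for f in by_class.get(cls, [])])

    non_adipose = [c for c in by_class if c != "adipose"]
    if "adipose" in by_class:
        neg = np.concatenate([col(c, "mean_slope") for c in non_adipose])
        slope_thr = _best_midpoint(col("adipose", "mean_slope"), neg, "mean_slope")
    else:
        slope_thr = np.inf

    if "tumor" in by_class and "benign" in by_class:
        rough_thr = _best_midpoint(col("tumor", "mean_roughness_sd"),
                                   col("benign", "mean_roughness_sd"),
                                   "mean_roughness_sd")
    elif "tumor" in by_class:
        rough_thr = -np.inf  # everything non-adipose is tumor
    else:
        rough_thr = np.inf

    stats = {
        cls: {feat: (float(col(cls, feat).mean()), float(col(cls, feat).std()))
              for feat in ("mean_roughness_sd", "mean_slope")}
        for cls in by_class
    }
    return ClassifierModel(
        slope_threshold=float(slope_thr),
        roughness_threshold=float(rough_thr),
        class_stats=stats,
        n_training_rois={cls: len(v) for cls, v in by_class.items()},
    )


def train_depth_resolved(pairs: list[tuple[int, ROIFeatures]],
                         pool_window: int = DEFAULT_POOL_WINDOW
                         ) -> ClassifierModel:
    """Train a model with depth-adjusted thresholds.

    ``pairs`` are (depth index, labeled ROI features).  The base
    decision list is trained on all ROIs pooled; additionally, each
    extraction depth with enough class coverage contributes its own
    threshold sample, so assignment accounts for the feature-contrast
    decay with depth.
    """
    base = train([f for _, f in pairs])
    by_depth: dict[int, list[ROIFeatures]] = {}
    for z, f in pairs:
        by_depth.setdefault(z, []).append(f)
    depths_s, slope_thrs = [], []
    depths_r, rough_thrs = [], []
    for z in sorted(by_depth):
        feats = by_depth[z]
        labels = {f.label for f in feats}
        if "adipose" in labels and labels - {"adipose"}:
            try:
                m = train(feats)
                if np.isfinite(m.slope_threshold):
                    depths_s.append(z)
                    slope_thrs.append(m.slope_threshold)
            except ValueError:
                pass
        if "tumor" in labels and "benign" in labels:
            try:
                m = train([f for f in feats if f.label in ("tumor", "benign")])
                if np.isfinite(m.roughness_threshold):
                    depths_r.append(z)
                    rough_thrs.append(m.roughness_threshold)
            except ValueError:
                pass
    depth_thresholds = None
    if depths_s or depths_r:
        # merge the two samplings onto one depth grid per feature
        depth_thresholds = (
            depths_s if depths_s else depths_r,
            slope_thrs if depths_s else [base.slope_threshold],
            rough_thrs if depths_r else [base.roughness_threshold],
        )
        if depths_s and depths_r and depths_s != depths_r:
            # keep separate grids: interpolate each on its own sampling
            depth_thresholds = (depths_s, slope_thrs,
                                list(np.interp(depths_s, depths_r, rough_thrs)))
    return ClassifierModel(
        slope_threshold=base.slope_threshold,
        roughness_threshold=base.roughness_threshold,
        class_stats=base.class_stats,
        n_training_rois=base.n_training_rois,
        pool_window=pool_window,
        depth_thresholds=depth_thresholds,
    )


@dataclass(frozen=True)
class PCAReport:
    """Principal components of a standardized ROI feature table."""

    loadings: np.ndarray           # components x features
    explained_variance: np.ndarray  # fractions, sum to 1
    cumulative: np.ndarray          # non-decreasing stair to 1
    feature_names: tuple[str, ...]


def pca_report(feature_table: np.ndarray,
               feature_names: tuple[str, ...] = FEATURE_NAMES) -> PCAReport:
    """Singular value decomposition of the standardized feature table.

    Features are standardized to zero mean and unit variance;
    zero-variance features are dropped with a warning.  The cumulative
    explained-variance stair indicates how many components carry the
    classification-relevant structure.
    """
    X = np.asarray(feature_table, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("feature table must be 2-D with at least 2 rows")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(feature_names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    return PCAReport(
        loadings=vt,
        explained_variance=frac,
        cumulative=np.cumsum(frac),
        feature_names=tuple(n for n, k in zip(feature_names, keep) if k),
    )


def _majority_smooth(labels: np.ndarray, classes: tuple[int, ...]) -> np.ndarray:
    """Majority vote over the 3x3x3 neighborhood (ties keep the first
    class in `classes` order)."""
    votes = np.stack([uniform_filter((labels == c).astype(float), size=3)
                      for c in classes])
    out = np.array(classes, dtype=labels.dtype)[votes.argmax(axis=0)]
    return out


def classify_voxels(volume: np.ndarray, model: ClassifierModel,
                    mask: np.ndarray,
                    texture_params: TextureParams | None = None,
                    majority_smooth: bool = True,
                    already_log: bool = False) -> np.ndarray:
    """Assign a tissue class to every voxel of a depth-compensated volume.

    Texture maps are computed independently on each en-face plane of the
    log-scaled volume, pooled over the model's lateral window, and pushed
    through the trained decision list.  Voxels outside the foreground
    mask are background.  A 3x3x3 majority vote (on by default) removes
    isolated misassignments.
    """
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask must share shape")
    if not np.isfinite(model.slope_threshold) and not np.isfinite(model.roughness_threshold):
        raise ValueError("model has no usable decision threshold")
    params = texture_params or TextureParams()
    logvol = vol if already_log else log_scale(vol)

    nz = vol.shape[0]
    labels = np.full(vol.shape, ph.BACKGROUND, dtype=np.uint8)
    w = model.pool_window
    for z in range(nz):
        if not msk[z].any():
            continue
        stack = compute_feature_stack(logvol[z], params)
        rsd = uniform_filter(stack.roughness_sd, w, mode="reflect")
        slope = uniform_filter(stack.slope, w, mode="reflect")
        s_thr, r_thr = model.thresholds_at(z)
        plane = np.where(slope > s_thr, ph.ADIPOSE,
                         np.where(rsd > r_thr,
                                  ph.TUMOR, ph.BENIGN)).astype(np.uint8)
        labels[z] = np.where(msk[z], plane, ph.BACKGROUND)

    if majority_smooth:
        smoothed = _majority_smooth(labels, (ph.ADIPOSE, ph.TUMOR, ph.BENIGN))
        labels = np.where(msk, smoothed, ph.BACKGROUND).astype(np.uint8)
    return labels


@dataclass(frozen=True)
class MarginMask:
    """Lateral projection of tumor presence near the specimen surface."""

    mask: np.ndarray               # 2-D bool (ny, nx)
    projection_depth_mm: float
    min_area_mm2: float
    pixel_area_mm2: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_area_mm2


def project_margin(labels: np.ndarray, top_depth: np.ndarray,
                   depth_mm: float = 1.0,
                   axial_voxel_um: float = 5.0,
                   lateral_voxel_um: float = 10.0,
                   min_area_mm2: float = 0.04) -> MarginMask:
    """Project tumor labels within a depth band below the surface.

    A lateral pixel is margin-positive when any voxel labeled tumor sits
    within ``depth_mm`` below the local top surface; connected
    components smaller than ``min_area_mm2`` are then removed.

    Parameters
    ----------
    labels : (nz, ny, nx) class volume
    top_depth : (ny, nx) top-surface depth index per lateral position
    """
    if depth_mm <= 0:
        raise ValueError("projection depth must be positive")
    lab = np.asarray(labels)
    top = np.asarray(top_depth, dtype=int)
    if top.shape != lab.shape[1:]:
        raise ValueError("top surface must match the lateral grid")
    nz = lab.shape[0]
    depth_vox = int(round(depth_mm * 1000.0 / axial_voxel_um))
    zz = np.arange(nz)[:, None, None]
    band = (zz >= top[None]) & (zz <= top[None] + depth_vox)
    mask = ((lab == ph.TUMOR) & band).any(axis=0)

    pixel_area = (lateral_voxel_um / 1000.0) ** 2
    min_px = max(1, int(np.ceil(min_area_mm2 / pixel_area)))
    # drop connected components with fewer than min_px pixels
    mask = remove_small_objects(mask, max_size=min_px - 1)
    return MarginMask(mask=mask, projection_depth_mm=depth_mm,
                      min_area_mm2=min_area_mm2, pixel_area_mm2=pixel_area)


def specimen_call(mask: MarginMask, min_area_mm2: float = 0.01) -> str:
    """Specimen-level dichotomy: 'positive' iff the surviving margin
    area reaches ``min_area_mm2``."""
    return "positive" if mask.area_mm2 >= min_area_mm2 else "negative"
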