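"""Spatial texture features for OCT tissue differentiation.

The discriminating machinery works on a roughness/waviness decomposition
of each image: high-frequency content is first suppressed with a small
Gaussian kernel; a much larger Gaussian then estimates the waviness
(large-scale baseline) which is subtracted from the smoothed image to
leave the roughness.  A sliding standard-deviation filter over the
roughness yields the key texture discriminator (tumor tissue scatters
with high local variance), and the Prewitt gradient magnitude yields the
tissue slope (adipose septa are strong edges).  A nine-feature summary
vector per region of interest feeds the classifier and the PCA report.

Depth compensation fits the exponential signal drop of the mean
foreground A-line and multiplies it back out, so downstream thresholds
apply uniformly at every depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, prewitt, uniform_filter

__all__ = [
    "TextureParams",
    "FeatureStack",
    "ROIFeatures",
    "DepthGain",
    "FEATURE_NAMES",
    "gaussian_smooth",
    "roughness_decompose",
    "roughness_sd",
    "prewitt_slope",
    "depth_compensate",
    "compute_feature_stack",
    "roi_features",
]

FEATURE_NAMES = (
    "mean_intensity",
    "intensity_sd",
    "mean_waviness",
    "mean_roughness_sd",
    "max_roughness_sd",
    "mean_slope",
    "slope_sd",
    "intensity_entropy",
    "local_contrast",
)


@dataclass(frozen=True)
class TextureParams:
    """Kernel sizes of the feature bank, in pixels.

    sigma_smooth < sigma_waviness is required: the first removes
    high-frequency (speckle-scale) content, the second estimates the
    large-scale baseline.
    """

    sigma_smooth: float = 2.0
    sigma_waviness: float = 16.0
    sd_window: int = 9
    #: the slope map is computed on a more strongly smoothed image so it
    #: responds to structural edges (adipose septa) rather than speckle
    sigma_slope: float = 3.0

    def __post_init__(self):
        if self.sigma_smooth <= 0:
            raise ValueError("sigma_smooth must be positive")
        if self.sigma_waviness <= self.sigma_smooth:
            raise ValueError("sigma_waviness must exceed sigma_smooth")
        if self.sd_window < 3 or self.sd_window % 2 == 0:
            raise ValueError("sd_window must be an odd integer >= 3")
        if self.sigma_slope <= 0:
            raise ValueError("sigma_slope must be positive")


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel texture maps derived from one image."""

    image: np.ndarray
    smoothed: np.ndarray
    waviness: np.ndarray
    roughness: np.ndarray
    roughness_sd: np.ndarray
    slope: np.ndarray
    params: TextureParams

    def __post_init__(self):
        shape = self.image.shape
        for name in ("smoothed", "waviness", "roughness", "roughness_sd", "slope"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} map shape differs from source image")


@dataclass(frozen=True)
class ROIFeatures:
    """Nine-scalar texture summary of a rectangular region of interest."""

    mean_intensity: float
    intensity_sd: float
    mean_waviness: float
    mean_roughness_sd: float
    max_roughness_sd: float
    mean_slope: float
    slope_sd: float
    intensity_entropy: float
    local_contrast: float
    label: str | None = None

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass(frozen=True)
class DepthGain:
    """Multiplicative depth-compensation curve, unit gain at the surface."""

    gain: np.ndarray
    rate_per_mm: float

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        if not np.isclose(g[0], 1.0):
            raise ValueError("gain must be normalized to 1 at the surface")
        object.__setattr__(self, "gain", g)


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution with reflective borders."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


def roughness_decompose(image: np.ndarray, sigma_smooth: float,
                        sigma_waviness: float) -> tuple[np.ndarray, np.ndarray]:
    """Split an image into waviness and roughness.

    The smoothed image (sigma_smooth) is filtered again at sigma_waviness
    to obtain the waviness profile, which is subtracted to leave the
    roughness, so smoothed == waviness + roughness exactly.

    Returns
    -------
    (waviness, roughness)
    """
    if sigma_waviness <= sigma_smooth:
        raise ValueError("sigma_waviness must exceed sigma_smooth")
    smoothed = gaussian_smooth(image, sigma_smooth)
    waviness = gaussian_smooth(smoothed, sigma_waviness)
    return waviness, smoothed - waviness


def roughness_sd(roughness: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window population standard deviation of the roughness map.

    Per-pixel SD over the ``window x window`` neighborhood (population
    normalization, n not n-1), reflective borders.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    r = np.asarray(roughness, dtype=float)
    mean = uniform_filter(r, window, mode="reflect")
    mean_sq = uniform_filter(r * r, window, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def prewitt_slope(image: np.ndarray) -> np.ndarray:
    """Prewitt gradient magnitude in intensity-per-pixel units.

    Kernels are normalized by 6 so a ramp of s per pixel yields slope s
    at interior pixels (and s*sqrt(2) on a 45-degree ramp).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    gy = prewitt(img, axis=0, mode="reflect") / 6.0
    gx = prewitt(img, axis=1, mode="reflect") / 6.0
    return np.hypot(gx, gy)


def depth_compensate(volume: np.ndarray, mask: np.ndarray,
                     axial_voxel_um: float = 5.0,
                     eps: float = 1e-12) -> tuple[DepthGain, np.ndarray]:
    """Fit and remove the exponential signal drop with depth.

    The mean foreground intensity vs depth (volume indexed [z, ...]) is
    fit in log space over a fixed set of lateral columns — those whose
    masked extent spans a common depth window (surface to the median
    bottom depth).  Holding the column set fixed avoids the survivorship
    bias of pooling all masked voxels, where dim columns leave the mask
    at shallow depths and flatten the apparent decay.  The fitted rate r
    gives a gain curve exp(+r z), unit at the surface, which multiplies
    the volume; for attenuation coefficient mu the fitted rate
    approximates the round-trip 2*mu.

    Parameters
    ----------
    volume, mask : ndarray
        Same shape; mask selects foreground (tissue) voxels.
    axial_voxel_um : float
        Axial voxel pitch, micrometres.

    Returns
    -------
    (DepthGain, compensated volume)
    """
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask must share shape")
    if not msk.any():
        raise ValueError("empty foreground mask")

    nz = vol.shape[0]
    flat = vol.reshape(nz, -1)
    mflat = msk.reshape(nz, -1)
    has = mflat.any(axis=0)
    tops = mflat[:, has].argmax(axis=0)
    bottoms = nz - 1 - mflat[::-1, has].argmax(axis=0)
    # start a couple of voxels below the surface: the specular window
    # reflection at the very top does not follow the tissue decay
    z_lo = int(np.percentile(tops, 90)) + 2
    z_hi = int(np.median(bottoms))
    cols = (tops <= z_lo) & (bottoms >= z_hi)
    if z_hi - z_lo < 1 or cols.sum() == 0:
        raise ValueError("too few populated depths to fit attenuation")
    z_mm = np.arange(nz) * axial_voxel_um / 1000.0
    window = slice(z_lo, z_hi + 1)
    log_mean = np.log(np.maximum(
        flat[window][:, has][:, cols].mean(axis=1), eps))
    slope, _ = np.polyfit(z_mm[window], log_mean, 1)
    if not np.isfinite(slope):
        raise ValueError("attenuation fit did not converge")
    rate = -slope  # positive for decaying signal
    gain = np.exp(rate * z_mm)
    gain = gain / gain[0]
    shape = (nz,) + (1,) * (vol.ndim - 1)
    return DepthGain(gain=gain, rate_per_mm=float(rate)), vol * gain.reshape(shape)


def compute_feature_stack(image: np.ndarray,
                          params: TextureParams | None = None) -> FeatureStack:
    """All per-pixel texture maps for one 2-D image."""
    params = params or TextureParams()
    img = np.asarray(image, dtype=float)
    waviness, roughness = roughness_decompose(
        img, params.sigma_smooth, params.sigma_waviness)
    smoothed = waviness + roughness
    return FeatureStack(
        image=img,
        smoothed=smoothed,
        waviness=waviness,
        roughness=roughness,
        roughness_sd=roughness_sd(roughness, params.sd_window),
        slope=prewitt_slope(gaussian_smooth(img, params.sigma_slope)),
        params=params,
    )


def _entropy_bits(values: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy of the intensity histogram, bits."""
    if np.ptp(values) == 0:
        return 0.0
    hist, _ = np.histogram(values, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def roi_features(stack: FeatureStack, roi: tuple[int, int, int, int],
                 label: str | None = None) -> ROIFeatures:
    """Nine-feature summary over a rectangular ROI.

    Parameters
    ----------
    roi : (row0, col0, height, width)
        Region in image coordinates, half-open.  Must fit inside the
        image and measure at least ``sd_window`` pixels per side; a
        border of ``sd_window // 2`` pixels is excluded from the
        statistics so the SD filter's support stays inside the ROI.
    """
    r0, c0, h, w = roi
    win = stack.params.sd_window
    if h < win or w < win:
        raise ValueError(f"ROI must be at least {win} px per side")
    nr, nc = stack.image.shape
    if r0 < 0 or c0 < 0 or r0 + h > nr or c0 + w > nc:
        raise ValueError("ROI exceeds image bounds")
    b = win // 2
    sl = (slice(r0 + b, r0 + h - b), slice(c0 + b, c0 + w - b))

    img = stack.image[sl]
    return ROIFeatures(
        mean_intensity=float(img.mean()),
        intensity_sd=float(img.std()),
        mean_waviness=float(stack.waviness[sl].mean()),
        mean_roughness_sd=float(stack.roughness_sd[sl].mean()),
        max_roughness_sd=float(stack.roughness_sd[sl].max()),
        mean_slope=float(stack.slope[sl].mean()),
        slope_sd=float(stack.slope[sl].std()),
        intensity_entropy=_entropy_bits(img.ravel()),
        local_contrast=float(np.abs(img - stack.smoothed[sl]).mean()),
        label=label,
    )
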