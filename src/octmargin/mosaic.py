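"""Line-strip coverage planning and cross-correlation stitching.

The instantaneous field of view (2.2 mm for OCT) is usually smaller than
the fluorescence-selected region of interest, so the region is covered
by parallel overlapping line strips.  Adjacent strips are registered by
normalized cross-correlation of their overlap bands (within a bounded
search around the nominal overlap) and composited with linear feathering.

Strips run along their long axis and are laid side by side along image
columns (axis 1); offsets are (row, col) pixel displacements of each
strip relative to its nominal position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StripLayout", "plan_strips", "register_pair", "stitch",
           "cut_strips", "DEFAULT_OVERLAP_FRACTION", "OCT_FOV_MM"]

#: Instantaneous OCT field of view, mm.
OCT_FOV_MM = 2.2
DEFAULT_OVERLAP_FRACTION = 0.10


@dataclass(frozen=True)
class StripLayout:
    """Geometry of a strip acquisition covering one ROI."""

    n_strips: int
    strip_length_mm: float
    step_mm: float
    overlap_mm: float
    fov_mm: float

    def __post_init__(self):
        if self.n_strips < 1:
            raise ValueError("need at least one strip")
        if not 0 < self.overlap_mm < self.fov_mm:
            raise ValueError("overlap must be in (0, fov)")

    @property
    def coverage_mm(self) -> float:
        return self.n_strips * self.fov_mm - (self.n_strips - 1) * self.overlap_mm


def plan_strips(roi_extent_mm: float, fov_mm: float = OCT_FOV_MM,
                overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
                strip_length_mm: float | None = None) -> StripLayout:
    """Number and geometry of strips needed to cover an ROI extent.

    overlap = overlap_fraction * fov; the strip count is the smallest n
    with n*fov - (n-1)*overlap >= roi_extent:
    n = ceil((roi - overlap) / (fov - overlap)), minimum 1.
    """
    if roi_extent_mm <= 0 or fov_mm <= 0:
        raise ValueError("ROI extent and FOV must be positive")
    if not 0 < overlap_fraction <= 0.5:
        raise ValueError("overlap fraction must be in (0, 0.5]")
    overlap = overlap_fraction * fov_mm
    n = max(1, math.ceil((roi_extent_mm - overlap) / (fov_mm - overlap) - 1e-9))
    return StripLayout(
        n_strips=n,
        strip_length_mm=strip_length_mm if strip_length_mm is not None else roi_extent_mm,
        step_mm=fov_mm - overlap,
        overlap_mm=overlap,
        fov_mm=fov_mm,
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation (Pearson) of two equal-shape blocks."""
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("constant overlap band — correlation undefined")
    return float((a * b).sum() / denom)


def register_pair(strip_a: np.ndarray, strip_b: np.ndarray,
                  nominal_overlap: int, search_radius: int
                  ) -> tuple[tuple[int, int], float]:
    """Estimate strip_b's displacement from its nominal position.

    strip_b nominally starts ``width(a) - nominal_overlap`` columns right
    of strip_a.  All integer displacements (dy, dx) within
    +/- search_radius are scored by normalized cross-correlation of the
    overlap band; the best-scoring displacement is returned with its
    score.  A constant overlap band raises, as the correlation is
    undefined there.
    """
    a = np.asarray(strip_a, dtype=float)
    b = np.asarray(strip_b, dtype=float)
    if nominal_overlap <= 0 or nominal_overlap > min(a.shape[1], b.shape[1]):
        raise ValueError("nominal overlap must be positive and fit both strips")
    if not 0 <= search_radius < nominal_overlap:
        raise ValueError("search radius must be smaller than the overlap")

    band_a_full = a[:, a.shape[1] - nominal_overlap:]
    best: tuple[int, int] | None = None
    best_score = -np.inf
    for dy in range(-search_radius, search_radius + 1):
        for dx in range(-search_radius, search_radius + 1):
            # b pixel aligning with band_a[y, j] is b[y - dy, j - dx]
            y0a, y1a = max(0, dy), min(a.shape[0], b.shape[0] + dy)
            j0, j1 = max(0, dx), min(nominal_overlap, b.shape[1] + dx)
            if y1a - y0a < 2 or j1 - j0 < 2:
                continue
            block_a = band_a_full[y0a:y1a, j0:j1]
            block_b = b[y0a - dy:y1a - dy, j0 - dx:j1 - dx]
            score = _ncc(block_a, block_b)
            if score > best_score:
                best_score = score
                best = (dy, dx)
    if best is None:
        raise ValueError("search window produced no valid overlap")
    return best, best_score


def stitch(strips: list[np.ndarray], offsets: list[tuple[int, int]],
           nominal_overlap: int | None = None,
           feather: int | None = None) -> np.ndarray:
    """Composite strips at cumulative offsets with linear feathering.

    Parameters
    ----------
    strips : list of 2-D arrays
        Ordered left to right.
    offsets : list of (dy, dx)
        Per adjacent pair, the displacement of the right strip from its
        nominal position (``len(strips) - 1`` entries).
    nominal_overlap : int
        Overlap in pixels implied by the acquisition plan; defaults to
        10% of the first strip's width.
    feather : int
        Width of the linear blend ramp at strip edges, px; defaults to
        the nominal overlap.

    Strips are accumulated with weights that ramp linearly from the
    lateral strip edges, then normalized, so constant inputs yield a
    constant mosaic and single-covered regions are passed through
    unchanged.
    """
    if len(strips) == 0:
        raise ValueError("no strips to stitch")
    if len(offsets) != len(strips) - 1:
        raise ValueError("need exactly one offset per adjacent pair")
    if len(strips) == 1:
        return np.asarray(strips[0], dtype=float).copy()
    if nominal_overlap is None:
        nominal_overlap = max(1, int(round(0.1 * strips[0].shape[1])))
    if feather is None:
        feather = nominal_overlap

    # cumulative placement (top-left corners)
    positions = [(0, 0)]
    for i, (dy, dx) in enumerate(offsets):
        py, px = positions[i]
        positions.append((py + dy, px + strips[i].shape[1] - nominal_overlap + dx))

    ys = [p[0] for p in positions]
    xs = [p[1] for p in positions]
    y_min = min(ys)
    x_min = min(xs)
    h = max(p[0] + s.shape[0] for p, s in zip(positions, strips)) - y_min
    w = max(p[1] + s.shape[1] for p, s in zip(positions, strips)) - x_min

    for i in range(1, len(strips)):
        if positions[i][1] >= positions[i - 1][1] + strips[i - 1].shape[1]:
            raise ValueError(f"strips {i - 1} and {i} are disjoint after offsets")

    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))
    for (py, px), s in zip(positions, strips):
        s = np.asarray(s, dtype=float)
        ramp = np.minimum(np.arange(1, s.shape[1] + 1),
                          np.arange(s.shape[1], 0, -1)).astype(float)
        weight = np.minimum(ramp / max(1, feather), 1.0)[None, :] * np.ones((s.shape[0], 1))
        sl = (slice(py - y_min, py - y_min + s.shape[0]),
              slice(px - x_min, px - x_min + s.shape[1]))
        acc[sl] += weight * s
        wacc[sl] += weight
    out = np.zeros_like(acc)
    np.divide(acc, wacc, out=out, where=wacc > 0)
    return out


def cut_strips(image: np.ndarray, n_strips: int, overlap_px: int,
               jitter_px: int = 0, rng: np.random.Generator | None = None
               ) -> tuple[list[np.ndarray], list[tuple[int, int]], int]:
    """Decompose an image into overlapping strips, optionally jittered.

    Emulates a strip acquisition of a known scene for round-trip and
    registration experiments: strips of equal width sharing
    ``overlap_px`` columns, each displaced by a uniform random (dy, dx)
    jitter of at most ``jitter_px`` from its nominal position.

    Returns
    -------
    (strips, true_offsets, overlap)
        ``true_offsets`` are the per-adjacent-pair displacements that
        ``register_pair`` should recover; ``overlap`` echoes the nominal
        overlap to pass to ``register_pair`` / ``stitch``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if n_strips < 1:
        raise ValueError("need at least one strip")
    if n_strips == 1:
        return [img.copy()], [], overlap_px
    # n strips of width (step + overlap) at spacing step span
    # n*step + overlap columns, which must fit inside the image
    step = (w - overlap_px) // n_strips
    if step <= 0:
        raise ValueError("image too narrow for the requested strips")
    width = step + overlap_px
    rng = rng or np.random.default_rng()
    strips = []
    true_offsets = []
    prev = (0, 0)
    height = h - 2 * jitter_px
    for i in range(n_strips):
        if i == 0 or jitter_px == 0:
            dy, dx = 0, 0
        else:
            dy = int(rng.integers(-jitter_px, jitter_px + 1))
            dx = int(rng.integers(-jitter_px, jitter_px + 1))
        x0 = min(max(0, i * step + dx), w - width)
        dx = x0 - i * step
        y0 = jitter_px + dy
        strips.append(img[y0:y0 + height, x0:x0 + width].copy())
        if i > 0:
            true_offsets.append((dy - prev[0], dx - prev[1]))
        prev = (dy, dx)
    return strips, true_offsets, overlap_px
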