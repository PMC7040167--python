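"""Leaf angle distribution by autonomous ROI sampling and local plane fits.

Instead of trusting every mesh face, this method samples square regions of
interest that plausibly lie on a single leaf — every pixel must carry a
plausible height and the square must contain no Canny edge, since edges mark
leaf boundaries — fits a plane to each ROI's back-projected point cloud, and
records the tilt angles in 5-degree classes from 0 to 90.  The sampler first
tries 30 px squares; if too few qualify it restarts at 20 px and finally
10 px, returning squares of a single size.

The plane fit is a vertical (z-on-xy) least squares by default: for a nadir
height field the error budget is dominated by depth noise along the optical
axis, which at a metre of range is an order of magnitude larger than the
lateral pixel size, and an orthogonal fit would mistake that noise for the
surface extent.  Orthogonal total least squares remains available for
near-isotropic point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, sobel
from skimage.feature import canny

from .camera_geometry import StereoRig
from .height_analysis import HeightMap


class FitError(ValueError):
    """Raised for degenerate point configurations."""


@dataclass(frozen=True)
class LeafROI:
    """One sampled leaf zone: origin (row, col), square size, fitted tilt."""

    origin: tuple[int, int]
    size: int
    tilt: float
    fit_rms: float


@dataclass
class AngleDistribution:
    """Leaf angle distribution in 5-degree classes over [0, 90)."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_rois: int
    mean_tilt: float

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.bin_edges) - 1:
            raise ValueError("frequencies must have one entry per bin")


# ---------------------------------------------------------------------------
# edges


def detect_leaf_edges(gray: np.ndarray, sigma: float = 1.4,
                      high_quantile: float = 0.90,
                      low_fraction: float = 0.4) -> np.ndarray:
    """Canny edge map with data-driven hysteresis thresholds.

    The high threshold is the ``high_quantile`` of the smoothed gradient
    magnitude; the low threshold is ``low_fraction`` times the high one.
    A constant image yields no edges.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a grayscale raster")
    smoothed = gaussian_filter(gray, sigma)
    gx, gy = sobel(smoothed, axis=1), sobel(smoothed, axis=0)
    mag = np.hypot(gx, gy)
    high = float(np.quantile(mag, high_quantile))
    if high <= 0:
        return np.zeros_like(gray, dtype=bool)
    return canny(gray, sigma=sigma, low_threshold=low_fraction * high,
                 high_threshold=high)


# ---------------------------------------------------------------------------
# plane fitting


def fit_plane(points: np.ndarray, method: str = "vertical"
              ) -> tuple[np.ndarray, float]:
    """Fit a plane; returns (unit normal, rms of orthogonal residuals in m).

    ``method="vertical"`` regresses z on (x, y) — the maximum-likelihood fit
    when errors live on the depth axis; ``method="orthogonal"`` is classical
    total least squares (smallest principal component of the centered cloud).
    Raises :class:`FitError` for fewer than three or collinear points.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise FitError("points must be (N, 3)")
    if len(P) < 3:
        raise FitError("need at least 3 points to fit a plane")
    centered = P - P.mean(axis=0)
    if method == "orthogonal":
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] < 1e-12 * max(s[0], 1e-300):
            raise FitError("points are collinear")
        normal = vt[2]
        rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    elif method == "vertical":
        A = centered[:, :2]
        # rank check on the xy footprint: collinear pixels cannot span a plane
        s = np.linalg.svd(A, compute_uv=False)
        if s[1] < 1e-12 * max(s[0], 1e-300):
            raise FitError("points are collinear in the image plane")
        coef, *_ = np.linalg.lstsq(np.column_stack([A, np.ones(len(A))]),
                                   centered[:, 2], rcond=None)
        a, b = coef[0], coef[1]
        normal = np.array([-a, -b, 1.0])
        normal /= np.linalg.norm(normal)
        resid = centered[:, 2] - (A @ coef[:2] + coef[2])
        rms = float(np.sqrt(np.mean((resid * normal[2]) ** 2)))
    else:
        raise ValueError(f"unknown fit method {method!r}")
    if normal[2] < 0:
        normal = -normal
    return normal, rms


def tilt_from_normal(normal: np.ndarray) -> float:
    """Angle (deg) between the plane and the horizontal, folded to [0, 90].

    Equals the angle between the normal and the z-axis, folded.
    """
    n = np.asarray(normal, dtype=float)
    mag = np.linalg.norm(n)
    if mag == 0:
        raise ValueError("zero normal vector")
    return float(np.degrees(np.arccos(np.clip(abs(n[2]) / mag, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# ROI sampling


def sample_rois(hmap: HeightMap, edges: np.ndarray, plant_mask: np.ndarray,
                rig: StereoRig, min_count: int = 20,
                sizes: Sequence[int] = (30, 20, 10),
                min_clearance: float = 0.6,
                fit_method: str = "vertical") -> list[LeafROI]:
    """Greedy scan for non-overlapping edge-free leaf squares, then fit each.

    Squares are tried on a row-major grid with stride equal to the square
    size, so returned ROIs can never overlap.  A square qualifies when every
    covered pixel is plant, carries a valid plausible height (between 0 and
    ``ground_depth - min_clearance``) and no detected edge.  If fewer than
    ``min_count`` squares qualify at the current size the scan restarts at the
    next smaller size; only the final size is returned (possibly an empty
    list).
    """
    edges = np.asarray(edges, dtype=bool)
    plant_mask = np.asarray(plant_mask, dtype=bool)
    max_height = hmap.ground_depth - min_clearance
    vals = np.nan_to_num(hmap.values, nan=-1.0)
    good = (plant_mask & hmap.valid & ~edges
            & (vals >= 0.0) & (vals <= max_height))
    bad = ~good
    h, w = good.shape
    # integral image of bad pixels: window sum == 0 <=> fully usable square
    I = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(bad, axis=0), axis=1, out=I[1:, 1:])

    def n_bad(r, c, size):
        return (I[r + size, c + size] - I[r, c + size]
                - I[r + size, c] + I[r, c])

    chosen: list[tuple[int, int]] = []
    final_size = None
    for size in sizes:
        # row-major greedy scan: a row band advances by the square size once it
        # yields a square (bands cannot overlap), by one pixel otherwise, so
        # squares lock onto leaves regardless of their grid offset
        chosen = []
        r = 0
        while r <= h - size:
            found = False
            c = 0
            while c <= w - size:
                if n_bad(r, c, size) == 0:
                    chosen.append((r, c))
                    found = True
                    c += size
                else:
                    c += 1
            r += size if found else 1
        final_size = size
        if len(chosen) >= min_count:
            break
    if not chosen:
        return []

    cx, cy = rig.center
    f = rig.focal_px
    rois = []
    for (r, c) in chosen:
        vv, uu = np.mgrid[r:r + final_size, c:c + final_size]
        z = hmap.ground_depth - hmap.values[r:r + final_size, c:c + final_size]
        x = (uu - cx) * z / f
        y = (vv - cy) * z / f
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        try:
            normal, rms = fit_plane(pts, method=fit_method)
        except FitError:
            continue
        rois.append(LeafROI(origin=(r, c), size=final_size,
                            tilt=tilt_from_normal(normal), fit_rms=rms))
    return rois


# ---------------------------------------------------------------------------
# distribution


def lad_histogram(rois: Sequence[LeafROI], bin_width: float = 5.0
                  ) -> AngleDistribution:
    """Normalized tilt histogram in 5-degree classes plus the local-fit MTA.

    Returns an all-NaN distribution for an empty ROI list.
    """
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    if len(rois) == 0:
        return AngleDistribution(edges, np.full(len(edges) - 1, np.nan), 0,
                                 float("nan"))
    tilts = np.array([r.tilt for r in rois], dtype=float)
    hist, _ = np.histogram(np.clip(tilts, 0.0, 90.0 - 1e-9), bins=edges)
    freq = hist / hist.sum()
    return AngleDistribution(edges, freq, len(rois), float(tilts.mean()))
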