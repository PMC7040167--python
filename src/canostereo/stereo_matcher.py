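"""Dense disparity estimation by semi-global block matching.

The matcher follows the classic recipe: a per-pixel matching cost (sum of
absolute differences over a square window) is aggregated along eight 1-D
scanline directions with small/large smoothness penalties P1/P2, and the
winner-take-all disparity is kept only where it beats the runner-up by a
uniqueness margin.  Sub-pixel disparity comes from a parabolic fit of the
three aggregated costs around the minimum.  Holes are later filled by
inverse-distance-weighted interpolation, but only where enough reliably
matched neighbors exist.

All passes are vectorized: each aggregation direction is a single dynamic
program whose inner state is a (rows x disparities) or (cols x disparities)
slab, so no per-pixel Python loops occur.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree

from .camera_geometry import DepthMap, ImagePair, StereoRig, disparity_to_depth

_BIG = np.float32(1e9)


@dataclass(frozen=True)
class MatcherConfig:
    """Knobs of the semi-global matcher.

    ``window_size`` is the side of the matching neighborhood (15 by default),
    ``disparity_range`` the maximal disparity searched, and ``uniqueness`` the
    percentage margin by which the best aggregated cost must beat the
    second-best (5 by default).  P1/P2 default to the standard 8*w^2 / 32*w^2
    scaling of the window area on the 0-255 intensity scale.
    """

    window_size: int = 15
    disparity_range: int = 64
    uniqueness: float = 5.0
    num_directions: int = 8
    p1: Optional[float] = None
    p2: Optional[float] = None
    lr_consistency: bool = True
    #: minimum window intensity variance (0-255 scale); below it a pixel has
    #: no information to match and is rejected as ambiguous
    texture_threshold: float = 1.0

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.disparity_range < 1:
            raise ValueError("disparity_range must be >= 1")
        if self.uniqueness < 0:
            raise ValueError("uniqueness must be >= 0")
        if self.num_directions not in (2, 4, 8):
            raise ValueError("num_directions must be 2, 4 or 8")

    @property
    def penalty1(self) -> float:
        return self.p1 if self.p1 is not None else 8.0 * self.window_size ** 2

    @property
    def penalty2(self) -> float:
        return self.p2 if self.p2 is not None else 32.0 * self.window_size ** 2


@dataclass
class DisparityMap:
    """Disparities of the left (reference) view, with validity bookkeeping.

    ``filled`` marks cells whose value came from interpolation rather than
    matching; ``filled`` is a subset of ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    filled: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.filled is None:
            self.filled = np.zeros_like(self.valid)
        self.values = np.where(self.valid, self.values, np.nan).astype(np.float32)

    def copy(self) -> "DisparityMap":
        return DisparityMap(self.values.copy(), self.valid.copy(), self.filled.copy())

    def to_depth(self, rig: StereoRig) -> DepthMap:
        z = disparity_to_depth(self.values, rig)
        ok = self.valid & np.isfinite(z) & (z > 0)
        return DepthMap(np.where(ok, z, np.nan), ok, self.filled & ok)


# ---------------------------------------------------------------------------
# cost volume and aggregation


def _to_gray255(img: np.ndarray, bit_depth: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 3:
        img = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return img * (255.0 / ((1 << bit_depth) - 1))


def _sad_cost_volume(left: np.ndarray, right: np.ndarray, ndisp: int,
                     window: int) -> np.ndarray:
    """(H, W, D) window-summed absolute differences; unreachable cells large."""
    h, w = left.shape
    cost = np.empty((h, w, ndisp), dtype=np.float32)
    area = float(window * window)
    half = window // 2
    for d in range(ndisp):
        diff = np.empty_like(left)
        diff[:, d:] = np.abs(left[:, d:] - right[:, : w - d])
        if d:
            diff[:, :d] = 0.0
        mean = uniform_filter(diff, size=window, mode="nearest")
        cost[:, :, d] = mean * area
        if d:
            # columns whose window touches the unmapped left band are unreliable
            cost[:, : min(w, d + half), d] = _BIG
    return cost


def _aggregate_direction(cost: np.ndarray, axis_steps: tuple[int, int],
                         p1: float, p2: float) -> np.ndarray:
    """Semi-global DP along one direction (dy, dx); returns path costs L_r."""
    dy, dx = axis_steps
    h, w, nd = cost.shape
    L = np.empty_like(cost)
    if dx != 0:
        cols = range(w) if dx > 0 else range(w - 1, -1, -1)
        first = next(iter(cols))
        prev = None
        for x in cols:
            c = cost[:, x, :]
            if x == first:
                L[:, x, :] = c
            else:
                L[:, x, :] = c + _dp_step(prev, dy, p1, p2)
            prev = L[:, x, :]
    else:
        rows = range(h) if dy > 0 else range(h - 1, -1, -1)
        first = next(iter(rows))
        prev = None
        for y in rows:
            c = cost[y, :, :]
            if y == first:
                L[y, :, :] = c
            else:
                L[y, :, :] = c + _dp_step(prev, 0, p1, p2)
            prev = L[y, :, :]
    return L


def _dp_step(prev: np.ndarray, shift_rows: int, p1: float, p2: float) -> np.ndarray:
    """One DP transition: min over (same d, d +/- 1 + P1, anything + P2).

    ``prev`` is a (N, D) slab of the previous pixel's path costs along the
    scanline; ``shift_rows`` realigns it for diagonal directions.
    """
    if shift_rows:
        prev = np.roll(prev, shift_rows, axis=0)
        if shift_rows > 0:
            prev[:shift_rows, :] = _BIG
        else:
            prev[shift_rows:, :] = _BIG
    m = prev.min(axis=1, keepdims=True)
    cand = prev.copy()
    cand[:, 1:] = np.minimum(cand[:, 1:], prev[:, :-1] + p1)
    cand[:, :-1] = np.minimum(cand[:, :-1], prev[:, 1:] + p1)
    np.minimum(cand, m + p2, out=cand)
    out = cand - m
    np.minimum(out, _BIG, out=out)  # keep unreachable cells finite-but-huge
    return out


_DIRECTIONS_8 = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1), (1, -1), (-1, 1)]


def match_semiglobal(pair: ImagePair, cfg: MatcherConfig = MatcherConfig()
                     ) -> DisparityMap:
    """Dense sub-pixel disparities of the left view.

    Requires a rectified pair; color input is converted to luminance
    internally and rescaled to the 0-255 range so behaviour is independent of
    the storage bit depth.
    """
    if not pair.rectified:
        raise ValueError("stereo matching requires a rectified pair")
    left = _to_gray255(pair.left, pair.bit_depth)
    right = _to_gray255(pair.right, pair.bit_depth)
    ndisp = int(cfg.disparity_range) + 1
    if ndisp > left.shape[1]:
        raise ValueError("disparity range exceeds image width")

    cost = _sad_cost_volume(left, right, ndisp, cfg.window_size)
    agg = np.zeros_like(cost)
    for dy, dx in _DIRECTIONS_8[: cfg.num_directions]:
        agg += _aggregate_direction(cost, (dy, dx), cfg.penalty1, cfg.penalty2)

    best = np.argmin(agg, axis=2)
    h, w = left.shape
    yy, xx = np.ogrid[:h, :w]
    best_cost = agg[yy, xx, best]

    # uniqueness: runner-up outside +/-1 of the winner must be clearly worse
    masked = agg.copy()
    for off in (-1, 0, 1):
        idx = np.clip(best + off, 0, ndisp - 1)
        masked[yy, xx, idx] = _BIG
    second = masked.min(axis=2)
    # strict margin: equal-cost ambiguity (e.g. textureless areas) is rejected
    ok_unique = best_cost * (1.0 + cfg.uniqueness / 100.0) < second
    ok_unique |= second >= _BIG  # no alternative candidate at all
    matched = best_cost < _BIG
    valid = ok_unique & matched

    # sub-pixel refinement: parabola through the three costs around the min
    disp = best.astype(np.float32)
    inner = (best > 0) & (best < ndisp - 1)
    bm = np.clip(best - 1, 0, ndisp - 1)
    bp = np.clip(best + 1, 0, ndisp - 1)
    cm = agg[yy, xx, bm]
    cp = agg[yy, xx, bp]
    denom = cm - 2.0 * best_cost + cp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (cm - cp) / denom
    refine = inner & np.isfinite(delta) & (np.abs(delta) <= 1.0) & (cm < _BIG) & (cp < _BIG)
    disp[refine] += delta[refine].astype(np.float32)

    if cfg.texture_threshold > 0:
        mu = uniform_filter(left, size=cfg.window_size, mode="nearest")
        mu2 = uniform_filter(left * left, size=cfg.window_size, mode="nearest")
        valid &= (mu2 - mu * mu) >= cfg.texture_threshold

    if cfg.lr_consistency:
        # WTA disparity of the right view from the same aggregated volume;
        # occluded left pixels have no consistent right-view partner
        best_r = np.full((h, w), _BIG, dtype=np.float32)
        d_right = np.zeros((h, w), dtype=np.int32)
        for d in range(ndisp):
            c = agg[:, d:, d]
            upd = c < best_r[:, : w - d]
            d_right[:, : w - d][upd] = d
            best_r[:, : w - d][upd] = c[upd]
        xr = np.clip(np.round(xx - disp).astype(int), 0, w - 1)
        dr = np.take_along_axis(d_right, xr, axis=1)
        valid &= np.abs(dr - disp) <= 1.0

    # image borders can never contain the full matching window
    half = cfg.window_size // 2
    if half:
        valid[:, :half] = False
        valid[:, -half:] = False
        valid[:half, :] = False
        valid[-half:, :] = False

    return DisparityMap(disp, valid)


# ---------------------------------------------------------------------------
# automatic disparity-range adjustment


def auto_disparity_range(pair: ImagePair, cfg: MatcherConfig,
                         peak_fraction: float = 0.02,
                         max_enlargements: int = 6) -> MatcherConfig:
    """Enlarge the disparity range until matches no longer pile up at its top.

    The range grows in multiples of 16 whenever more than ``peak_fraction`` of
    the valid disparities land in the topmost bin, signalling that the true
    maximum disparity was clipped.  Raises if the range would exceed the image
    width or the scene keeps peaking after ``max_enlargements`` retries.
    """
    width = pair.left.shape[1]
    current = cfg
    for _ in range(max_enlargements + 1):
        if current.disparity_range >= width:
            raise ValueError("disparity range exceeds image width")
        dmap = match_semiglobal(pair, current)
        vals = dmap.values[dmap.valid]
        if vals.size == 0:
            return current
        top = np.count_nonzero(vals >= current.disparity_range - 1)
        if top <= peak_fraction * vals.size:
            return current
        grown = 16 * int(np.ceil((current.disparity_range * 1.5) / 16.0))
        current = replace(current, disparity_range=grown)
    raise ValueError("disparity histogram still peaked after maximal enlargement")


# ---------------------------------------------------------------------------
# hole filling


def fill_disparity(dmap: DisparityMap, max_radius: float = 12.0,
                   min_neighbors: int = 4, k_neighbors: int = 8) -> DisparityMap:
    """Interpolate invalid cells from reliably matched neighbors.

    A cell is filled by inverse-distance weighting of up to ``k_neighbors``
    matched (never previously interpolated) cells within ``max_radius``
    pixels, and only if at least ``min_neighbors`` such cells exist; isolated
    holes inside large unmatched regions stay invalid.  Because sources are
    restricted to originally matched cells, the operation is idempotent and
    never alters valid cells.
    """
    out = dmap.copy()
    sources = dmap.valid & ~dmap.filled
    targets = ~dmap.valid
    if not targets.any() or not sources.any():
        return out
    src_idx = np.argwhere(sources)
    tgt_idx = np.argwhere(targets)
    tree = cKDTree(src_idx)
    k = min(k_neighbors, len(src_idx))
    dist, nbr = tree.query(tgt_idx, k=k, distance_upper_bound=max_radius)
    dist = np.atleast_2d(dist.T).T if dist.ndim == 1 else dist
    nbr = np.atleast_2d(nbr.T).T if nbr.ndim == 1 else nbr
    found = np.isfinite(dist)
    enough = found.sum(axis=1) >= min_neighbors
    if not enough.any():
        return out
    src_vals = dmap.values[sources.nonzero()]
    w = np.where(found, 1.0 / np.maximum(dist, 0.5), 0.0)
    vals = np.where(found, src_vals[np.clip(nbr, 0, len(src_idx) - 1)], 0.0)
    est = (w * vals).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-12)
    rows, cols = tgt_idx[enough, 0], tgt_idx[enough, 1]
    out.values[rows, cols] = est[enough].astype(np.float32)
    out.valid[rows, cols] = True
    out.filled[rows, cols] = True
    return out


# ---------------------------------------------------------------------------
# matching-quality indicator


def plausible_height_fraction(dmap: DisparityMap, plant_mask: np.ndarray,
                              rig: StereoRig, ground_depth: float,
                              min_clearance: float = 0.6) -> float:
    """Fraction of plant pixels whose depth lies between the ground and
    ``min_clearance`` metres below the device.

    A matching-quality indicator: heights outside that band are physically
    implausible for the canopy, so a low fraction flags poor matching.
    Returns NaN for an empty plant mask.
    """
    if ground_depth <= min_clearance:
        raise ValueError("ground depth must exceed the clearance band")
    plant_mask = np.asarray(plant_mask, dtype=bool)
    n_plant = int(plant_mask.sum())
    if n_plant == 0:
        return float("nan")
    depth = disparity_to_depth(dmap.values, rig)
    ok = dmap.valid & np.isfinite(depth) & (depth >= min_clearance) & (depth <= ground_depth)
    return float(np.count_nonzero(ok & plant_mask)) / n_plant
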