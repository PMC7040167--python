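"""Canopy height maps and their statistical descriptors.

Plant height is the difference between the camera-ground and camera-plant
distances.  The ground distance is taken from the depth of visible soil
pixels — a high percentile, since soil is the farthest surface and mixed
border pixels bias low — with a manual fallback for dense canopies that show
too little soil.  Canopy height is summarized by order statistics (median,
75th and 95th percentiles) plus the standard deviation; after ear emergence
the agronomically relevant trait is the mean spike-top height, the mean over
spike objects of each object's 95th height percentile (objects weigh equally
regardless of their pixel count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.measure import label as cc_label

from .camera_geometry import DepthMap


@dataclass
class HeightMap:
    """Heights above ground (m) for plant pixels, clipped to [0, ground]."""

    values: np.ndarray
    valid: np.ndarray
    ground_depth: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ground_depth <= 0:
            raise ValueError("ground depth must be positive")


@dataclass(frozen=True)
class HeightDescriptors:
    median: float
    p75: float
    p95: float
    std: float

    def __post_init__(self):
        if not (self.median <= self.p75 + 1e-12 and self.p75 <= self.p95 + 1e-12):
            raise ValueError("percentiles must be ordered")
        if self.std < 0:
            raise ValueError("std must be nonnegative")


def estimate_ground_depth(dmap: DepthMap, soil_mask: np.ndarray,
                          fallback: Optional[float] = None,
                          min_pixels: int = 200,
                          percentile: float = 90.0) -> float:
    """Camera-ground distance from the soil pixels' depth distribution.

    Uses the given high percentile of valid soil depths.  When fewer than
    ``min_pixels`` valid soil pixels are visible the estimate is considered
    unreliable and the configured ``fallback`` (a manually measured distance)
    is returned instead; with no fallback, raises.
    """
    soil_mask = np.asarray(soil_mask, dtype=bool)
    depths = dmap.values[soil_mask & dmap.valid]
    depths = depths[np.isfinite(depths)]
    if len(depths) < min_pixels:
        if fallback is not None:
            return float(fallback)
        raise ValueError(
            f"only {len(depths)} valid soil pixels (<{min_pixels}) and no "
            "manual ground-depth override configured")
    return float(np.percentile(depths, percentile))


def depth_to_height(dmap: DepthMap, ground_depth: float,
                    plant_mask: Optional[np.ndarray] = None) -> HeightMap:
    """Height map: ground depth minus plant depth, clipped to [0, ground]."""
    if ground_depth <= 0:
        raise ValueError("ground depth must be positive")
    valid = dmap.valid.copy()
    if plant_mask is not None:
        valid &= np.asarray(plant_mask, dtype=bool)
    h = np.clip(ground_depth - dmap.values, 0.0, ground_depth)
    return HeightMap(np.where(valid, h, np.nan), valid, ground_depth)


def height_descriptors(hmap: HeightMap,
                       plant_mask: Optional[np.ndarray] = None) -> HeightDescriptors:
    """Median, 75th, 95th percentile and standard deviation of plant heights.

    Percentiles interpolate linearly between order statistics.
    """
    sel = hmap.valid if plant_mask is None else (hmap.valid & np.asarray(plant_mask, bool))
    vals = hmap.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid plant heights")
    med, p75, p95 = np.percentile(vals, [50, 75, 95])
    return HeightDescriptors(float(med), float(p75), float(p95), float(vals.std()))


def mean_spike_top_height(hmap: HeightMap, spike_mask: np.ndarray,
                          min_size: int = 50, connectivity: int = 2) -> float:
    """Mean over spike objects of each object's 95th height percentile.

    Spike objects come from 8-connected components of the spike mask; blobs
    smaller than ``min_size`` pixels are treated as segmentation noise.  Every
    surviving object contributes equally.  Returns NaN when no object
    survives.
    """
    spike_mask = np.asarray(spike_mask, dtype=bool) & hmap.valid
    lab = cc_label(spike_mask, connectivity=connectivity)
    tops = []
    for obj in range(1, lab.max() + 1):
        sel = lab == obj
        if sel.sum() < min_size:
            continue
        vals = hmap.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            tops.append(np.percentile(vals, 95))
    if not tops:
        return float("nan")
    return float(np.mean(tops))
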