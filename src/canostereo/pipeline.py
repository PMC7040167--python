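"""End-to-end trait extraction: rectify, bin, match, segment, measure.

One call takes a raw stereo pair to a row of canopy traits: height
descriptors, raw (and optionally calibrated) LAI, MTA by both the global
Delaunay and the local-fitting method, the LAD table, and the matching /
saturation quality indicators.  Processing order follows the acquisition
pipeline: rectification, grayscale conversion, 2x2 binning, semi-global
matching with automatic disparity range, hole filling, depth conversion,
segmentation, then traits.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import camera_geometry as cg
from . import height_analysis as ha
from . import local_fitting as lf
from . import mesh_traits as mt
from . import segmentation as seg
from . import stereo_matcher as sm
from .lai_calibration import ExponentialModel, predict

log = logging.getLogger("canostereo")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the images themselves."""

    rig: cg.StereoRig
    matcher: sm.MatcherConfig = field(default_factory=sm.MatcherConfig)
    n_classes: int = 2
    model: Optional[seg.ClassifierModel] = None
    calibration: Optional[ExponentialModel] = None
    ground_override: Optional[float] = None
    min_clearance: float = 0.6
    bin_images: bool = True
    fill_holes: bool = True
    mesh_exclude_filled: bool = True
    mesh_bin_factor: int = 1
    # light despeckle: with sub-pixel matching the depth noise is far below
    # the resolution step, and wider medians mainly erode thin leaves
    mesh_median_window: int = 3
    max_edge_m: float = 0.03
    roi_min_count: int = 20
    spike_min_size: int = 50
    seed: int = 0

    def config_hash(self) -> str:
        rec = {
            "baseline_m": self.rig.baseline_m,
            "focal_mm": self.rig.focal_mm,
            "pixel_pitch_m": self.rig.pixel_pitch_m,
            "binning": self.rig.binning,
            "window": self.matcher.window_size,
            "range": self.matcher.disparity_range,
            "uniqueness": self.matcher.uniqueness,
            "n_classes": self.n_classes,
            "ground_override": self.ground_override,
            "mesh_bin_factor": self.mesh_bin_factor,
            "mesh_median_window": self.mesh_median_window,
            "max_edge_m": self.max_edge_m,
            "seed": self.seed,
        }
        return hashlib.sha256(yaml.safe_dump(rec, sort_keys=True).encode()).hexdigest()[:12]


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


@dataclass
class PairResult:
    traits: dict
    lad: Optional[pd.DataFrame]
    depth: cg.DepthMap
    mask: seg.SegmentationMask
    height: ha.HeightMap


def process_pair(pair: cg.ImagePair, cfg: PipelineConfig,
                 image_id: str = "pair") -> PairResult:
    """Run the full pipeline on one stereo pair."""
    t0 = time.perf_counter()
    rig = cfg.rig
    if not pair.rectified:
        pair = cg.rectify_pair(pair, rig)

    sat = seg.saturation_fraction(pair.left, pair.bit_depth)

    left_rgb = np.asarray(pair.left, dtype=float)
    gray_l = _to_gray(pair.left)
    gray_r = _to_gray(pair.right)
    if cfg.bin_images:
        gray_l, gray_r = cg.bin2x2(gray_l), cg.bin2x2(gray_r)
        if left_rgb.ndim == 3:
            left_rgb = cg.bin2x2(left_rgb)
        rig = rig.binned()
    gray_pair = cg.ImagePair(gray_l, gray_r, pair.bit_depth, rectified=True)

    mcfg = sm.auto_disparity_range(gray_pair, cfg.matcher)
    dmap_raw = sm.match_semiglobal(gray_pair, mcfg)
    dmap = sm.fill_disparity(dmap_raw) if cfg.fill_holes else dmap_raw
    depth = dmap.to_depth(rig)
    log.info("%s: matched %.1f%% of pixels in %.2fs", image_id,
             100 * dmap_raw.valid.mean(), time.perf_counter() - t0)

    # provisional heights for the 3-class height predictor; the additive
    # ground constant cancels inside the (p95 - h) feature
    prov_ground = float(np.nanpercentile(depth.values, 99)) if depth.valid.any() else 1.0
    prov_h = np.where(depth.valid, prov_ground - depth.values, np.nan)

    if cfg.model is not None:
        if left_rgb.ndim != 3:
            raise ValueError("segmentation requires RGB input")
        feats, names = seg.extract_features(
            left_rgb, height_map=prov_h if cfg.n_classes == 3 else None,
            bit_depth=pair.bit_depth,
            include_texture=cfg.n_classes == 3)
        mask = seg.classify_image(cfg.model, feats, names)
        mask = seg.median_filter_mask(mask)
    else:
        raise ValueError("no segmentation model configured")

    plant = mask.labels != seg.SOIL
    soil = mask.labels == seg.SOIL
    ground = ha.estimate_ground_depth(depth, soil, fallback=cfg.ground_override)
    hmap = ha.depth_to_height(depth, ground, plant_mask=plant)
    desc = ha.height_descriptors(hmap)
    # matching-quality indicator on raw matches, before any interpolation
    plaus = sm.plausible_height_fraction(dmap_raw, plant, rig, ground,
                                         cfg.min_clearance)

    spike_top = float("nan")
    n_spikes = 0
    if cfg.n_classes == 3:
        spike_top = ha.mean_spike_top_height(hmap, mask.mask_of(seg.SPIKE),
                                             min_size=cfg.spike_min_size)
        n_spikes = int(np.isfinite(spike_top))

    # LAI is computed over the stereo-overlap region only: the leftmost
    # columns (x < disparity) have no right-view correspondence, so they can
    # contribute neither mesh area nor, consistently, ground footprint
    overlap = np.zeros_like(plant)
    d_plant = dmap_raw.values[plant & dmap_raw.valid]
    d_lim = float(np.nanpercentile(d_plant, 99)) if d_plant.size else 0.0
    overlap[:, int(np.ceil(d_lim)):] = True

    # mesh traits on the conditioned plant depth map; interpolated cells are
    # occlusion guesses that drape phantom area across gaps, so by default the
    # mesh uses genuinely matched vertices only
    mesh_ok = plant & depth.valid & overlap
    if cfg.mesh_exclude_filled:
        mesh_ok &= ~depth.filled
    plant_depth = cg.DepthMap(np.where(mesh_ok, depth.values, np.nan),
                              mesh_ok, depth.filled & mesh_ok)
    mesh_depth, bf = mt.prepare_depth_for_mesh(plant_depth, cfg.mesh_bin_factor,
                                               cfg.mesh_median_window)
    mesh_rig = mt.scaled_rig_for_binning(rig, bf)
    lai_raw = float("nan")
    mta_delaunay = float("nan")
    n_faces = 0
    if mesh_depth.valid.sum() >= 3:
        cloud = mt.depth_map_to_point_cloud(mesh_depth, mesh_rig)
        try:
            mesh = mt.filter_giant_triangles(mt.build_mesh(cloud), cfg.max_edge_m)
            # median camera-wheat distance: robust to rim pixels mismatched to
            # the ground, which drag the mean toward deeper values
            zbar_wheat = float(np.nanmedian(depth.values[plant & depth.valid]))
            a_soil = cg.soil_area(zbar_wheat, rig, n_pixels=int(overlap.sum()))
            lai_raw = mt.compute_lai(mesh, a_soil)
            mta_delaunay = mt.compute_mta_delaunay(mesh)
            n_faces = mesh.n_faces
        except mt.MeshError:
            pass

    edges = lf.detect_leaf_edges(gray_l)
    rois = lf.sample_rois(hmap, edges, plant, rig, min_count=cfg.roi_min_count,
                          min_clearance=cfg.min_clearance)
    lad = lf.lad_histogram(rois)
    lad_df = None
    if lad.n_rois:
        lad_df = pd.DataFrame({
            "image_id": image_id,
            "bin_lo_deg": lad.bin_edges[:-1],
            "bin_hi_deg": lad.bin_edges[1:],
            "frequency": lad.frequencies,
        })

    lai_cal = float("nan")
    if cfg.calibration is not None and np.isfinite(lai_raw):
        lai_cal = float(predict(cfg.calibration, lai_raw))

    traits = {
        "image_id": image_id,
        "ground_depth_m": ground,
        "median_m": desc.median,
        "p75_m": desc.p75,
        "p95_m": desc.p95,
        "std_m": desc.std,
        "mean_spike_top_m": spike_top,
        "n_spike_objects": n_spikes,
        "lai_raw": lai_raw,
        "lai_calibrated": lai_cal,
        "mta_delaunay_deg": mta_delaunay,
        "mta_local_deg": lad.mean_tilt,
        "n_rois": lad.n_rois,
        "roi_size_px": rois[0].size if rois else 0,
        "n_faces": n_faces,
        "plausible_height_fraction": plaus,
        "saturation_fraction": sat,
        "config_hash": cfg.config_hash(),
    }
    return PairResult(traits, lad_df, depth, mask, hmap)


def run_pipeline(cfg: PipelineConfig, pairs: Sequence[tuple[str, cg.ImagePair]]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process several pairs; failures are logged and skipped.

    Returns (trait table, LAD table).  Raises if every pair fails.
    """
    rows, lads = [], []
    for image_id, pair in pairs:
        try:
            res = process_pair(pair, cfg, image_id)
        except Exception:
            log.exception("pipeline failed for %s; skipping", image_id)
            continue
        rows.append(res.traits)
        if res.lad is not None:
            lads.append(res.lad)
    if not rows:
        raise RuntimeError("all image pairs failed")
    traits = pd.DataFrame(rows)
    lad = pd.concat(lads, ignore_index=True) if lads else pd.DataFrame(
        columns=["image_id", "bin_lo_deg", "bin_hi_deg", "frequency"])
    return traits, lad


def repeatability_cv(values: Sequence[float], ddof: int = 0) -> float:
    """Coefficient of variation (sigma over mean) of repeated measurements.

    Used to quantify e.g. wind-induced variability across repeated captures
    of the same zone.  Population sigma by default.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(vals.std(ddof=ddof) / mean)
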