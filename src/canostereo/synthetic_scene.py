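"""Ground-truthed synthetic wheat canopy scenes rendered into stereo pairs.

The generator builds a scene from geometric primitives whose morphology is
known in closed form — a textured ground plane about a metre below the rig,
planar (optionally bowed) leaf patches of known area, tilt and azimuth, and
spikes modelled as steep grainy patches protruding above the foliage — and renders
it into the two pinhole views of a :class:`~canostereo.camera_geometry.StereoRig`
by exact ray casting.  Because the scene is analytic, true LAI, MTA, LAD,
height fields and depth maps are available exactly and never measured from
the renders.

Textures are deterministic functions of the 3-D surface coordinates (sums of
random-phase sinusoids for smooth surfaces, hashed cell noise for spike
grain), so the two views are photometrically consistent, which is what block
matchers require.  A "direct mode" (:meth:`SceneSpec.true_depth_left` plus
optional Gaussian depth noise) hands exact geometry to downstream modules
without going through rendering and matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .camera_geometry import DepthMap, ImagePair, StereoRig, soil_area

SOIL, LEAF, SPIKE = 0, 1, 2


# ---------------------------------------------------------------------------
# primitives


@dataclass
class LeafQuad:
    """Rectangular leaf patch of known area.

    ``tilt`` is the angle between the leaf surface and the horizontal plane,
    ``azimuth`` the compass direction of the uphill length axis.  ``curvature``
    bows the patch along its length by the given total turn angle (degrees);
    the length is arc length, so ``area = width * length`` exactly for any
    curvature.
    """

    center: np.ndarray
    width: float
    length: float
    tilt: float
    azimuth: float
    curvature: float = 0.0
    #: per-leaf brightness factor (leaves differ in age, chlorophyll and
    #: illumination, which is what makes leaf-on-leaf boundaries visible)
    color_scale: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not (0.0 <= self.tilt <= 90.0):
            raise ValueError("tilt must lie in [0, 90] degrees")
        if self.width <= 0 or self.length <= 0:
            raise ValueError("leaf dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.length

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(width axis, uphill length axis, unit normal) in camera coordinates.

        Camera z points down toward the ground, so a leaf whose physical
        normal points up has normal z-component -cos(tilt).
        """
        th = math.radians(self.tilt)
        az = math.radians(self.azimuth)
        e_w = np.array([-math.sin(az), math.cos(az), 0.0])
        e_l = np.array([math.cos(az) * math.cos(th), math.sin(az) * math.cos(th),
                        -math.sin(th)])
        n = np.cross(e_w, e_l)
        return e_w, e_l, n

    def strips(self, max_turn_deg: float = 10.0):
        """Decompose into planar strips (1 for a flat leaf).

        Yields (center, e_w, e_b, half_width, half_len, s_offset, tilt_deg)
        per strip, with s_offset the arc-length coordinate of the strip center
        (for texture continuity).
        """
        e_w, e_l, n = self.frame()
        if abs(self.curvature) < 1e-9:
            yield (self.center, e_w, e_l, self.width / 2, self.length / 2, 0.0, self.tilt)
            return
        n_strips = max(2, int(math.ceil(abs(self.curvature) / max_turn_deg)))
        c = math.radians(self.curvature)
        R = self.length / c
        for i in range(n_strips):
            s0 = -self.length / 2 + (i + 0.5) * self.length / n_strips
            phi = s0 * c / self.length
            # direction and position on the circular bow
            d = math.cos(phi) * e_l + math.sin(phi) * n
            pos = self.center + R * (math.sin(phi) * e_l + (1 - math.cos(phi)) * n)
            strip_n = np.cross(e_w, d)
            tilt = math.degrees(math.acos(min(1.0, abs(strip_n[2]))))
            yield (pos, e_w, d, self.width / 2, self.length / (2 * n_strips), s0, tilt)


@dataclass
class Spike:
    """Wheat ear stand-in: a steeply tilted, narrow, grain-textured patch.

    From a nadir camera an ear appears as an elongated blob with a height
    gradient running down from its tip; ``tip_depth`` is the camera distance
    of the uppermost end, so the true tip height is ``ground - tip_depth``.
    """

    center_xy: np.ndarray
    width: float = 0.012
    length: float = 0.07
    tilt: float = 65.0
    azimuth: float = 0.0
    tip_depth: float = 0.75

    def __post_init__(self):
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        if self.width <= 0 or self.length <= 0:
            raise ValueError("spike dimensions must be positive")
        if not (0.0 <= self.tilt <= 90.0):
            raise ValueError("spike tilt must lie in [0, 90] degrees")

    def as_quad(self) -> LeafQuad:
        """The underlying planar patch, positioned so its top end is the tip."""
        dz_half = (self.length / 2) * math.sin(math.radians(self.tilt))
        center = np.array([self.center_xy[0], self.center_xy[1],
                           self.tip_depth + dz_half])
        return LeafQuad(center=center, width=self.width, length=self.length,
                        tilt=self.tilt, azimuth=self.azimuth)


@dataclass
class SceneSpec:
    """Complete ground-truthed description of a synthetic canopy."""

    rig: StereoRig
    ground_depth: float = 1.05
    leaves: list[LeafQuad] = field(default_factory=list)
    spikes: list[Spike] = field(default_factory=list)
    depth_noise_sigma: float = 0.0
    saturation_fraction_target: float = 0.0
    #: leaf reflectance modulation: wheat blades are comparatively smooth, so
    #: their texture is weak next to leaf-boundary and soil contrast
    texture_contrast: float = 0.12
    ground_texture_contrast: float = 0.22
    spike_grain_contrast: float = 0.5
    seed: int = 0

    def __post_init__(self):
        depths = [l.center[2] for l in self.leaves] + [s.tip_depth for s in self.spikes]
        if any(z >= self.ground_depth for z in depths):
            raise ValueError("canopy elements must lie above the ground plane")

    # -- closed-form ground truth -------------------------------------------

    @property
    def mean_canopy_depth(self) -> float:
        """Area-weighted mean camera-wheat distance, or ground if bare.

        Each leaf's surface is symmetric about its center, so the closed-form
        area-weighted mean depth of the canopy surface is the area-weighted
        mean of the leaf center depths.
        """
        if not self.leaves:
            return self.ground_depth
        z = np.array([l.center[2] for l in self.leaves])
        a = np.array([l.area for l in self.leaves])
        return float(np.average(z, weights=a))

    @property
    def footprint_m2(self) -> float:
        return soil_area(self.mean_canopy_depth, self.rig)

    @property
    def total_leaf_area(self) -> float:
        return float(sum(l.area for l in self.leaves))

    @property
    def true_lai(self) -> float:
        return self.total_leaf_area / self.footprint_m2

    @property
    def true_mta(self) -> float:
        """Area-weighted mean tilt of the leaf surface elements (degrees)."""
        areas, tilts = self._strip_tilts()
        if len(tilts) == 0:
            return float("nan")
        return float(np.average(tilts, weights=areas))

    def _strip_tilts(self):
        areas, tilts = [], []
        for leaf in self.leaves:
            for (_, _, _, hw, hl, _, tilt) in leaf.strips():
                areas.append(4 * hw * hl)
                tilts.append(tilt)
        return np.asarray(areas), np.asarray(tilts)

    def true_lad(self, bin_width: float = 5.0) -> np.ndarray:
        """Area-weighted tilt histogram over [0, 90) in ``bin_width`` classes."""
        areas, tilts = self._strip_tilts()
        edges = np.arange(0.0, 90.0 + bin_width, bin_width)
        if len(tilts) == 0:
            return np.zeros(len(edges) - 1)
        hist, _ = np.histogram(np.clip(tilts, 0, 90 - 1e-9), bins=edges, weights=areas)
        return hist / hist.sum()

    @property
    def spike_tip_heights(self) -> np.ndarray:
        return np.array([self.ground_depth - s.tip_depth for s in self.spikes])

    # -- geometry ------------------------------------------------------------

    def _cast(self, origin_x: float):
        """Ray-cast one view.  Returns (z, label, object id, texture value)."""
        rig = self.rig
        h, w = rig.image_height_px, rig.image_width_px
        cx, cy = rig.center
        f = rig.focal_px
        uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        dx = (uu - cx) / f
        dy = (vv - cy) / f
        ox = origin_x

        # ground plane always hit: t = ground_depth (dz = 1)
        t_buf = np.full((h, w), self.ground_depth)
        label = np.full((h, w), SOIL, dtype=np.int16)
        obj = np.full((h, w), -1, dtype=np.int32)
        gx = ox + t_buf * dx
        gy = t_buf * dy
        tex = 1.0 + _smooth_noise(gx, gy, self.seed, -1,
                                  self.ground_texture_contrast, base_freq=30.0)

        oid = 0
        for leaf in self.leaves:
            for (pc, e_w, e_b, hw, hl, s_off, _tilt) in leaf.strips():
                n = np.cross(e_w, e_b)
                denom = n[0] * dx + n[1] * dy + n[2]
                rel = pc - np.array([ox, 0.0, 0.0])
                num = float(n @ rel)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = num / denom
                px = ox + t * dx - pc[0]
                py = t * dy - pc[1]
                pz = t - pc[2]
                a = px * e_w[0] + py * e_w[1] + pz * e_w[2]
                b = px * e_b[0] + py * e_b[1] + pz * e_b[2]
                inside = (np.abs(a) <= hw) & (np.abs(b) <= hl) & (t > 0.05) & (t < t_buf)
                if inside.any():
                    val = (1.0 + _smooth_noise(
                        a[inside], b[inside] + s_off, self.seed, oid,
                        self.texture_contrast, base_freq=60.0)) * leaf.color_scale
                    t_buf[inside] = t[inside]
                    label[inside] = LEAF
                    obj[inside] = oid
                    tex[inside] = val
            oid += 1

        for spike in self.spikes:
            quad = spike.as_quad()
            for (pc, e_w, e_b, hw, hl, s_off, _tilt) in quad.strips():
                n = np.cross(e_w, e_b)
                denom = n[0] * dx + n[1] * dy + n[2]
                rel = pc - np.array([ox, 0.0, 0.0])
                num = float(n @ rel)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = num / denom
                px = ox + t * dx - pc[0]
                py = t * dy - pc[1]
                pz = t - pc[2]
                a = px * e_w[0] + py * e_w[1] + pz * e_w[2]
                b = px * e_b[0] + py * e_b[1] + pz * e_b[2]
                inside = (np.abs(a) <= hw) & (np.abs(b) <= hl) & (t > 0.05) & (t < t_buf)
                if inside.any():
                    tex[inside] = 1.0 + _grain_noise(
                        a[inside], b[inside] + s_off, self.seed, oid,
                        self.spike_grain_contrast)
                    t_buf[inside] = t[inside]
                    label[inside] = SPIKE
                    obj[inside] = oid
            oid += 1

        return t_buf, label, obj, tex

    def true_depth_left(self) -> tuple[DepthMap, np.ndarray]:
        """Exact left-view depth map and class labels (direct mode)."""
        z, label, _, _ = self._cast(0.0)
        return DepthMap(z, np.ones_like(z, dtype=bool)), label

    def noisy_depth_left(self, rng: Optional[np.random.Generator] = None
                         ) -> tuple[DepthMap, np.ndarray]:
        """Direct mode with additive Gaussian depth noise of scene sigma."""
        dmap, label = self.true_depth_left()
        if self.depth_noise_sigma > 0:
            if rng is None:
                rng = np.random.default_rng(self.seed + 1)
            vals = dmap.values + rng.normal(0.0, self.depth_noise_sigma, dmap.values.shape)
            dmap = DepthMap(np.maximum(vals, 1e-6), dmap.valid)
        return dmap, label


# ---------------------------------------------------------------------------
# textures


def _rng_for(seed: int, obj_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(obj_id + 2,)))


def _smooth_noise(a, b, seed, obj_id, contrast, base_freq=60.0, n_waves=10):
    """Band-limited texture: random-phase sinusoid sum on surface coords (m).

    The band is capped a few pixels above the render sampling rate so the two
    views stay photometrically consistent (real optics band-limit the image;
    aliased texture would make surfaces unmatchable for no physical reason).
    """
    rng = _rng_for(seed, obj_id)
    freqs = base_freq * np.exp(rng.uniform(0.0, 1.2, n_waves))
    angs = rng.uniform(0, 2 * np.pi, n_waves)
    phases = rng.uniform(0, 2 * np.pi, n_waves)
    amps = rng.uniform(0.5, 1.0, n_waves)
    out = np.zeros_like(np.asarray(a, dtype=float))
    for fq, an, ph, am in zip(freqs, angs, phases, amps):
        out += am * np.sin(2 * np.pi * fq * (a * np.cos(an) + b * np.sin(an)) + ph)
    return contrast * out / np.sum(np.abs(amps) ** 2) ** 0.5


def _grain_noise(a, b, seed, obj_id, contrast, cell=0.004):
    """Speckle texture: hashed integer cells of ``cell`` metres on a surface.

    Cells span a few rendered pixels so both views sample the same pattern;
    finer grain would alias and decorrelate the views.
    """
    ia = np.floor(np.asarray(a) / cell).astype(np.int64)
    ib = np.floor(np.asarray(b) / cell).astype(np.int64)
    h = ia * 73856093 ^ ib * 19349663 ^ np.int64((obj_id + 1) * 83492791 + seed * 2654435761)
    h = (h ^ (h >> 13)) * np.int64(0x5BD1E995)
    h = h ^ (h >> 15)
    return contrast * ((h & 0xFFFF).astype(float) / 32767.5 - 1.0)


# ---------------------------------------------------------------------------
# rendering


_CLASS_COLORS = {
    SOIL: np.array([950.0, 680.0, 470.0]),       # shaded loam brown, 12-bit scale
    LEAF: np.array([760.0, 1650.0, 640.0]),      # wheat green
    SPIKE: np.array([900.0, 1700.0, 700.0]),     # green ear, close to leaf
}


def render_views(scene: SceneSpec) -> tuple[ImagePair, DepthMap, np.ndarray]:
    """Render left/right 12-bit RGB views plus exact left depth and labels.

    The cameras share orientation; the right camera sits at +baseline along x,
    so corresponding points land on identical rows (exact epipolar geometry)
    and the left-image disparity is ``f * b / z``.
    """
    rig = scene.rig
    views = []
    depth_left = None
    label_left = None
    for origin_x in (0.0, rig.baseline_m):
        z, label, obj, tex = scene._cast(origin_x)
        img = np.zeros(z.shape + (3,), dtype=float)
        for cls, col in _CLASS_COLORS.items():
            m = label == cls
            if m.any():
                img[m] = col[None, :] * tex[m, None]
        if scene.saturation_fraction_target > 0:
            img = _add_saturation(img, label, tex, scene.saturation_fraction_target)
        img = np.clip(img, 0, 4095).astype(np.uint16)
        views.append(img)
        if origin_x == 0.0:
            depth_left = DepthMap(z, np.ones_like(z, dtype=bool))
            label_left = label
    pair = ImagePair(views[0], views[1], bit_depth=12, rectified=True)
    return pair, depth_left, label_left


def _add_saturation(img, label, tex, target):
    """Blow out the brightest textured vegetation until ~target fraction saturates.

    The glint is a function of the surface texture value, so it is consistent
    between the two views (a crude stand-in for specular sunlight).
    """
    veg = label != SOIL
    if not veg.any():
        return img
    thresh = np.quantile(tex[veg], max(0.0, 1.0 - target / max(veg.mean(), 1e-9)))
    glint = veg & (tex >= thresh)
    img[glint] = 4095.0
    return img


def quantize_depth(dmap: DepthMap, step: float) -> DepthMap:
    """Round depths to integer multiples of ``step`` (stair-step regime)."""
    if step <= 0:
        raise ValueError("quantization step must be positive")
    vals = np.round(dmap.values / step) * step
    return DepthMap(np.where(dmap.valid, vals, np.nan), dmap.valid.copy(),
                    dmap.filled.copy())


# ---------------------------------------------------------------------------
# scene generation


#: Quarter-scale simulation sensor: same 50 mm baseline and 16 mm lens as the
#: field rig, 20 um effective pixels on 640 x 512 — disparity ~40 px at 1 m.
SIM_RIG = StereoRig(baseline_m=0.05, focal_mm=16.0, pixel_pitch_m=2e-5,
                    image_width_px=640, image_height_px=512)


def generate_scene(
    n_leaves: int = 40,
    leaf_width: tuple[float, float] = (0.012, 0.02),
    leaf_length: tuple[float, float] = (0.05, 0.09),
    tilt_range: tuple[float, float] = (10.0, 70.0),
    depth_band: tuple[float, float] = (0.78, 0.98),
    ground_depth: float = 1.05,
    rig: StereoRig = SIM_RIG,
    n_spikes: int = 0,
    spike_tip_depth: tuple[float, float] = (0.7, 0.8),
    curvature: float = 0.0,
    allow_overlap: bool = False,
    depth_noise_sigma: float = 0.0,
    saturation_fraction_target: float = 0.0,
    seed: int = 0,
    max_attempts: int = 4000,
) -> SceneSpec:
    """Place leaves (and optionally spikes) into a ground-truthed scene.

    Leaves are dropped uniformly over the visible footprint with uniform
    azimuth and tilts drawn uniformly from ``tilt_range``.  Unless
    ``allow_overlap`` is set, nadir projections are kept disjoint by enforcing
    a circumradius separation between leaf centers; if the requested density
    cannot be placed within ``max_attempts`` draws, a ValueError is raised.
    """
    rng = np.random.default_rng(seed)
    zc = float(np.mean(depth_band))
    half_x = 0.5 * (rig.image_width_px - 10) * zc / rig.focal_px
    half_y = 0.5 * (rig.image_height_px - 10) * zc / rig.focal_px

    leaves: list[LeafQuad] = []
    radii: list[float] = []
    centers: list[np.ndarray] = []
    attempts = 0
    while len(leaves) < n_leaves:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n_leaves} non-overlapping leaves in "
                f"{max_attempts} attempts; lower the density or allow overlap")
        attempts += 1
        w = rng.uniform(*leaf_width)
        ln = rng.uniform(*leaf_length)
        tilt = rng.uniform(*tilt_range)
        az = rng.uniform(0.0, 360.0)
        r = math.hypot(ln / 2, w / 2)
        margin = r + 0.01
        cx = rng.uniform(-half_x + margin, half_x - margin)
        cy = rng.uniform(-half_y + margin, half_y - margin)
        # keep the whole tilted patch above the ground and below the rig
        dz_half = (ln / 2) * math.sin(math.radians(tilt))
        cz = rng.uniform(depth_band[0] + dz_half, depth_band[1] - dz_half) \
            if depth_band[1] - dz_half > depth_band[0] + dz_half else zc
        c = np.array([cx, cy, cz])
        if not allow_overlap:
            ok = all(np.hypot(*(c[:2] - pc[:2])) > r + pr
                     for pc, pr in zip(centers, radii))
            if not ok:
                continue
        leaves.append(LeafQuad(center=c, width=w, length=ln, tilt=tilt,
                               azimuth=az, curvature=curvature,
                               color_scale=rng.uniform(0.85, 1.15)))
        centers.append(c)
        radii.append(r)

    spikes: list[Spike] = []
    for _ in range(n_spikes):
        for _try in range(200):
            sx = rng.uniform(-half_x * 0.8, half_x * 0.8)
            sy = rng.uniform(-half_y * 0.8, half_y * 0.8)
            if all(np.hypot(sx - s.center_xy[0], sy - s.center_xy[1]) > 0.05
                   for s in spikes):
                break
        spikes.append(Spike(center_xy=np.array([sx, sy]),
                            width=rng.uniform(0.011, 0.016),
                            length=rng.uniform(0.06, 0.09),
                            tilt=rng.uniform(55.0, 70.0),
                            azimuth=rng.uniform(0.0, 360.0),
                            tip_depth=rng.uniform(*spike_tip_depth)))

    return SceneSpec(rig=rig, ground_depth=ground_depth, leaves=leaves,
                     spikes=spikes, depth_noise_sigma=depth_noise_sigma,
                     saturation_fraction_target=saturation_fraction_target,
                     seed=seed)


def preset_scene(name: str, seed: int = 0, rig: StereoRig = SIM_RIG) -> SceneSpec:
    """Named study conditions used throughout the tests and examples."""
    if name == "flat-target":
        leaf = LeafQuad(center=np.array([0.0, 0.0, 0.9]), width=0.24, length=0.2,
                        tilt=0.0, azimuth=0.0)
        return SceneSpec(rig=rig, ground_depth=1.05, leaves=[leaf], seed=seed)
    if name == "tilted-target":
        leaf = LeafQuad(center=np.array([0.0, 0.0, 0.9]), width=0.22, length=0.18,
                        tilt=30.0, azimuth=0.0)
        return SceneSpec(rig=rig, ground_depth=1.05, leaves=[leaf], seed=seed)
    if name == "sparse-canopy":
        return generate_scene(n_leaves=26, tilt_range=(5.0, 45.0), seed=seed, rig=rig)
    if name == "dense-canopy":
        return generate_scene(n_leaves=110, tilt_range=(15.0, 70.0), seed=seed,
                              rig=rig, allow_overlap=True,
                              depth_band=(0.6, 0.98))
    if name == "spiked-canopy":
        # flowering-stage canopy: dense overlapping foliage with ears on top
        return generate_scene(n_leaves=90, tilt_range=(20.0, 60.0), n_spikes=12,
                              depth_band=(0.82, 1.0), allow_overlap=True,
                              spike_tip_depth=(0.66, 0.74), seed=seed, rig=rig)
    raise ValueError(f"unknown preset {name!r}")


def training_set_from_render(rgb: np.ndarray, labels: np.ndarray,
                             n: int = 10000, seed: int = 0,
                             height_map: Optional[np.ndarray] = None,
                             bit_depth: int = 12):
    """Labelled pixel samples drawn from a rendered scene and its true mask.

    Stratified uniformly over the classes present; features follow
    :func:`canostereo.segmentation.extract_features` (color only in 2-class
    mode, plus texture and the height predictor when ``height_map`` is given).
    """
    from .segmentation import TrainingSet, extract_features

    feats, names = extract_features(rgb, height_map=height_map,
                                    bit_depth=bit_depth,
                                    include_texture=height_map is not None)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    per = n // len(classes)
    rows, ys = [], []
    flat_feats = feats.reshape(-1, feats.shape[-1])
    flat_labels = np.asarray(labels).ravel()
    for cls in classes:
        idx = np.nonzero(flat_labels == cls)[0]
        take = rng.choice(idx, size=min(per, len(idx)), replace=False)
        rows.append(flat_feats[take])
        ys.append(flat_labels[take])
    X = np.vstack(rows)
    y = np.concatenate(ys)
    perm = rng.permutation(len(y))
    return TrainingSet(features=X[perm], labels=y[perm], feature_names=names,
                       seed=seed)


# ---------------------------------------------------------------------------
# pixel-level training fixture for the segmentation classifier


def make_pixel_training_set(n: int = 5000, n_classes: int = 3, seed: int = 0,
                            matched_spike_color: bool = True,
                            include_height: bool = True):
    """Synthetic labelled pixel samples mimicking field class statistics.

    Soil is brown and lies at the ground; leaves are green, smooth-textured
    and spread through the canopy; spikes are grainy and sit at the very top.
    With ``matched_spike_color`` the spike color distribution equals the leaf
    one, so only texture and the height-below-p95 predictor can separate them
    — the regime that motivates the 3-class feature set.

    Returns a :class:`canostereo.segmentation.TrainingSet` on the normalized
    [0, 1] intensity scale.
    """
    from .segmentation import TrainingSet, FEATURE_NAMES_COLOR

    rng = np.random.default_rng(seed)
    per = n // n_classes
    counts = [per, per, n - 2 * per][:n_classes]
    rows, labels = [], []

    def hsv_block(h, s, v, m):
        hh = np.clip(rng.normal(h, 0.03, m) % 1.0, 0, 1)
        ss = np.clip(rng.normal(s, 0.12, m), 0.05, 1)
        vv = np.clip(rng.normal(v, 0.14, m), 0.03, 1)
        import colorsys
        rgb = np.array([colorsys.hsv_to_rgb(a, b, c) for a, b, c in zip(hh, ss, vv)])
        return rgb, np.column_stack([hh, ss, vv])

    # spike grain is coarser than leaf texture but the distributions overlap:
    # texture alone cannot separate color-matched spikes from leaves, which is
    # precisely why the height predictor matters
    specs = {
        SOIL: dict(h=0.08, s=0.45, v=0.40, tex_sq=(2e-4, 1e-3), height=(0.55, 0.08)),
        LEAF: dict(h=0.30, s=0.60, v=0.45, tex_sq=(1e-4, 1.2e-3), height=(0.25, 0.12)),
        SPIKE: dict(h=0.30 if matched_spike_color else 0.22, s=0.60, v=0.45,
                    tex_sq=(5e-4, 2.5e-3), height=(0.03, 0.03)),
    }
    for cls, m in zip((SOIL, LEAF, SPIKE), counts):
        sp = specs[cls]
        rgb, hsv = hsv_block(sp["h"], sp["s"], sp["v"], m)
        tex_mean = np.clip(hsv[:, 2] + rng.normal(0, 0.02, m), 0, 1)
        lo, hi = sp["tex_sq"]
        tex_sq = rng.uniform(lo, hi, m)
        mu, sd = sp["height"]
        height = np.clip(rng.normal(mu, sd, m), 0.0, 0.9)
        cols = [rgb[:, 0], rgb[:, 1], rgb[:, 2], hsv[:, 0], hsv[:, 1], hsv[:, 2]]
        names = list(FEATURE_NAMES_COLOR)
        if n_classes == 3:
            cols += [tex_mean, tex_sq]
            names += ["tex_mean", "tex_sqdiff"]
            if include_height:
                cols.append(height)
                names.append("height_pred")
        rows.append(np.column_stack(cols))
        labels.append(np.full(m, cls))

    X = np.vstack(rows)
    y = np.concatenate(labels)
    perm = rng.permutation(len(y))
    return TrainingSet(features=X[perm], labels=y[perm], feature_names=names,
                       seed=seed)
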