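"""Stereo rig model, rectification, pixel binning and the depth/area formulas.

The rig is a pair of identical pinhole cameras with parallel optical axes,
looking straight down (nadir) at a wheat canopy from roughly one metre.  The
left camera is the reference frame for all 3-D coordinates: x rightward
(columns), y downward (rows), z along the optical axis toward the ground.
Depth follows the classical triangulation relation ``Z = b f / d`` with the
baseline *b* in metres, the focal length *f* in pixels and the disparity *d*
in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation


class ConfigurationError(ValueError):
    """Raised for missing or degenerate rig/calibration parameters."""


@dataclass(frozen=True)
class RectificationParams:
    """Extrinsics of the right camera relative to the left, plus distortion.

    ``rotation`` and ``translation`` map left-camera coordinates to
    right-camera coordinates, ``X_r = R @ X_l + t``.  ``distortion`` holds
    radial coefficients (k1, k2) shared by both cameras.
    """

    rotation: np.ndarray
    translation: np.ndarray
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ConfigurationError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ConfigurationError("rotation matrix is not orthonormal")
        if t.shape != (3,) or np.linalg.norm(t) == 0:
            raise ConfigurationError("translation must be a nonzero 3-vector")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "distortion", np.asarray(self.distortion, dtype=float))

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rotation, np.eye(3), atol=1e-12)
            and np.allclose(self.distortion, 0.0)
            and abs(self.translation[1]) < 1e-12
            and abs(self.translation[2]) < 1e-12
        )


@dataclass(frozen=True)
class StereoRig:
    """Geometry of the stereo device.

    Parameters mirror the physical build: 50 mm baseline, 16 mm objectives,
    5 µm sensor pixels on a 2560 x 2048 CMOS.  ``binning`` is the software
    binning factor already applied to the images this rig describes (2 after
    one 2x2 binning pass); the effective pixel pitch is
    ``pixel_pitch_m * binning`` and the focal length in pixels follows.
    """

    baseline_m: float = 0.05
    focal_mm: float = 16.0
    pixel_pitch_m: float = 5e-6
    image_width_px: int = 2560
    image_height_px: int = 2048
    binning: int = 1
    principal_point: Optional[tuple[float, float]] = None
    rectification: Optional[RectificationParams] = None

    def __post_init__(self):
        if self.baseline_m <= 0 or self.focal_mm <= 0 or self.pixel_pitch_m <= 0:
            raise ConfigurationError("baseline, focal length and pixel pitch must be positive")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")

    @property
    def focal_m(self) -> float:
        return self.focal_mm * 1e-3

    @property
    def effective_pitch_m(self) -> float:
        return self.pixel_pitch_m * self.binning

    @property
    def focal_px(self) -> float:
        return self.focal_m / self.effective_pitch_m

    @property
    def center(self) -> tuple[float, float]:
        if self.principal_point is not None:
            return self.principal_point
        return ((self.image_width_px - 1) / 2.0, (self.image_height_px - 1) / 2.0)

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        cx, cy = self.center
        f = self.focal_px
        return np.array([[f, 0.0, cx], [0.0, f, cy], [0.0, 0.0, 1.0]])

    def binned(self) -> "StereoRig":
        """Rig describing images after one further 2x2 binning pass."""
        if self.image_width_px % 2 or self.image_height_px % 2:
            raise ConfigurationError("cannot bin a rig with odd image dimensions")
        pp = None
        if self.principal_point is not None:
            pp = ((self.principal_point[0] - 0.5) / 2.0, (self.principal_point[1] - 0.5) / 2.0)
        return replace(
            self,
            image_width_px=self.image_width_px // 2,
            image_height_px=self.image_height_px // 2,
            binning=self.binning * 2,
            principal_point=pp,
        )


#: The rig as built: 50 mm baseline, 16 mm lenses, 5 um pixels, 2560 x 2048.
FULL_RIG = StereoRig()
#: Same sensor after the 2x2 binning used for all field processing.
BINNED_RIG = FULL_RIG.binned()


@dataclass
class ImagePair:
    left: np.ndarray
    right: np.ndarray
    bit_depth: int = 8
    rectified: bool = False

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("left and right images must have identical dimensions")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class DepthMap:
    """Per-pixel camera-object distance in metres.

    Invalid cells carry NaN in ``values`` and False in ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    filled: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid rasters must share a shape")
        if self.filled is None:
            self.filled = np.zeros_like(self.valid)
        bad = self.valid & ~(self.values > 0)
        if bad.any():
            raise ValueError("valid depth cells must be strictly positive")
        self.values = np.where(self.valid, self.values, np.nan)

    def copy(self) -> "DepthMap":
        return DepthMap(self.values.copy(), self.valid.copy(), self.filled.copy())


# ---------------------------------------------------------------------------
# depth formulas


def disparity_to_depth(d, rig: StereoRig):
    """Depth Z = b f / d in metres; nonpositive disparities map to NaN.

    Works element-wise on arrays and on scalars.
    """
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(d > 0, rig.baseline_m * rig.focal_px / d, np.nan)
    if z.ndim == 0:
        return float(z)
    return z


def depth_to_disparity(z, rig: StereoRig):
    """Inverse of :func:`disparity_to_depth`; nonpositive depths map to NaN."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(z > 0, rig.baseline_m * rig.focal_px / z, np.nan)
    if d.ndim == 0:
        return float(d)
    return d


def depth_resolution(z, rig: StereoRig):
    """Depth difference between two consecutive disparities at depth ``z``.

    This is the smallest depth increment the rig can represent at that range:
    ``|Z(d-1) - Z(d)|`` evaluated at the (real-valued) disparity matching
    ``z``.  It grows roughly as Z^2/(b f) and doubles under 2x2 binning.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("depth must be positive")
    bf = rig.baseline_m * rig.focal_px
    d = bf / z
    if np.any(d <= 1):
        raise ValueError("depth beyond the rig's single-disparity range")
    res = bf / (d - 1) - z
    if res.ndim == 0:
        return float(res)
    return res


def soil_area(mean_depth: float, rig: StereoRig, n_pixels: Optional[int] = None) -> float:
    """Ground footprint of the image at the mean camera-canopy distance (m^2).

    A_soil = (Z_bar * P_S / f_m)^2 * A_image, with P_S the effective pixel
    side on the sensor and A_image the pixel count.  Invariant to binning: the
    pitch doubles while the pixel count quarters.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if n_pixels is None:
        n_pixels = rig.image_width_px * rig.image_height_px
    side = mean_depth * rig.effective_pitch_m / rig.focal_m
    return side * side * n_pixels


def lateral_pixel_size(z, rig: StereoRig):
    """Ground distance represented by one pixel side at depth ``z`` (m)."""
    return np.asarray(z, dtype=float) * rig.effective_pitch_m / rig.focal_m


# ---------------------------------------------------------------------------
# binning


def bin2x2(image: np.ndarray) -> np.ndarray:
    """Average each 2x2 block, halving both image dimensions.

    Accepts (H, W) or (H, W, C) rasters; returns float64.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h % 2 or w % 2:
        raise ValueError("both image dimensions must be even for 2x2 binning")
    out = image.reshape(h // 2, 2, w // 2, 2, *image.shape[2:]).astype(np.float64)
    return out.mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# rectification


def _project(K: np.ndarray, X: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Project camera-frame points (N, 3) to pixel coordinates (N, 2)."""
    x = X[:, 0] / X[:, 2]
    y = X[:, 1] / X[:, 2]
    if dist is not None and np.any(dist != 0):
        r2 = x * x + y * y
        k1, k2 = dist[0], dist[1] if len(dist) > 1 else 0.0
        scale = 1.0 + k1 * r2 + k2 * r2 * r2
        x, y = x * scale, y * scale
    u = K[0, 0] * x + K[0, 2]
    v = K[1, 1] * y + K[1, 2]
    return np.column_stack([u, v])


def rectifying_rotations(rig: StereoRig) -> tuple[np.ndarray, np.ndarray]:
    """Rotations applied to (left, right) camera frames to rectify the rig.

    Splits the relative rotation evenly between the cameras and then aligns
    the new common x-axis with the baseline so epipolar lines become image
    rows (Bouguet's construction).
    """
    if rig.rectification is None:
        raise ConfigurationError("rig has no rectification parameters")
    R = rig.rectification.rotation
    t = rig.rectification.translation
    rvec = Rotation.from_matrix(R).as_rotvec()
    A = Rotation.from_rotvec(rvec / 2.0).as_matrix()       # applied to left
    B = Rotation.from_rotvec(-rvec / 2.0).as_matrix()      # applied to right
    t_new = B @ t
    e1 = t_new / np.linalg.norm(t_new)
    if e1[0] < 0:  # new x-axis points rightward in image coordinates
        e1 = -e1
    e2 = np.array([-e1[1], e1[0], 0.0])
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        raise ConfigurationError("degenerate baseline: parallel to optical axis")
    e2 /= n2
    e3 = np.cross(e1, e2)
    R_align = np.vstack([e1, e2, e3])
    return R_align @ A, R_align @ B


def project_rectified(rig: StereoRig, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of 3-D points (left-camera frame) in both rectified views.

    Useful as an oracle: corresponding rows must agree after rectification.
    """
    Rl, Rr = rectifying_rotations(rig)
    K = rig.intrinsic_matrix
    P = np.atleast_2d(np.asarray(points, dtype=float))
    params = rig.rectification
    Xl = P @ Rl.T
    Xr = (P @ params.rotation.T + params.translation) @ Rr.T
    return _project(K, Xl, None), _project(K, Xr, None)


def _warp_to_rectified(image: np.ndarray, K: np.ndarray, R_cam: np.ndarray,
                       dist: np.ndarray) -> np.ndarray:
    """Resample ``image`` so it appears taken by the rotated, undistorted camera."""
    h, w = image.shape[:2]
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    rays = np.stack([(uu - K[0, 2]) / K[0, 0], (vv - K[1, 2]) / K[1, 1],
                     np.ones_like(uu)], axis=-1)
    src = rays.reshape(-1, 3) @ R_cam  # R_cam.T applied row-wise
    px = _project(K, src, dist).reshape(h, w, 2)
    coords = np.stack([px[..., 1], px[..., 0]])  # (row, col) for map_coordinates
    if image.ndim == 2:
        return map_coordinates(image.astype(float), coords, order=1, mode="nearest")
    out = [map_coordinates(image[..., c].astype(float), coords, order=1, mode="nearest")
           for c in range(image.shape[2])]
    return np.stack(out, axis=-1)


def rectify_pair(pair: ImagePair, rig: StereoRig) -> ImagePair:
    """Align the pair so scene points share the same row in both images.

    Consumes precomputed calibration (rotation, translation, radial
    distortion).  An already-ideal rig (identity rotation, baseline along x,
    no distortion) passes images through untouched.
    """
    if pair.rectified:
        raise ValueError("pair is already rectified")
    if rig.rectification is None:
        raise ConfigurationError("rig has no rectification parameters")
    if rig.rectification.is_identity:
        return ImagePair(pair.left, pair.right, pair.bit_depth, rectified=True)
    Rl, Rr = rectifying_rotations(rig)
    K = rig.intrinsic_matrix
    dist = rig.rectification.distortion
    left = _warp_to_rectified(pair.left, K, Rl, dist)
    right = _warp_to_rectified(pair.right, K, Rr, dist)
    return ImagePair(left, right, pair.bit_depth, rectified=True)


# ---------------------------------------------------------------------------
# calibration record I/O


def save_rig(rig: StereoRig, path) -> None:
    rec = {
        "baseline_m": rig.baseline_m,
        "focal_mm": rig.focal_mm,
        "pixel_pitch_m": rig.pixel_pitch_m,
        "image_width_px": rig.image_width_px,
        "image_height_px": rig.image_height_px,
        "binning": rig.binning,
    }
    if rig.principal_point is not None:
        rec["principal_point"] = list(rig.principal_point)
    if rig.rectification is not None:
        rec["rotation"] = rig.rectification.rotation.tolist()
        rec["translation"] = rig.rectification.translation.tolist()
        rec["distortion"] = rig.rectification.distortion.tolist()
    with open(path, "w") as fh:
        yaml.safe_dump(rec, fh, sort_keys=False)


def load_rig(path) -> StereoRig:
    with open(path) as fh:
        rec = yaml.safe_load(fh)
    if not isinstance(rec, dict):
        raise ConfigurationError(f"not a calibration record: {path}")
    rect = None
    if "rotation" in rec:
        rect = RectificationParams(
            rotation=np.asarray(rec["rotation"], dtype=float),
            translation=np.asarray(rec["translation"], dtype=float),
            distortion=np.asarray(rec.get("distortion", [0.0, 0.0]), dtype=float),
        )
    pp = rec.get("principal_point")
    return StereoRig(
        baseline_m=float(rec["baseline_m"]),
        focal_mm=float(rec["focal_mm"]),
        pixel_pitch_m=float(rec["pixel_pitch_m"]),
        image_width_px=int(rec["image_width_px"]),
        image_height_px=int(rec["image_height_px"]),
        binning=int(rec.get("binning", 1)),
        principal_point=tuple(pp) if pp is not None else None,
        rectification=rect,
    )
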