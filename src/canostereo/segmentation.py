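"""Pixel classification of canopy images into soil / leaf / spike.

Two-class mode (before ear emergence) uses only the RGB and HSV components of
each pixel; three-class mode adds two 7x7 texture statistics — the local mean
intensity and the mean squared difference to the central pixel, separating the
grainy ears from smooth leaf blades — and a height predictor, the distance of
the pixel below the 95th height percentile of the scene, which is invariant
to the camera-ground distance.  Binary SVMs with an RBF kernel are combined
one-vs-one under the error-correcting output codes (ECOC) principle with
minimum-code-distance decoding.  A 5x5 median (binary) or plurality
(three-class) filter removes speckle from the resulting masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter, uniform_filter
from skimage.color import rgb2hsv
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SOIL, LEAF, SPIKE = 0, 1, 2
CLASS_NAMES = {SOIL: "soil", LEAF: "leaf", SPIKE: "spike"}
#: Figure-style mask palette: soil blue, leaves green, spikes red.
CLASS_COLORS = {SOIL: (40, 90, 220), LEAF: (50, 190, 60), SPIKE: (220, 50, 40)}

FEATURE_NAMES_COLOR = ("r", "g", "b", "h", "s", "v")
FEATURE_NAMES_TEXTURE = ("tex_mean", "tex_sqdiff")
FEATURE_NAME_HEIGHT = "height_pred"


@dataclass
class TrainingSet:
    """Labelled pixel samples with a seeded 70/30 train/validation split."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: Sequence[str]
    seed: int = 0
    train_fraction: float = 0.70

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the feature columns")

    def split(self):
        """Stratified 70/30 partition; every class lands in both halves."""
        return train_test_split(
            self.features, self.labels,
            train_size=self.train_fraction,
            random_state=self.seed,
            stratify=self.labels,
        )


@dataclass
class SegmentationMask:
    labels: np.ndarray
    n_classes: int = 2

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.n_classes == 2 and np.any(self.labels == SPIKE):
            raise ValueError("spike label present in a 2-class mask")

    def mask_of(self, cls: int) -> np.ndarray:
        return self.labels == cls

    def to_rgb(self) -> np.ndarray:
        out = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for cls, col in CLASS_COLORS.items():
            out[self.labels == cls] = col
        return out


@dataclass
class ClassifierModel:
    """One binary SVM (2-class) or three pairwise SVMs with ECOC decoding."""

    scaler: StandardScaler
    learners: list
    code_matrix: np.ndarray          # (n_classes, n_learners) in {-1, 0, +1}
    classes: np.ndarray
    feature_names: Sequence[str]
    validation_accuracy: float = float("nan")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Predicted class per row by minimum code distance."""
        Xs = self.scaler.transform(X)
        votes = np.column_stack([np.sign(svm.decision_function(Xs))
                                 for svm in self.learners])
        votes[votes == 0] = 1.0
        # Hamming-style distance; a zero code entry contributes 1/2 either way
        dist = np.stack([np.sum(np.abs(code[None, :] - votes) / 2.0 *
                                np.where(code[None, :] == 0, 0.5, 1.0), axis=1)
                         for code in self.code_matrix], axis=1)
        return self.classes[np.argmin(dist, axis=1)]


# ---------------------------------------------------------------------------
# features


def extract_features(rgb: np.ndarray, height_map: Optional[np.ndarray] = None,
                     bit_depth: int = 12, include_texture: Optional[bool] = None,
                     window: int = 7) -> tuple[np.ndarray, list[str]]:
    """Per-pixel feature raster (H, W, F) on the normalized [0, 1] scale.

    Color features are always present (r, g, b, h, s, v).  Texture features —
    the window mean intensity and the mean squared difference to the central
    pixel, reflect-padded at the borders — default to on exactly when a height
    map is supplied (3-class mode); the height predictor is the 95th height
    percentile minus the pixel height, in metres.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) color raster")
    if include_texture is None:
        include_texture = height_map is not None
    maxv = (1 << bit_depth) - 1
    norm = np.clip(rgb / maxv, 0.0, 1.0)
    hsv = rgb2hsv(norm)
    feats = [norm[..., 0], norm[..., 1], norm[..., 2],
             hsv[..., 0], hsv[..., 1], hsv[..., 2]]
    names = list(FEATURE_NAMES_COLOR)
    if include_texture:
        gray = 0.299 * norm[..., 0] + 0.587 * norm[..., 1] + 0.114 * norm[..., 2]
        mean = uniform_filter(gray, size=window, mode="reflect")
        mean_sq = uniform_filter(gray * gray, size=window, mode="reflect")
        # E[(I_n - I_c)^2] over the window = E[I_n^2] - 2 I_c E[I_n] + I_c^2
        sqdiff = np.maximum(mean_sq - 2 * gray * mean + gray * gray, 0.0)
        feats += [mean, sqdiff]
        names += list(FEATURE_NAMES_TEXTURE)
    if height_map is not None:
        h = np.asarray(height_map, dtype=float)
        ref = np.nanpercentile(h, 95)
        feats.append(np.nan_to_num(ref - h, nan=ref))
        names.append(FEATURE_NAME_HEIGHT)
    return np.stack(feats, axis=-1), names


# ---------------------------------------------------------------------------
# training and prediction


def train_classifier(ts: TrainingSet, n_classes: int = 2,
                     C: float = 10.0, gamma: str | float = "scale") -> ClassifierModel:
    """Fit the SVM classifier and report held-out validation accuracy.

    For three classes, three pairwise binary learners are fitted (soil/leaf,
    soil/spike, leaf/spike) and decoded by minimum code distance; features are
    standardized with training-partition statistics only.
    """
    classes = np.unique(ts.labels)
    if len(classes) != n_classes:
        raise ValueError(
            f"training set has classes {classes.tolist()}, expected {n_classes}")
    Xtr, Xval, ytr, yval = ts.split()
    for cls in classes:
        if np.count_nonzero(ytr == cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 training samples")
    scaler = StandardScaler().fit(Xtr)
    Xs = scaler.transform(Xtr)

    if n_classes == 2:
        pairs = [(classes[0], classes[1])]
    else:
        pairs = [(classes[0], classes[1]), (classes[0], classes[2]),
                 (classes[1], classes[2])]
    learners, codes = [], []
    for neg, pos in pairs:
        sel = (ytr == neg) | (ytr == pos)
        svm = SVC(kernel="rbf", C=C, gamma=gamma)
        svm.fit(Xs[sel], np.where(ytr[sel] == pos, 1, -1))
        learners.append(svm)
        codes.append([1 if c == pos else (-1 if c == neg else 0) for c in classes])
    model = ClassifierModel(scaler=scaler, learners=learners,
                            code_matrix=np.array(codes, dtype=float).T,
                            classes=classes, feature_names=list(ts.feature_names))
    model.validation_accuracy = float(np.mean(model.decision(Xval) == yval))
    return model


def classify_image(model: ClassifierModel, features: np.ndarray,
                   feature_names: Optional[Sequence[str]] = None,
                   chunk: int = 200_000) -> SegmentationMask:
    """Label every pixel of a feature raster with the trained model."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError("expected an (H, W, F) feature raster")
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise ValueError(
            f"feature schema {list(feature_names)} does not match the model's "
            f"{list(model.feature_names)}")
    if features.shape[2] != len(model.feature_names):
        raise ValueError("feature raster width does not match the model schema")
    h, w, f = features.shape
    flat = features.reshape(-1, f)
    out = np.empty(len(flat), dtype=np.int16)
    for start in range(0, len(flat), chunk):
        out[start:start + chunk] = model.decision(flat[start:start + chunk])
    return SegmentationMask(out.reshape(h, w), n_classes=model.n_classes)


# ---------------------------------------------------------------------------
# mask post-processing


def median_filter_mask(mask: SegmentationMask, window: int = 5,
                       max_iterations: int = 10) -> SegmentationMask:
    """Remove segmentation speckle with a window vote, applied to a fixed point.

    Binary masks use a plain median; three-class masks use a plurality vote
    with ties broken toward the center pixel's own label.  The vote is
    repeated until the mask stops changing (usually 1-2 passes), which makes
    the operation idempotent.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    labels = mask.labels
    for _ in range(max_iterations):
        if mask.n_classes == 2:
            out = median_filter(labels, size=window, mode="reflect")
        else:
            counts = np.stack(
                [uniform_filter((labels == cls).astype(float), size=window,
                                mode="reflect")
                 for cls in (SOIL, LEAF, SPIKE)], axis=-1)
            winner = np.argmax(counts, axis=-1)
            own = np.take_along_axis(counts, labels[..., None].astype(int),
                                     axis=-1)[..., 0]
            best = np.max(counts, axis=-1)
            out = np.where(own >= best - 1e-9, labels, winner).astype(np.int16)
        if np.array_equal(out, labels):
            break
        labels = out
    return SegmentationMask(labels, n_classes=mask.n_classes)


def saturation_fraction(image: np.ndarray, bit_depth: int) -> float:
    """Fraction of pixels at the maximum representable value.

    For color rasters a pixel counts as saturated when any channel peaks,
    matching the gray-level saturation read on raw sensor data.
    """
    image = np.asarray(image)
    maxv = (1 << bit_depth) - 1
    sat = image >= maxv
    if image.ndim == 3:
        sat = sat.any(axis=-1)
    return float(np.count_nonzero(sat)) / sat.size if sat.size else float("nan")
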