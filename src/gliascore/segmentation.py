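"""Scribble-trained pixel classification and area-fraction measurement.

The workflow mirrors interactive trainable segmentation: the user scribbles
a handful of pixels as *object* or *background* on a projection, a per-pixel
classifier is trained on local image features at those pixels, the whole
channel is classified, and connected pixel groups smaller than a background
threshold (default 24 px, 8-neighborhood) are suppressed before the object
area fraction is measured.

The feature bank (raw intensity, Gaussian-smoothed intensity at several
scales, gradient magnitude, local variance) is a compact version of the
banks used by trainable-segmentation tools; it is versioned via
``FEATURE_RECIPE`` and recorded in each trained model so that recipe
mismatches between training and prediction are caught.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from gliascore.io_projection import CHANNEL_LABELS, Projection

FEATURE_RECIPE = "intensity+gauss(1,2,4)+gradmag+localvar(5)-v1"
_GAUSS_SIGMAS = (1.0, 2.0, 4.0)
_VAR_WINDOW = 5

OBJECT = "object"
BACKGROUND = "background"


@dataclass
class ScribbleSet:
    """Sparse training annotations for one channel.

    ``entries`` is a list of ``(row, col, class)`` with class in
    {"object", "background"}.
    """

    entries: list[tuple[int, int, str]]
    channel_label: str

    def __post_init__(self) -> None:
        for row, col, klass in self.entries:
            if klass not in (OBJECT, BACKGROUND):
                raise ValueError(f"unknown scribble class {klass!r}")
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(f"unknown channel label {self.channel_label!r}")

    @property
    def classes(self) -> set[str]:
        return {klass for _, _, klass in self.entries}

    def validate_against(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for row, col, _ in self.entries:
            if not (0 <= row < rows and 0 <= col < cols):
                raise ValueError(f"scribble ({row}, {col}) outside raster {shape}")

    @classmethod
    def from_csv(cls, path: str | Path, channel_label: str | None = None) -> "ScribbleSet":
        """Load scribbles from a CSV with columns x, y, class[, channel].

        x is the column index, y the row index (image convention).
        """
        df = pd.read_csv(path)
        required = {"x", "y", "class"}
        if not required.issubset(df.columns):
            raise ValueError(f"scribble CSV needs columns {sorted(required)}")
        if channel_label is None:
            if "channel" not in df.columns or df["channel"].nunique() != 1:
                raise ValueError("channel_label required when CSV is ambiguous")
            channel_label = str(df["channel"].iloc[0])
        elif "channel" in df.columns:
            df = df[df["channel"] == channel_label]
        entries = [
            (int(y), int(x), str(k)) for x, y, k in zip(df["x"], df["y"], df["class"])
        ]
        return cls(entries=entries, channel_label=channel_label)


@dataclass
class PixelClassifierModel:
    """Trained per-pixel object/background decision function.

    Prediction is deterministic given identical features and seed: the
    underlying ensemble is seeded and single-threaded.
    """

    recipe: str
    estimator: RandomForestClassifier
    channel_label: str
    seed: int
    n_object_scribbles: int
    n_background_scribbles: int
    training_accuracy: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Return a boolean object mask flattened to the feature order."""
        return self.estimator.predict(features).astype(bool)


def extract_features(projection: Projection, channel_label: str) -> np.ndarray:
    """Per-pixel feature table for one channel, shape (rows*cols, n_features).

    Features (row-major pixel order): raw intensity; Gaussian-smoothed
    intensity at sigmas 1, 2 and 4 px; Sobel gradient magnitude; local
    variance in a 5x5 window.
    """
    raster = projection.channel(channel_label).astype(np.float32)
    feats = [raster]
    for sigma in _GAUSS_SIGMAS:
        feats.append(ndimage.gaussian_filter(raster, sigma=sigma))
    gr = ndimage.sobel(raster, axis=0)
    gc = ndimage.sobel(raster, axis=1)
    feats.append(np.hypot(gr, gc))
    local_mean = ndimage.uniform_filter(raster, size=_VAR_WINDOW)
    local_sq = ndimage.uniform_filter(raster**2, size=_VAR_WINDOW)
    feats.append(np.maximum(local_sq - local_mean**2, 0.0))
    return np.stack([f.ravel() for f in feats], axis=1)


def train_pixel_classifier(
    features: np.ndarray,
    scribbles: ScribbleSet,
    shape: tuple[int, int],
    seed: int = 0,
) -> PixelClassifierModel:
    """Train the object/background classifier on scribbled pixels.

    Parameters
    ----------
    features:
        Feature table from :func:`extract_features` for the same raster.
    shape:
        (rows, cols) of the raster the features were extracted from; used to
        map scribble coordinates to feature rows.
    """
    if scribbles.classes != {OBJECT, BACKGROUND}:
        raise ValueError("scribbles must contain both object and background pixels")
    scribbles.validate_against(shape)
    _, cols = shape
    idx = np.array([row * cols + col for row, col, _ in scribbles.entries])
    y = np.array([klass == OBJECT for _, _, klass in scribbles.entries])
    X = features[idx]
    est = RandomForestClassifier(
        n_estimators=50,
        max_depth=12,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    acc = float((est.predict(X) == y).mean())
    return PixelClassifierModel(
        recipe=FEATURE_RECIPE,
        estimator=est,
        channel_label=scribbles.channel_label,
        seed=seed,
        n_object_scribbles=int(y.sum()),
        n_background_scribbles=int((~y).sum()),
        training_accuracy=acc,
    )


@dataclass
class SegmentationMask:
    """Binary object raster for one channel (object=True)."""

    mask: np.ndarray
    channel_label: str
    min_object_size_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be binary")
            self.mask = self.mask.astype(bool)
        if self.min_object_size_px < 0:
            raise ValueError("min_object_size_px must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def segment(
    projection: Projection,
    model: PixelClassifierModel,
    channel_label: str | None = None,
) -> SegmentationMask:
    """Classify every pixel of one channel as object or background."""
    if model.recipe != FEATURE_RECIPE:
        raise ValueError(
            f"model recipe {model.recipe!r} incompatible with {FEATURE_RECIPE!r}"
        )
    label = channel_label or model.channel_label
    features = extract_features(projection, label)
    mask = model.predict(features).reshape(projection.shape)
    return SegmentationMask(mask=mask, channel_label=label, min_object_size_px=0)


def filter_small_objects(mask: SegmentationMask, min_size: int = 24) -> SegmentationMask:
    """Suppress connected pixel groups strictly smaller than ``min_size``.

    Connectivity is the 8-neighborhood: diagonally touching fluorescent
    pixels belong to one structure. Groups of exactly ``min_size`` pixels
    survive (strictly-below removal).
    """
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    labels, n = ndimage.label(mask.mask, structure=np.ones((3, 3), bool))
    if n == 0 or min_size <= 1:
        filtered = mask.mask.copy()
    else:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size
        keep[0] = False
        filtered = keep[labels]
    return SegmentationMask(
        mask=filtered, channel_label=mask.channel_label, min_object_size_px=min_size
    )


def area_fraction(mask: SegmentationMask) -> float:
    """Object area as a percentage of the total image area, in [0, 100]."""
    if mask.mask.size == 0:
        raise ValueError("zero-area image")
    return 100.0 * float(mask.mask.sum()) / mask.mask.size


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Write a binary mask as a single-page uint8 TIFF (object=255)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path
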