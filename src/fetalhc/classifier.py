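"""Skull / background pixel classification.

Training samples come from annotated images: every pixel of the rasterized
annotation ellipse is a positive, and an equal number of negatives is drawn
uniformly from pixels at least ``d_min`` mm away from the curve.  Each image
also contributes its horizontally flipped copy (a flipped-transducer
acquisition looks like a mirrored scan), doubling both sample sets.  The
classifier is a random forest; the emitted likelihood is the fraction of
trees voting "skull", i.e. the forest's soft vote in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .core_io import EllipseAnnotation, ScaledImage, rasterize_ellipse
from .haar import feature_stack

__all__ = [
    "TrainingSampleSet",
    "LikelihoodMap",
    "SkullClassifier",
    "sample_training_pixels",
    "train_classifier",
    "predict_likelihood",
]


@dataclass
class TrainingSampleSet:
    """Balanced per-pixel training samples with provenance."""

    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # 1 = skull, 0 = background
    provenance: list = field(default_factory=list)  # (image id, (row, col), flipped)
    scales: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")

    def merged_with(self, other: "TrainingSampleSet") -> "TrainingSampleSet":
        if self.scales != other.scales:
            raise ValueError("cannot merge sample sets with different feature scales")
        return TrainingSampleSet(
            np.vstack([self.features, other.features]),
            np.concatenate([self.labels, other.labels]),
            self.provenance + other.provenance,
            self.scales,
        )


@dataclass(frozen=True)
class LikelihoodMap:
    """Per-pixel skull probability aligned to its source image."""

    values: np.ndarray
    pixel_size: float
    pipeline: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("likelihood values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _sample_one(img, ann, d_min, f_scales, rng, flipped):
    """Positives on the annotation curve, equal negatives >= d_min away."""
    curve = rasterize_ellipse(ann, img, "curve")
    pos = np.argwhere(curve)
    if len(pos) == 0:
        raise ValueError(f"annotation does not intersect image {img.id!r}")
    # distance (mm) from every pixel to the annotation curve
    dist = ndimage.distance_transform_edt(~curve) * img.pixel_size
    eligible = np.argwhere((dist >= d_min) & ~curve)
    if len(eligible) < len(pos):
        raise ValueError(
            f"too few background pixels at distance >= {d_min} mm in image {img.id!r}"
        )
    pick = rng.choice(len(eligible), size=len(pos), replace=False)
    neg = eligible[pick]
    stack = feature_stack(img, f_scales)
    rows = np.concatenate([pos[:, 0], neg[:, 0]])
    cols = np.concatenate([pos[:, 1], neg[:, 1]])
    feats = stack.at(rows, cols)
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    prov = [(img.id, (int(r), int(c)), flipped) for r, c in zip(rows, cols)]
    return TrainingSampleSet(feats, labels, prov, tuple(float(s) for s in f_scales))


def sample_training_pixels(
    img: ScaledImage,
    ann: EllipseAnnotation,
    d_min: float,
    f_scales,
    rng_seed: int = 0,
) -> TrainingSampleSet:
    """Build the balanced sample set for one annotated image.

    Both the original and the horizontally flipped image contribute; the
    flipped annotation is the mirror of ``ann`` about the vertical midline
    of the frame.  Reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    width_mm = img.shape[1] * img.pixel_size
    ann_flip = EllipseAnnotation(width_mm - ann.cx, ann.cy, ann.a, ann.b, (np.pi - ann.theta) % np.pi)
    s0 = _sample_one(img, ann, d_min, f_scales, rng, flipped=False)
    s1 = _sample_one(img.flipped_horizontally(), ann_flip, d_min, f_scales, rng, flipped=True)
    return s0.merged_with(s1)


@dataclass
class SkullClassifier:
    """A trained forest bundled with its feature configuration.

    Bundling the scales prevents a prediction-time feature mismatch: the
    model refuses images featurized with a different configuration.
    """

    forest: RandomForestClassifier
    f_scales: tuple[float, ...]
    n_trees: int
    name: str = ""

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"forest": self.forest, "f_scales": self.f_scales,
             "n_trees": self.n_trees, "name": self.name, "format": 1},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SkullClassifier":
        d = joblib.load(path)
        return cls(d["forest"], tuple(d["f_scales"]), d["n_trees"], d.get("name", ""))


def train_classifier(samples: TrainingSampleSet, n_trees: int = 10, rng_seed: int = 0,
                     name: str = "") -> SkullClassifier:
    """Fit the random forest on a balanced sample set.

    Only the forest size is pinned; the remaining tree hyperparameters are
    scikit-learn defaults (unbounded depth, sqrt feature subsampling),
    recorded inside the saved model.
    """
    classes = np.unique(samples.labels)
    if len(classes) < 2:
        raise ValueError("training requires both skull and background samples")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=rng_seed, n_jobs=1)
    forest.fit(samples.features, samples.labels)
    return SkullClassifier(forest, samples.scales, n_trees, name)


def predict_likelihood(model: SkullClassifier, img: ScaledImage,
                       f_scales=None) -> LikelihoodMap:
    """Per-pixel skull likelihood (soft forest vote) for a whole frame."""
    scales = tuple(float(s) for s in (f_scales if f_scales is not None else model.f_scales))
    if scales != tuple(model.f_scales):
        raise ValueError(
            f"model was trained with scales {model.f_scales}, got {scales}"
        )
    stack = feature_stack(img, scales)
    h, w = img.shape
    flat = stack.values.reshape(h * w, -1)
    prob = model.forest.predict_proba(flat)
    skull_col = int(np.where(model.forest.classes_ == 1)[0][0])
    values = prob[:, skull_col].reshape(h, w)
    return LikelihoodMap(values, img.pixel_size, model.name)
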