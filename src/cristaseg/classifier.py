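"""Random-forest pixel classification from sparse stroke annotations.

The user marks a handful of pixels as "Cristae" and a handful as
"Background" (everything that is not a crista, including the mitochondrial
matrix). Feature vectors at those pixels accumulate in a
:class:`TrainingSet` — possibly across several images and sessions — and a
random forest is trained on them. Applied to a full feature stack the
forest yields a per-pixel :class:`ProbabilityMap` whose first plane is the
cristae class, following the channel-1 convention of the workflow this
package reimplements.

Class probabilities are the mean of per-tree leaf posteriors rather than
hard-vote fractions; the smoother maps behave better under the downstream
0.5 probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from scipy.io import arff as scipy_arff
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureStack
from .image import CalibratedImage

__all__ = [
    "CLASS_NAMES",
    "StrokeAnnotation",
    "TrainingSet",
    "PixelClassifier",
    "ProbabilityMap",
    "add_annotations",
    "train_classifier",
    "predict_probability",
    "read_arff",
    "write_arff",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)

CLASS_NAMES = ("Cristae", "Background")  # fixed order; Cristae is plane 0

DEFAULT_N_TREES = 200
DEFAULT_SEED = 42

_FORMAT_VERSION = 1


class IncompatibleFeaturesError(ValueError):
    """Feature schema of a stack does not match the training data / model."""


@dataclass(frozen=True)
class StrokeAnnotation:
    """A user stroke: pixel coordinates sharing one class label."""

    image_id: str
    pixel_coords: np.ndarray  # (n, 2) of (row, col)
    class_label: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.pixel_coords, dtype=np.intp)
        if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
            raise ValueError("pixel_coords must be a non-empty (n, 2) array")
        if self.class_label not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_label!r}; expected one of {CLASS_NAMES}"
            )
        object.__setattr__(self, "pixel_coords", coords)


@dataclass
class TrainingSet:
    """Labelled feature vectors accumulated across annotation sessions."""

    feature_names: tuple[str, ...] = ()
    samples: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_per_class(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == i)) for i, name in enumerate(CLASS_NAMES)
        }


def add_annotations(
    training: TrainingSet, stack: FeatureStack, strokes: Iterable[StrokeAnnotation]
) -> TrainingSet:
    """Append the feature vectors under each stroke pixel to the training set.

    Duplicates are allowed — re-tracing a structure re-weights it. Returns a
    new, grown set; the input set is not modified.

    Raises
    ------
    IncompatibleFeaturesError
        If the stack's feature names/order differ from the set's schema.
    """
    if len(training) > 0 and training.feature_names != stack.names:
        raise IncompatibleFeaturesError(
            "feature stack schema does not match the training set: "
            f"{stack.names} vs {training.feature_names}"
        )
    rows_list, labels_list = [], []
    for stroke in strokes:
        coords = stroke.pixel_coords
        if (
            coords[:, 0].min() < 0
            or coords[:, 1].min() < 0
            or coords[:, 0].max() >= stack.source_shape[0]
            or coords[:, 1].max() >= stack.source_shape[1]
        ):
            raise ValueError(f"stroke on {stroke.image_id} is out of image bounds")
        rows_list.append(stack.as_samples(coords))
        labels_list.append(
            np.full(len(coords), CLASS_NAMES.index(stroke.class_label), dtype=np.intp)
        )
    if not rows_list:
        return training
    new_rows = np.concatenate(rows_list)
    new_labels = np.concatenate(labels_list)
    if len(training) > 0:
        new_rows = np.concatenate([training.samples, new_rows])
        new_labels = np.concatenate([training.labels, new_labels])
    return TrainingSet(stack.names, new_rows, new_labels)


@dataclass
class PixelClassifier:
    """A trained random forest plus the feature schema it expects."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    n_trees: int
    features_per_split: Optional[int]
    seed: int


def train_classifier(
    training: TrainingSet,
    n_trees: int = DEFAULT_N_TREES,
    features_per_split: Optional[int] = None,
    seed: int = DEFAULT_SEED,
) -> PixelClassifier:
    """Fit a random forest on the accumulated stroke samples.

    ``features_per_split`` defaults to floor(sqrt(n_features)). Training is
    deterministic given ``seed``. Out-of-bag stroke accuracy is logged so the
    user can judge when to stop the annotate/train loop — there is no
    automatic stopping criterion.

    Raises
    ------
    ValueError
        If fewer than two classes are present (degenerate training set).
    """
    if len(training) == 0 or len(np.unique(training.labels)) < 2:
        raise ValueError(
            "training set must contain samples of both classes; "
            f"got {training.n_per_class}"
        )
    max_features = features_per_split if features_per_split else "sqrt"
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    model.fit(training.samples, training.labels)
    try:
        logger.info(
            "trained %d trees on %d samples %s; out-of-bag stroke accuracy %.3f",
            n_trees,
            len(training),
            training.n_per_class,
            model.oob_score_,
        )
    except AttributeError:  # too few samples for every tree to have OOB rows
        logger.info("trained %d trees on %d samples", n_trees, len(training))
    return PixelClassifier(
        model, training.feature_names, n_trees, features_per_split, seed
    )


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class probabilities, plane 0 = Cristae, plane 1 = Background."""

    planes: np.ndarray  # (2, rows, cols)
    pixel_size_um: float
    time_s: Optional[float] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.shape[0] != len(CLASS_NAMES):
            raise ValueError("planes must be (2, rows, cols)")
        if self.planes.min() < 0 or self.planes.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.planes.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1 per pixel")

    @property
    def cristae(self) -> np.ndarray:
        return self.planes[0]

    def as_image(self) -> CalibratedImage:
        """The cristae plane as a calibrated image (for export/inspection)."""
        return CalibratedImage(
            self.planes[0], self.pixel_size_um, self.time_s, self.frame_index
        )


def predict_probability(
    classifier: PixelClassifier,
    stack: FeatureStack,
    image: Optional[CalibratedImage] = None,
) -> ProbabilityMap:
    """Apply the forest to every pixel of a feature stack.

    When the source ``image`` is given, its calibration and time stamp are
    inherited by the map; otherwise the map carries a unit pixel size.
    """
    if stack.names != tuple(classifier.feature_names):
        raise IncompatibleFeaturesError(
            "feature stack schema does not match the classifier: "
            f"{stack.names} vs {tuple(classifier.feature_names)}"
        )
    proba = classifier.model.predict_proba(stack.flatten())
    # model.classes_ are the integer codes of CLASS_NAMES; reorder defensively
    order = np.argsort(classifier.model.classes_)
    proba = proba[:, order]
    planes = proba.T.reshape(len(CLASS_NAMES), *stack.source_shape)
    if image is None:
        return ProbabilityMap(planes, pixel_size_um=1.0)
    return ProbabilityMap(planes, image.pixel_size_um, image.time_s, image.frame_index)


# ---------------------------------------------------------------------------
# persistence


def save_classifier(classifier: PixelClassifier, path) -> None:
    """Persist model + schema + hyperparameters in a versioned file."""
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "feature_names": tuple(classifier.feature_names),
            "n_trees": classifier.n_trees,
            "features_per_split": classifier.features_per_split,
            "seed": classifier.seed,
            "model": classifier.model,
        },
        str(path),
    )


def load_classifier(path) -> PixelClassifier:
    payload = joblib.load(str(path))
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported classifier file version: {version}")
    return PixelClassifier(
        payload["model"],
        tuple(payload["feature_names"]),
        payload["n_trees"],
        payload["features_per_split"],
        payload["seed"],
    )


# ---------------------------------------------------------------------------
# ARFF training-data interchange


def write_arff(training: TrainingSet, path, relation: str = "cristae-training") -> None:
    """Export a training set as ARFF (numeric features + nominal class)."""
    if len(training) == 0:
        raise ValueError("cannot export an empty training set")
    lines = [f"@relation {relation}", ""]
    for name in training.feature_names:
        lines.append(f"@attribute {name} numeric")
    lines.append("@attribute class {" + ",".join(CLASS_NAMES) + "}")
    lines += ["", "@data"]
    for row, label in zip(training.samples, training.labels):
        values = ",".join(repr(float(v)) for v in row)
        lines.append(f"{values},{CLASS_NAMES[label]}")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_arff(path) -> TrainingSet:
    """Import ARFF training data (e.g. saved by the original plugin).

    The last nominal attribute is taken as the class; its values must be the
    package's two class names. All other attributes become features.
    """
    data, meta = scipy_arff.loadarff(str(path))
    names = list(meta.names())
    class_attr = names[-1]
    feature_names = tuple(names[:-1])
    raw_labels = [v.decode() if isinstance(v, bytes) else str(v) for v in data[class_attr]]
    unknown = set(raw_labels) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels in ARFF file: {sorted(unknown)}")
    labels = np.array([CLASS_NAMES.index(v) for v in raw_labels], dtype=np.intp)
    samples = np.column_stack([np.asarray(data[n], dtype=np.float64) for n in feature_names])
    return TrainingSet(feature_names, samples, labels)
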