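"""Shared fixtures: synthetic scenes and a reference-trained classifier.

Heavy artefacts (feature stacks, the trained forest) are session-scoped;
every test that consumes them sees the identical object, which also
exercises the pipeline's determinism guarantees implicitly.
"""

from __future__ import annotations

import numpy as np
import pytest

import cristaseg as cs
from cristaseg.classifier import TrainingSet
from cristaseg.features import build_feature_stack
from cristaseg.preprocess import subtract_background

REFERENCE_SPACING_UM = 0.25  # resolvable-lamellae study condition
DENSE_SPACING_UM = 0.18  # below the intensity-thresholding merge distance
SUB_PSF_SPACING_UM = 0.08  # below the PSF scale: unresolvable


def train_reference_classifier(seed: int = 0):
    """Two-scene training recipe: 400 stroke px/class per scene, forest seed 42."""
    training = TrainingSet()
    for i, scene_seed in enumerate((seed + 1000, seed + 2000)):
        image, truth = cs.generate_scene(cs.SceneSpec(seed=scene_seed))
        pre = subtract_background(image)
        stack = build_feature_stack(pre)
        strokes = cs.strokes_from_truth(truth, seed=seed + 100 + i)
        training = cs.add_annotations(training, stack, strokes)
    return cs.train_classifier(training, seed=42)


@pytest.fixture(scope="session")
def reference_classifier():
    return train_reference_classifier(seed=0)


@pytest.fixture(scope="session")
def default_scene():
    """Resolvable-lamellae scene, seed 0, with preprocessed image and stack."""
    image, truth = cs.generate_scene(cs.SceneSpec(seed=0))
    pre = subtract_background(image)
    stack = build_feature_stack(pre)
    return {"image": image, "truth": truth, "pre": pre, "stack": stack}


@pytest.fixture(scope="session")
def dense_scene():
    """Dense-lamellae scene (0.18 um pitch), seed 0."""
    image, truth = cs.generate_scene(
        cs.SceneSpec(seed=0, cristae_spacing_um=DENSE_SPACING_UM)
    )
    pre = subtract_background(image)
    return {"image": image, "truth": truth, "pre": pre}


@pytest.fixture(scope="session")
def small_image():
    """A deterministic small calibrated image for unit tests."""
    rng = np.random.default_rng(7)
    return cs.CalibratedImage(rng.uniform(0, 100, size=(32, 32)), 0.04)


def disk_coords(radius_px: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    rr, cc = np.nonzero(yy**2 + xx**2 <= radius_px**2)
    return np.column_stack([rr, cc])


def rect_coords(height_px: int, width_px: int) -> np.ndarray:
    rr, cc = np.mgrid[0:height_px, 0:width_px]
    return np.column_stack([rr.ravel(), cc.ravel()])
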