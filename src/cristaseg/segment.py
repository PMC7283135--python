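"""From probability maps (or raw intensities) to filtered cristae particles.

The classifier route thresholds the cristae probability plane (default 0.5)
and extracts 8-connected particles; the baseline routes threshold raw
intensities with classical histogram criteria (MaxEntropy/Kapur, Shanbhag,
Otsu, isodata). All histogram methods operate on a 256-bin histogram of
min–max-scaled data — an 8-bit emulation that keeps the selected bins
bit-compatible with the reference implementations of those criteria — and
treat bins strictly above the returned threshold as foreground.

Particles smaller than the theoretical crista cross-section (default
0.017 um^2; boundary inclusive) are excluded, and the mitochondrial network
is segmented separately to provide the denominator for cristae density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .classifier import PixelClassifier, ProbabilityMap, predict_probability
from .features import FeatureConfig, build_feature_stack
from .image import CalibratedImage
from .morphometry import DEFAULT_MIN_AREA_UM2, Particle, measure_particle

__all__ = [
    "BinaryMask",
    "AUTO_THRESHOLD_METHODS",
    "histogram_256",
    "auto_threshold",
    "threshold_probability",
    "threshold_intensity",
    "connected_particles",
    "filter_particles",
    "segment_mito_network",
    "label_mask",
]

logger = logging.getLogger(__name__)

AUTO_THRESHOLD_METHODS = ("max_entropy", "shanbhag", "otsu", "default_isodata")
_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class BinaryMask:
    """Boolean segmentation mask with inherited calibration."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


# ---------------------------------------------------------------------------
# histogram thresholding


def histogram_256(values: np.ndarray) -> np.ndarray:
    """256-bin histogram of min–max-scaled values (8-bit emulation).

    Values are mapped linearly so the minimum lands in bin 0 and the maximum
    in bin 255 (rounded to nearest). A constant array maps entirely to bin 0.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    if hi == lo:
        bins = np.zeros(values.shape, dtype=np.intp)
    else:
        bins = np.rint((values - lo) / (hi - lo) * 255.0).astype(np.intp)
    return np.bincount(bins, minlength=256)


def scale_to_bins(values: np.ndarray) -> np.ndarray:
    """The per-pixel bin indices used by :func:`histogram_256`."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    return np.rint((values - lo) / (hi - lo) * 255.0).astype(np.intp)


def auto_threshold(histogram: np.ndarray, method: str) -> int:
    """Select a threshold bin from a 256-bin histogram.

    Foreground is the set of bins strictly above the returned bin. All
    criteria are evaluated exhaustively over candidate bins.

    Raises
    ------
    ValueError
        For an unknown method or a histogram with < 2 nonempty bins.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or len(hist) != 256:
        raise ValueError("histogram must be a flat 256-bin array")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")
    if method == "max_entropy":
        return _kapur_max_entropy(hist)
    if method == "shanbhag":
        return _shanbhag(hist)
    if method == "otsu":
        return _otsu(hist)
    if method == "default_isodata":
        return _isodata(hist)
    raise ValueError(f"unknown method {method!r}; expected one of {AUTO_THRESHOLD_METHODS}")


def _kapur_max_entropy(hist: np.ndarray) -> int:
    """Kapur–Sahoo–Wong: maximize background + foreground Shannon entropies."""
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    first = int(np.argmax(P1 > _EPS))
    last = 255 - int(np.argmax((1.0 - P1 + p)[::-1] > _EPS))
    best_t, best_crit = first, -np.inf
    for t in range(first, last + 1):
        pb, pf = P1[t], 1.0 - P1[t]
        if pb <= _EPS or pf <= _EPS:
            continue
        back = p[: t + 1] / pb
        back = back[back > _EPS]
        fore = p[t + 1 :] / pf
        fore = fore[fore > _EPS]
        crit = -(back * np.log(back)).sum() - (fore * np.log(fore)).sum()
        if crit > best_crit:
            best_crit, best_t = crit, t
    return best_t


def _shanbhag(hist: np.ndarray) -> int:
    """Shanbhag's fuzzy-membership information measure, minimized in |.|."""
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    first = int(np.argmax(np.abs(P1) >= _EPS))
    last = 255 - int(np.argmax(np.abs(P2[::-1]) >= _EPS))
    last = max(last, first)
    best_t, best_crit = first, np.inf
    for t in range(first, last + 1):
        if P1[t] <= _EPS or P2[t] <= _EPS:
            continue
        term = 0.5 / P1[t]
        ih = np.arange(1, t + 1)
        ent_back = -(p[ih] * np.log(1.0 - term * P1[ih - 1])).sum() * term
        term = 0.5 / P2[t]
        ih = np.arange(t + 1, 256)
        ent_obj = -(p[ih] * np.log(1.0 - term * P2[ih])).sum() * term
        crit = abs(ent_back - ent_obj)
        if crit < best_crit:
            best_crit, best_t = crit, t
    return best_t


def _otsu(hist: np.ndarray) -> int:
    """Maximize between-class variance."""
    p = hist / hist.sum()
    bins = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)
    mu = np.cumsum(p * bins)
    mu_total = mu[-1]
    best_t, best_var = 0, -np.inf
    for t in range(256):
        w0, w1 = omega[t], 1.0 - omega[t]
        if w0 <= _EPS or w1 <= _EPS:
            continue
        m0 = mu[t] / w0
        m1 = (mu_total - mu[t]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def _isodata(hist: np.ndarray) -> int:
    """Iterate threshold to the midpoint of the two class means."""
    bins = np.arange(256, dtype=np.float64)
    nonzero = np.nonzero(hist)[0]
    t = int(round(float((hist * bins).sum() / hist.sum())))
    t = min(max(t, int(nonzero[0])), int(nonzero[-1]) - 1)
    for _ in range(1000):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        if below.sum() == 0:
            t += 1
            continue
        if above.sum() == 0:
            t -= 1
            continue
        m_below = (below * bins[: t + 1]).sum() / below.sum()
        m_above = (above * bins[t + 1 :]).sum() / above.sum()
        t_new = int(round((m_below + m_above) / 2.0))
        if t_new == t:
            break
        t = t_new
    return t


# ---------------------------------------------------------------------------
# masks


def threshold_probability(prob: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Binary mask where the cristae-class probability is >= ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return BinaryMask(prob.cristae >= threshold, prob.pixel_size_um)


def threshold_intensity(
    image: CalibratedImage,
    method: Optional[str] = None,
    manual_threshold: Optional[float] = None,
) -> tuple[BinaryMask, float]:
    """Threshold raw intensities with an automatic criterion or a manual cut.

    With ``method``, the image is min–max-scaled to 256 bins, the criterion
    picks a bin and pixels in bins strictly above it are foreground; the
    selected bin is returned. With ``manual_threshold`` (the conventional
    workflow), pixels with intensity >= the given value are foreground.
    """
    if (method is None) == (manual_threshold is None):
        raise ValueError("supply exactly one of method or manual_threshold")
    if manual_threshold is not None:
        return (
            BinaryMask(image.pixels >= manual_threshold, image.pixel_size_um),
            float(manual_threshold),
        )
    t = auto_threshold(histogram_256(image.pixels), method)
    mask = scale_to_bins(image.pixels) > t
    return BinaryMask(mask, image.pixel_size_um), float(t)


# ---------------------------------------------------------------------------
# particles


def connected_particles(mask: BinaryMask, connectivity: int = 8) -> list[Particle]:
    """Maximal connected components of the mask as measured particles.

    Particle ids follow the row-major order of each component's
    top-left-most pixel, making the output deterministic.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels = skmeasure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)
    n = labels.max()
    if n == 0:
        return []
    objects = ndimage.find_objects(labels)
    components = []
    ncols = labels.shape[1]
    for lbl in range(1, n + 1):
        sl = objects[lbl - 1]
        rr, cc = np.nonzero(labels[sl] == lbl)
        coords = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        first = int(np.min(coords[:, 0] * ncols + coords[:, 1]))
        components.append((first, coords))
    components.sort(key=lambda item: item[0])
    return [
        measure_particle(coords, mask.pixel_size_um, particle_id=i)
        for i, (_, coords) in enumerate(components)
    ]


def filter_particles(
    particles: Sequence[Particle],
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> list[Particle]:
    """Exclude particles below the theoretical crista area (boundary kept)."""
    if min_area_um2 < 0:
        raise ValueError(f"min_area_um2 must be >= 0, got {min_area_um2}")
    return [p for p in particles if p.area_um2 >= min_area_um2]


# ---------------------------------------------------------------------------
# mitochondrial network


def segment_mito_network(
    image: CalibratedImage,
    strategy: str = "otsu_on_smoothed",
    classifier: Optional[PixelClassifier] = None,
    feature_config: Optional[FeatureConfig] = None,
    prob_threshold: float = 0.5,
    smoothing_sigma_px: float = 2.0,
) -> tuple[BinaryMask, float]:
    """Segment whole mitochondria (cristae + matrix + boundary membrane).

    ``otsu_on_smoothed`` smooths with a Gaussian (sigma 2 px) and applies
    Otsu on the smoothed intensities — adequate because whole organelles are
    bright against the cell background even when individual cristae are not
    resolvable. ``classifier`` uses a second two-class model trained on
    organelle-vs-background strokes. Returns the mask and its area in um^2;
    an empty foreground yields a warning and area 0.
    """
    if strategy == "otsu_on_smoothed":
        smoothed = image.with_pixels(
            ndimage.gaussian_filter(image.pixels, sigma=smoothing_sigma_px, mode="reflect")
        )
        try:
            mask, _ = threshold_intensity(smoothed, method="otsu")
        except ValueError:  # constant image: nothing to segment
            mask = BinaryMask(np.zeros(image.shape, dtype=bool), image.pixel_size_um)
    elif strategy == "classifier":
        if classifier is None:
            raise ValueError("classifier strategy requires a trained model")
        stack = build_feature_stack(image, feature_config)
        prob = predict_probability(classifier, stack, image)
        mask = threshold_probability(prob, prob_threshold)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    area = mask.area_um2
    if area == 0.0:
        warnings.warn("empty mitochondrial network mask", stacklevel=2)
    return mask, area


def label_mask(mask: BinaryMask, connectivity: int = 8) -> np.ndarray:
    """Label connected mitochondria in a network mask (ids row-major stable)."""
    return skmeasure.label(mask.pixels, connectivity=1 if connectivity == 4 else 2)


def particle_outlines(particles: Sequence[Particle], shape: tuple[int, int]) -> np.ndarray:
    """ROI outlines as a labeled boundary mask (particle id + 1 on borders).

    A particle pixel is a boundary pixel when one of its 4-neighbours lies
    outside the particle.
    """
    out = np.zeros(shape, dtype=np.uint16)
    for p in particles:
        member = np.zeros(shape, dtype=bool)
        member[p.pixel_coords[:, 0], p.pixel_coords[:, 1]] = True
        interior = ndimage.binary_erosion(member, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
        out[member & ~interior] = p.id + 1
    return out
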