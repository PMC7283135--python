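"""Per-pixel feature stack for trainable cristae segmentation.

Three feature families feed the pixel classifier, mirroring the trainable
segmentation workflow the package reimplements:

* **Gaussian blur** at several scales — noise suppression.
* **Sobel edge magnitude** after Gaussian pre-smoothing at the same scales —
  cristae are membrane edges at the resolution limit.
* **Membrane projections** — the image is convolved with a line kernel
  rotated through 30 orientations (6 degree steps); six pixelwise statistics
  across the 30 responses (sum, mean, std, median, max, min) strongly
  enhance thin elongated structures of any orientation.

Raw intensity is included by default. Features are computed in pixel units;
spatial calibration enters only at measurement time, so a trained classifier
ports across images acquired at the same pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import CalibratedImage

__all__ = [
    "FeatureConfig",
    "FeatureStack",
    "gaussian_features",
    "edge_features",
    "membrane_projection_features",
    "membrane_kernels",
    "build_feature_stack",
]

DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0, 16.0)
MEMBRANE_N_ORIENTATIONS = 30
MEMBRANE_PROJECTIONS = ("sum", "mean", "std", "median", "max", "min")

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature stack.

    ``sigmas`` are Gaussian scales in pixels (strictly increasing);
    ``membrane_kernel_px`` is the side of the square line kernel (odd, >= 3);
    ``membrane_width_px`` the line thickness. Defaults reproduce the public
    defaults of the trainable-segmentation tool this package follows.
    """

    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    membrane_kernel_px: int = 19
    membrane_width_px: int = 1
    include_raw: bool = True

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        if len(sig) == 0:
            raise ValueError("sigmas must be non-empty")
        if any(s <= 0 for s in sig):
            raise ValueError("sigmas must be positive")
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigmas must be strictly increasing")
        if self.membrane_kernel_px % 2 != 1 or self.membrane_kernel_px < 3:
            raise ValueError("membrane_kernel_px must be odd and >= 3")
        if self.membrane_width_px < 1:
            raise ValueError("membrane_width_px must be >= 1")
        object.__setattr__(self, "sigmas", sig)

    def feature_names(self) -> list[str]:
        names = ["raw"] if self.include_raw else []
        names += [f"gaussian_s{s:g}" for s in self.sigmas]
        names += [f"sobel_s{s:g}" for s in self.sigmas]
        names += [f"membrane_{p}_k{self.membrane_kernel_px}" for p in MEMBRANE_PROJECTIONS]
        return names

    def to_text(self) -> str:
        """Serialize as a plain ``key = value`` config block."""
        return "\n".join(
            [
                "sigmas = " + ",".join(f"{s:g}" for s in self.sigmas),
                f"membrane_kernel_px = {self.membrane_kernel_px}",
                f"membrane_width_px = {self.membrane_width_px}",
                f"include_raw = {'true' if self.include_raw else 'false'}",
            ]
        )

    @classmethod
    def from_text(cls, text: str) -> "FeatureConfig":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = (part.strip() for part in line.split("=", 1))
            kv[k] = v
        kwargs = {}
        if "sigmas" in kv:
            kwargs["sigmas"] = tuple(float(s) for s in kv["sigmas"].split(","))
        if "membrane_kernel_px" in kv:
            kwargs["membrane_kernel_px"] = int(kv["membrane_kernel_px"])
        if "membrane_width_px" in kv:
            kwargs["membrane_width_px"] = int(kv["membrane_width_px"])
        if "include_raw" in kv:
            kwargs["include_raw"] = kv["include_raw"].lower() in ("true", "1", "yes")
        return cls(**kwargs)


@dataclass(frozen=True)
class FeatureStack:
    """Ordered feature planes congruent with their source image."""

    planes: np.ndarray  # (n_features, rows, cols)
    names: tuple[str, ...]
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.planes.ndim != 3:
            raise ValueError("planes must be (n_features, rows, cols)")
        if self.planes.shape[0] != len(self.names):
            raise ValueError("one name per plane required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.planes.shape[1:] != tuple(self.source_shape):
            raise ValueError("planes must match source shape")

    @property
    def n_features(self) -> int:
        return self.planes.shape[0]

    def as_samples(self, coords: np.ndarray) -> np.ndarray:
        """Feature vectors at (row, col) coordinates, shape (n, n_features)."""
        coords = np.asarray(coords)
        return self.planes[:, coords[:, 0], coords[:, 1]].T

    def flatten(self) -> np.ndarray:
        """All pixels as a (rows*cols, n_features) design matrix."""
        return self.planes.reshape(self.n_features, -1).T


def gaussian_features(image: CalibratedImage, sigmas: Sequence[float]) -> np.ndarray:
    """Isotropic Gaussian blur of the image at each scale."""
    sigmas = _check_sigmas(sigmas)
    return np.stack(
        [ndimage.gaussian_filter(image.pixels, sigma=s, mode="reflect") for s in sigmas]
    )


def edge_features(image: CalibratedImage, sigmas: Sequence[float]) -> np.ndarray:
    """Sobel gradient magnitude after Gaussian pre-smoothing at each scale."""
    sigmas = _check_sigmas(sigmas)
    planes = []
    for s in sigmas:
        smooth = ndimage.gaussian_filter(image.pixels, sigma=s, mode="reflect")
        gx = ndimage.convolve(smooth, _SOBEL_X, mode="reflect")
        gy = ndimage.convolve(smooth, _SOBEL_Y, mode="reflect")
        planes.append(np.hypot(gx, gy))
    return np.stack(planes)


def membrane_kernels(kernel_px: int, width_px: int = 1) -> np.ndarray:
    """The 30 rotated line kernels, each normalized to unit sum.

    A centred line of thickness ``width_px`` is rasterized at orientations
    0, 6, ..., 174 degrees by nearest-neighbour inclusion: a pixel belongs
    to the line when its perpendicular distance to the line through the
    kernel centre is at most ``width_px / 2``. Unit-sum normalization makes
    the response to a constant image identical across orientations.
    """
    if kernel_px % 2 != 1 or kernel_px < 3:
        raise ValueError("kernel_px must be odd and >= 3")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    half = kernel_px // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels = []
    for i in range(MEMBRANE_N_ORIENTATIONS):
        theta = np.deg2rad(6.0 * i)
        # distance from pixel centre to the line with direction (cos t, sin t)
        d_perp = np.abs(-xx * np.sin(theta) + yy * np.cos(theta))
        k = (d_perp <= width_px / 2.0).astype(np.float64)
        kernels.append(k / k.sum())
    return np.stack(kernels)


def membrane_projection_features(
    image: CalibratedImage, kernel_px: int = 19, width_px: int = 1
) -> np.ndarray:
    """Six pixelwise projections across the 30 oriented line responses.

    Returns planes in the fixed order sum, mean, std, median, max, min.
    """
    if kernel_px > min(image.shape):
        raise ValueError(
            f"membrane kernel ({kernel_px}) larger than image {image.shape}"
        )
    kernels = membrane_kernels(kernel_px, width_px)
    responses = np.stack(
        [ndimage.convolve(image.pixels, k, mode="reflect") for k in kernels]
    )
    return np.stack(
        [
            responses.sum(axis=0),
            responses.mean(axis=0),
            responses.std(axis=0),
            np.median(responses, axis=0),
            responses.max(axis=0),
            responses.min(axis=0),
        ]
    )


def build_feature_stack(
    image: CalibratedImage, config: FeatureConfig | None = None
) -> FeatureStack:
    """Assemble raw + Gaussian + Sobel + membrane planes in documented order.

    The order is: raw intensity (if configured), Gaussian planes by
    increasing sigma, Sobel planes by increasing sigma, then the six
    membrane projections. It is deterministic given the configuration, so
    classifiers trained on one stack remain valid on any stack built with
    the same configuration.
    """
    config = config or FeatureConfig()
    parts = []
    if config.include_raw:
        parts.append(image.pixels[None])
    parts.append(gaussian_features(image, config.sigmas))
    parts.append(edge_features(image, config.sigmas))
    parts.append(
        membrane_projection_features(
            image, config.membrane_kernel_px, config.membrane_width_px
        )
    )
    planes = np.concatenate(parts, axis=0)
    return FeatureStack(planes, tuple(config.feature_names()), image.shape)


def write_stack_tiff(stack: FeatureStack, path) -> None:
    """Export the stack as a multi-page 32-bit TIFF (one page per feature)."""
    import tifffile

    tifffile.imwrite(
        str(path),
        stack.planes.astype(np.float32),
        metadata={"Labels": list(stack.names)},
    )


def _check_sigmas(sigmas: Sequence[float]) -> list[float]:
    sigmas = [float(s) for s in sigmas]
    if not sigmas:
        raise ValueError("sigma list must be non-empty")
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    return sigmas
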