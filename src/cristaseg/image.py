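"""Calibrated image container and TIFF input/output.

Every stage of the pipeline consumes and produces :class:`CalibratedImage`:
a 2D intensity grid together with its spatial calibration (micrometres per
pixel edge) and, for time-lapse data, the acquisition time of the frame.
Intensities are held in floating point regardless of the bit depth on disk;
16-bit detector counts are not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import tifffile

__all__ = ["CalibratedImage", "read_tiff", "write_tiff"]

MIN_SIDE = 8


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D micrograph with spatial (and optionally temporal) calibration.

    Parameters
    ----------
    pixels
        Non-negative intensity grid, row-major, origin at the top-left,
        pixel centres at integer coordinates.
    pixel_size_um
        Physical size of one pixel edge in micrometres (> 0).
    time_s
        Acquisition time of the frame in seconds, if part of a series.
    frame_index
        Position of the frame in its series, if any.
    """

    pixels: np.ndarray
    pixel_size_um: float
    time_s: Optional[float] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if min(px.shape) < MIN_SIDE:
            raise ValueError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Return a copy carrying ``pixels`` but the same calibration."""
        return replace(self, pixels=pixels)


def read_tiff(
    path,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
) -> list[CalibratedImage]:
    """Read a single- or multi-page TIFF into a list of calibrated frames.

    Pixel size is taken from the TIFF resolution tags when present (with
    ``ResolutionUnit`` centimetre or inch) unless ``pixel_size_um`` overrides
    it. A missing calibration in both places is an error. ``frame_interval_s``
    assigns time stamps ``i * frame_interval_s`` to multi-page series.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        size = pixel_size_um
        if size is None:
            size = _pixel_size_from_tags(tif.pages[0])
    if size is None:
        raise ValueError(
            f"{path}: no resolution tags; supply pixel_size_um explicitly"
        )
    if data.ndim == 2:
        data = data[None]
    frames = []
    for i, plane in enumerate(data):
        t = None if frame_interval_s is None else i * frame_interval_s
        frames.append(
            CalibratedImage(plane.astype(np.float64), size, time_s=t, frame_index=i)
        )
    return frames


def _pixel_size_from_tags(page) -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    per_unit = num / den  # pixels per unit
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None:
        return None
    return unit_um / per_unit


def write_tiff(path, frames: Sequence[CalibratedImage] | CalibratedImage) -> None:
    """Write frame(s) as a (multi-page) 32-bit float TIFF with resolution tags."""
    if isinstance(frames, CalibratedImage):
        frames = [frames]
    size = frames[0].pixel_size_um
    stack = np.stack([f.pixels for f in frames]).astype(np.float32)
    px_per_cm = 10000.0 / size
    tifffile.imwrite(
        str(path),
        stack if len(frames) > 1 else stack[0],
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
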