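"""Core image containers and TIFF round-tripping.

All analysis is 2D on maximum-projected fields. Images carry their pixel
size (microns per pixel) so every downstream distance and area is reported
in physical units. Coordinate convention throughout the package: 0-based,
row = y, column = x, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.108
"""Microns per pixel of the reference acquisition (60x, sCMOS, 1x1 binning)."""

CHANNELS = ("DAPI", "DNA", "RNA")


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 2D grayscale image with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities. Stored as float64.
    pixel_size
        Microns per pixel; must be positive.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"expected a 2D image, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_constant(self) -> bool:
        return bool(np.all(self.pixels == self.pixels.flat[0]))


@dataclass
class Acquisition:
    """Co-registered channel images for one imaged field.

    ``channels`` maps channel names (typically DAPI / DNA / RNA) to images
    of identical shape. ``metadata`` records provenance such as an applied
    registration vector.
    """

    channels: dict[str, GrayImage]
    well: str = "A01"
    field: int = 1
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: img.shape for name, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes disagree: {shapes}")

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def __getitem__(self, channel: str) -> GrayImage:
        return self.channels[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels


def read_image(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a single-channel grayscale TIFF (8/16-bit integer or float)."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D single-channel TIFF, got shape {arr.shape}")
    return GrayImage(arr, pixel_size=pixel_size)


def write_image(path: str | Path, img: GrayImage | np.ndarray, dtype=np.uint16) -> None:
    """Write an image as TIFF, clipping into the target integer range."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max)
    tifffile.imwrite(str(path), arr.astype(dtype))


def as_image(data: np.ndarray | GrayImage, pixel_size: float | None = None) -> GrayImage:
    """Coerce an array to :class:`GrayImage`, optionally overriding pixel size."""
    if isinstance(data, GrayImage):
        return data if pixel_size is None else replace(data, pixel_size=pixel_size)
    return GrayImage(np.asarray(data), pixel_size=pixel_size or DEFAULT_PIXEL_SIZE_UM)
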