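"""Reading, writing and 8-bit conversion of grayscale medical images.

The feature backends operate on 8-bit grayscale rasters.  This module
provides the :class:`GrayImage` container used throughout the package,
readers for single-frame DICOM (with rescale slope/intercept applied, so CT
pixels are in Hounsfield units) and 8/16-bit grayscale PNG/TIFF, and the
windowing operator that maps a calibrated intensity range onto [0, 255].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayImage",
    "WindowSpec",
    "BRAIN_WINDOW",
    "read_image",
    "write_image",
    "to_eight_bit",
    "round_half_up",
]


class UnsupportedFormatError(ValueError):
    """Raised for color, multi-frame or otherwise unsupported image inputs."""


@dataclass(frozen=True)
class WindowSpec:
    """Intensity display window (center/width, in the image's units; HU for CT)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @property
    def low(self) -> float:
        return self.center - self.width / 2.0

    @property
    def high(self) -> float:
        return self.center + self.width / 2.0


#: Conventional brain display window used by default for CT input.
BRAIN_WINDOW = WindowSpec(center=40.0, width=80.0)


@dataclass
class GrayImage:
    """A 2-D grayscale raster.

    ``pixels`` is row-major with the origin at the top-left: index ``[y, x]``
    with y increasing downward and x rightward.  ``bit_depth`` is 8 or 16.
    8-bit images hold values in [0, 255]; 16-bit images may hold signed
    calibrated values (e.g. Hounsfield units after DICOM rescale), bounded by
    [-32768, 65535].  ``spacing_mm`` is the optional (row, col) pixel spacing.
    """

    pixels: np.ndarray
    bit_depth: int
    spacing_mm: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = (0, 255) if self.bit_depth == 8 else (-32768, 65535)
        pmin, pmax = self.pixels.min(), self.pixels.max()
        if pmin < lo or pmax > hi:
            raise ValueError(
                f"pixel values [{pmin}, {pmax}] outside the {self.bit_depth}-bit "
                f"range [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.bit_depth, self.spacing_mm)


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves rounded up (toward +inf)."""
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


def _from_array(arr: np.ndarray, spacing_mm=None) -> GrayImage:
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"only single-channel 2-D images are supported, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype in (np.uint16, np.int16):
        depth = 16
    else:
        raise UnsupportedFormatError(f"unsupported pixel dtype {arr.dtype}")
    return GrayImage(arr.astype(np.int32), depth, spacing_mm)


def _read_dicom(path: str) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError("color DICOM is not supported")
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError("multi-frame DICOM is not supported")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    bits = int(getattr(ds, "BitsAllocated", 16))
    depth = 8 if bits <= 8 and slope == 1.0 and intercept == 0.0 else 16
    return GrayImage(np.asarray(round_half_up(arr), dtype=np.int32), depth, spacing)


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a single-frame DICOM or an 8/16-bit grayscale PNG/TIFF.

    DICOM pixel values have the rescale slope/intercept applied (CT values in
    HU) and carry ``spacing_mm`` when PixelSpacing is present.  Color inputs
    are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom", ""):
        return _read_dicom(path)
    if ext in (".tif", ".tiff"):
        return _from_array(tifffile.imread(path))
    if ext == ".png":
        return _from_array(iio.imread(path))
    raise UnsupportedFormatError(f"unsupported file extension {ext!r}")


def write_image(path: str | os.PathLike, img: GrayImage) -> None:
    """Write PNG (unsigned 8/16-bit) or TIFF (8-bit or signed/unsigned 16-bit)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if img.bit_depth == 8:
        arr = img.pixels.astype(np.uint8)
    elif img.pixels.min() < 0:
        arr = img.pixels.astype(np.int16)
    else:
        arr = img.pixels.astype(np.uint16)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif ext == ".png":
        if arr.dtype == np.int16:
            raise UnsupportedFormatError("PNG cannot store signed 16-bit pixels")
        iio.imwrite(path, arr)
    else:
        raise UnsupportedFormatError(f"unsupported file extension {ext!r}")


def to_eight_bit(img: GrayImage, window: WindowSpec | None = None) -> GrayImage:
    """Window an image to 8 bits.

    Maps ``[center - width/2, center + width/2]`` linearly onto [0, 255],
    rounding half up and clipping outside the window.  Without an explicit
    window, 8-bit input is returned unchanged and 16-bit input is min-max
    scaled.  The map is monotone non-decreasing in the input intensity.
    """
    if window is None:
        if img.bit_depth == 8:
            return img.copy()
        lo, hi = float(img.pixels.min()), float(img.pixels.max())
        if hi == lo:
            hi = lo + 1.0
        window = WindowSpec(center=(lo + hi) / 2.0, width=hi - lo)
    scaled = (img.pixels.astype(np.float64) - window.low) / window.width * 255.0
    out = np.clip(round_half_up(scaled), 0, 255).astype(np.int32)
    return GrayImage(out, 8, img.spacing_mm)
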