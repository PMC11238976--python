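"""Degradation operators: Gaussian blur with the kernel-size sigma rule,
and the translation / rotation / scaling series used for robustness testing.

The blur sigma is tied to the (odd) kernel size k by

    sigma(k) = 0.3 * (k/2 - 1) + 0.8

with k/2 evaluated as a real division (k = 3 -> 0.95, k = 21 -> 3.65).
Note this differs from the common library convention
0.3 * ((k - 1)/2 - 1) + 0.8 (which gives 0.8 at k = 3); that variant is
available behind the ``opencv_convention`` flag.

Affine transforms preserve the image dimensions (a requirement for
full-reference comparison), use bilinear interpolation, rotate/scale about
the geometric image centre ((w-1)/2, (h-1)/2), and fill exposed regions
with a constant border value (0 = air, by default).  Positive dx moves
content rightward, positive dy downward, and positive angles rotate content
counter-clockwise in the displayed image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, round_half_up

__all__ = [
    "BlurSpec",
    "AffineSpec",
    "eq_sigma",
    "gaussian_blur",
    "apply_affine",
    "PAPER_BLUR_KERNELS",
    "PAPER_TRANSLATIONS_PX",
    "PAPER_ROTATIONS_DEG",
    "PAPER_REDUCTION_FACTORS",
    "PAPER_ENLARGEMENT_FACTORS",
    "blur_series",
    "translation_series",
    "rotation_series",
    "scale_series",
]

PAPER_BLUR_KERNELS = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21)
PAPER_TRANSLATIONS_PX = (2, 4, 8, 12, 16, 20, 24, 28, 32, 36, 40)
PAPER_ROTATIONS_DEG = (1, 3, 5, 10, 15, 20, 25, 30, 35, 40, 45)
PAPER_REDUCTION_FACTORS = (0.75, 0.8, 0.85, 0.9, 0.95)
PAPER_ENLARGEMENT_FACTORS = (1.05, 1.1, 1.15, 1.2, 1.25)


def eq_sigma(k: int, opencv_convention: bool = False) -> float:
    """Blur sigma from the kernel size: 0.3*(k/2 - 1) + 0.8 for odd k >= 3."""
    if not isinstance(k, (int, np.integer)) or k < 3 or k % 2 == 0:
        raise ValueError(f"kernel size must be an odd integer >= 3, got {k!r}")
    if opencv_convention:
        return 0.3 * ((k - 1) / 2.0 - 1.0) + 0.8
    return 0.3 * (k / 2.0 - 1.0) + 0.8


@dataclass(frozen=True)
class BlurSpec:
    """Gaussian blur of kernel size k; sigma is derived, never free."""

    kernel_size: int
    opencv_convention: bool = False

    def __post_init__(self) -> None:
        eq_sigma(self.kernel_size, self.opencv_convention)  # validates

    @property
    def sigma(self) -> float:
        return eq_sigma(self.kernel_size, self.opencv_convention)


@dataclass(frozen=True)
class AffineSpec:
    """One affine degradation: a translation, a rotation or a scaling."""

    kind: str  # "translate" | "rotate" | "scale"
    dx: float = 0.0
    dy: float = 0.0
    angle: float = 0.0  # degrees, counter-clockwise
    factor: float = 1.0
    border: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("translate", "rotate", "scale"):
            raise ValueError(f"unknown affine kind {self.kind!r}")
        if self.factor <= 0:
            raise ValueError("scale factor must be > 0")

    @property
    def label(self) -> str:
        if self.kind == "translate":
            return f"translate_{self.dx:g}_{self.dy:g}px"
        if self.kind == "rotate":
            return f"rotate_{self.angle:g}deg"
        return f"scale_{self.factor:g}x"


def _gaussian_kernel(k: int, sigma: float) -> np.ndarray:
    half = (k - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    w = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def gaussian_blur(img: GrayImage, spec: BlurSpec | int) -> GrayImage:
    """Separable k x k Gaussian convolution with reflective borders."""
    if isinstance(spec, (int, np.integer)):
        spec = BlurSpec(int(spec))
    kern = _gaussian_kernel(spec.kernel_size, spec.sigma)
    out = ndimage.convolve1d(img.pixels.astype(np.float64), kern, axis=0,
                             mode="reflect")
    out = ndimage.convolve1d(out, kern, axis=1, mode="reflect")
    lo, hi = (0, 255) if img.bit_depth == 8 else (-32768, 65535)
    pixels = np.clip(round_half_up(out), lo, hi).astype(np.int32)
    return GrayImage(pixels, img.bit_depth, img.spacing_mm)


def _affine_matrix(spec: AffineSpec, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map (output -> input) as matrix/offset in (row, col) order."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if spec.kind == "translate":
        return np.eye(2), np.array([-spec.dy, -spec.dx], dtype=np.float64)
    if spec.kind == "rotate":
        # content rotates CCW on screen (y down): inverse maps output->input
        th = np.radians(spec.angle)
        c, s = np.cos(th), np.sin(th)
        m = np.array([[c, -s], [s, c]], dtype=np.float64)
    else:
        m = np.eye(2) / spec.factor
    offset = np.array([cy, cx]) - m @ np.array([cy, cx])
    return m, offset


def apply_affine(img: GrayImage, spec: AffineSpec) -> GrayImage:
    """Apply one affine transform, keeping the image dimensions.

    Identity parameters (zero shift, zero angle, unit factor) return a
    bit-identical image.  Bilinear interpolation; exposed regions take the
    constant border value.
    """
    identity = (
        (spec.kind == "translate" and spec.dx == 0 and spec.dy == 0)
        or (spec.kind == "rotate" and spec.angle == 0)
        or (spec.kind == "scale" and spec.factor == 1)
    )
    if identity:
        return img.copy()
    m, offset = _affine_matrix(spec, img.shape)
    out = ndimage.affine_transform(
        img.pixels.astype(np.float64), m, offset=offset, order=1,
        mode="constant", cval=spec.border, output_shape=img.shape,
    )
    lo, hi = (0, 255) if img.bit_depth == 8 else (-32768, 65535)
    pixels = np.clip(round_half_up(out), lo, hi).astype(np.int32)
    return GrayImage(pixels, img.bit_depth, img.spacing_mm)


def blur_series(kernels=PAPER_BLUR_KERNELS) -> list[BlurSpec]:
    return [BlurSpec(int(k)) for k in kernels]


def translation_series(shifts=PAPER_TRANSLATIONS_PX) -> list[AffineSpec]:
    """Horizontal translations by the given pixel amounts."""
    return [AffineSpec(kind="translate", dx=float(s)) for s in shifts]


def rotation_series(angles=PAPER_ROTATIONS_DEG) -> list[AffineSpec]:
    return [AffineSpec(kind="rotate", angle=float(a)) for a in angles]


def scale_series(factors) -> list[AffineSpec]:
    return [AffineSpec(kind="scale", factor=float(f)) for f in factors]
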