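"""Conventional full-reference comparators: SSIM and PSNR.

These serve as the external criteria against which the keypoint-feature
index is validated.  SSIM follows the standard local-statistics formulation
(sliding window means, variances and covariance with the C1/C2 stabilisers),
averaged over all window positions; PSNR is 10 log10(peak^2 / MSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import GrayImage

__all__ = ["SSIMParams", "ssim", "ssim_map", "psnr"]


@dataclass(frozen=True)
class SSIMParams:
    """Window size, stabilisation constants and dynamic range for SSIM."""

    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 255.0
    gaussian_weighted: bool = False

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("K1 and K2 must be > 0")


def _as_float(img: GrayImage | np.ndarray) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels.astype(np.float64)
    return np.asarray(img, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def ssim_map(ref: GrayImage | np.ndarray, tgt: GrayImage | np.ndarray,
             params: SSIMParams | None = None) -> np.ndarray:
    """Local SSIM map from sliding-window statistics."""
    params = params or SSIMParams()
    x, y = _as_float(ref), _as_float(tgt)
    _check_shapes(x, y)

    if params.gaussian_weighted:
        sigma = (params.window - 1) / 6.0  # +/- 3 sigma spans the window
        def filt(a):
            return ndimage.gaussian_filter(a, sigma=sigma, mode="reflect",
                                           truncate=3.0)
    else:
        def filt(a):
            return ndimage.uniform_filter(a, size=params.window, mode="reflect")

    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2

    mu_x, mu_y = filt(x), filt(y)
    var_x = filt(x * x) - mu_x * mu_x
    var_y = filt(y * y) - mu_y * mu_y
    cov = filt(x * y) - mu_x * mu_y

    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return num / den


def ssim(ref: GrayImage | np.ndarray, tgt: GrayImage | np.ndarray,
         params: SSIMParams | None = None) -> float:
    """Mean structural similarity between two equally shaped images, in [-1, 1]."""
    return float(ssim_map(ref, tgt, params).mean())


def psnr(ref: GrayImage | np.ndarray, tgt: GrayImage | np.ndarray,
         data_range: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    x, y = _as_float(ref), _as_float(tgt)
    _check_shapes(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))
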