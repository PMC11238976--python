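"""Synthetic head-CT phantom and dose-dependent quantum-noise emulation.

A reconstructed head CT slice is emulated as a bright elliptical skull ring
surrounding near-uniform brain-like tissue scattered with low-contrast
elliptical structures, on an air background, with intensities in Hounsfield
units.  Quantum noise is modelled as additive white Gaussian noise whose
standard deviation scales as the inverse square root of the dose index
(CTDI_vol), the first-order behaviour of photon noise after filtered back
projection.  Both generators are fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import BRAIN_WINDOW, GrayImage, WindowSpec, round_half_up, to_eight_bit

__all__ = [
    "PhantomSpec",
    "DoseNoiseSpec",
    "PAPER_CTDI_SERIES",
    "REFERENCE_CTDI",
    "generate_head_phantom",
    "simulate_dose_noise",
    "noise_sigma",
]

#: CTDI_vol values (mGy) of the emulated low-dose target series.
PAPER_CTDI_SERIES = (2.7, 5.5, 13.7, 21.9, 27.4, 35.6, 41.0, 53.4, 59.4, 74.2)

#: CTDI_vol (mGy) of the high-quality reference acquisition.
REFERENCE_CTDI = 89.1

_HU_AIR = -1000
_HU_BONE = 800


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of the synthetic head slice.

    Radii are fractions of the image side.  ``n_structures`` low-contrast
    ellipses at ``tissue_mean +/- structure_contrast`` HU are placed without
    overlap inside the skull; small high-curvature ellipses are what give the
    corner/blob detectors something to latch onto.
    """

    size: int = 512
    skull_outer: float = 0.45
    skull_inner: float = 0.40
    tissue_mean: float = 40.0
    n_structures: int = 60
    structure_contrast: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.skull_inner < self.skull_outer < 0.5):
            raise ValueError("need 0 < skull_inner < skull_outer < 0.5")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")
        if self.size < 32:
            raise ValueError("size must be >= 32")


@dataclass(frozen=True)
class DoseNoiseSpec:
    """Dose-indexed Gaussian noise: sigma = sigma_at_ref * sqrt(ref_ctdi/ctdi)."""

    ctdi: float
    ref_ctdi: float = REFERENCE_CTDI
    sigma_at_ref: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ctdi > 0:
            raise ValueError(f"ctdi must be > 0 mGy, got {self.ctdi}")
        if not self.ref_ctdi > 0 or not self.sigma_at_ref > 0:
            raise ValueError("ref_ctdi and sigma_at_ref must be > 0")

    @property
    def sigma(self) -> float:
        return noise_sigma(self.ctdi, self.ref_ctdi, self.sigma_at_ref)


def noise_sigma(ctdi: float, ref_ctdi: float = REFERENCE_CTDI,
                sigma_at_ref: float = 3.0) -> float:
    """Noise standard deviation at dose ``ctdi`` under the 1/sqrt(dose) law."""
    if ctdi <= 0:
        raise ValueError(f"ctdi must be > 0 mGy, got {ctdi}")
    return float(sigma_at_ref * np.sqrt(ref_ctdi / ctdi))


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_head_phantom(spec: PhantomSpec | None = None) -> GrayImage:
    """Render the synthetic head slice as a 16-bit image in HU.

    The skull ring and head outline are ellipses with a 0.82 lateral aspect
    ratio (heads are longer front-to-back than side-to-side).  Interior
    structures are placed by seeded rejection sampling so they never overlap
    each other or the skull; with ``n_structures = 0`` the interior is exactly
    uniform tissue.  Everything is lightly smoothed (sigma 0.7 px) to emulate
    the band-limit of a reconstruction kernel, then rounded to integer HU.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    c = (n - 1) / 2.0
    aspect = 0.82

    r_out, r_in = spec.skull_outer * n, spec.skull_inner * n
    outer = _ellipse_mask(n, c, c, r_out, r_out * aspect, 0.0)
    inner = _ellipse_mask(n, c, c, r_in, r_in * aspect, 0.0)

    hu = np.full((n, n), float(_HU_AIR))
    hu[outer] = _HU_BONE
    hu[inner] = spec.tissue_mean

    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    attempts = 0
    count = 0
    while count < spec.n_structures and attempts < spec.n_structures * 200:
        attempts += 1
        ry = rng.uniform(0.008, 0.035) * n
        rx = rng.uniform(0.008, 0.035) * n
        theta = rng.uniform(0.0, np.pi)
        rad = max(ry, rx)
        # centre restricted so the ellipse stays well inside the skull
        ang = rng.uniform(0.0, 2 * np.pi)
        rho = np.sqrt(rng.uniform(0.0, 1.0))
        cy = c + rho * (r_in * 0.88 - rad) * np.sin(ang)
        cx = c + rho * (r_in * 0.88 - rad) * aspect * np.cos(ang)
        if any(np.hypot(cy - py, cx - px) < rad + pr + 2 for py, px, pr in placed):
            continue
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        mask = _ellipse_mask(n, cy, cx, ry, rx, theta)
        hu[mask] = spec.tissue_mean + sign * spec.structure_contrast
        placed.append((cy, cx, rad))
        count += 1

    hu = ndimage.gaussian_filter(hu, sigma=0.7, mode="nearest")
    pixels = np.clip(round_half_up(hu), -32768, 65535).astype(np.int32)
    return GrayImage(pixels, 16)


def simulate_dose_noise(img: GrayImage, spec: DoseNoiseSpec) -> GrayImage:
    """Add dose-indexed zero-mean Gaussian noise, clipping at the range edges."""
    rng = np.random.default_rng(spec.seed)
    noisy = img.pixels.astype(np.float64) + rng.normal(0.0, spec.sigma, img.shape)
    lo, hi = (0, 255) if img.bit_depth == 8 else (-32768, 65535)
    pixels = np.clip(round_half_up(noisy), lo, hi).astype(np.int32)
    return GrayImage(pixels, img.bit_depth, img.spacing_mm)


def default_reference_image(spec: PhantomSpec | None = None,
                            noise: DoseNoiseSpec | None = None,
                            window: WindowSpec = BRAIN_WINDOW) -> GrayImage:
    """Convenience: phantom + reference-dose noise, windowed to 8 bits."""
    clean = generate_head_phantom(spec)
    if noise is None:
        noise = DoseNoiseSpec(ctdi=REFERENCE_CTDI, seed=(spec.seed if spec else 0) + 1)
    return to_eight_bit(simulate_dose_noise(clean, noise), window)
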