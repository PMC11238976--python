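"""Keypoint detection and binary descriptor extraction.

Four interchangeable backends produce index-aligned keypoints and
fixed-length binary descriptors from an 8-bit grayscale image:

``orb``
    scikit-image's ORB (multi-scale FAST with Harris ranking and rotated
    BRIEF), 256 bits, capped at 500 keypoints by default.
``brisk``
    An in-repo BRISK-style backend: multi-scale FAST (segment test, 9
    contiguous of 16) with the concentric 60-point sampling pattern, gradient
    based orientation from long-distance point pairs and 512 short-distance
    intensity comparisons.
``akaze``
    An in-repo AKAZE-style backend: Perona-Malik nonlinear diffusion scale
    space, scale-normalised determinant-of-Hessian detection, and the
    M-LDB descriptor (2x2 + 3x3 + 4x4 grids, intensity/dx/dy channels,
    486 bits).
``ref``
    A deliberately small, fully self-contained backend used as the package's
    library-independent oracle: single-scale segment-test corners plus a
    BRIEF-style descriptor with a frozen seeded sampling pattern (256 bits).

All backends are deterministic: identical input images yield bit-identical
keypoints and descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import GrayImage

__all__ = [
    "Keypoint",
    "DescriptorSet",
    "BackendParams",
    "BACKENDS",
    "BIT_LENGTHS",
    "detect_and_describe",
    "reference_detect_describe",
    "default_params",
]

BACKENDS = ("akaze", "brisk", "orb", "ref")

#: Descriptor bit length per backend; the scale of the quality index depends
#: on it, so it is asserted rather than inferred.
BIT_LENGTHS = {"orb": 256, "brisk": 512, "akaze": 486, "ref": 256}


@dataclass(frozen=True)
class Keypoint:
    """A salient image location (0-based; x = column, y = row, sub-pixel allowed)."""

    x: float
    y: float
    scale: float = 1.0
    orientation: float = 0.0  # degrees in [0, 360)
    response: float = 0.0


@dataclass
class DescriptorSet:
    """N binary descriptors of L bits each, index-aligned with keypoints."""

    bits: np.ndarray  # (N, L) bool
    backend_id: str

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            self.bits = self.bits.reshape(0, BIT_LENGTHS[self.backend_id])
        expected = BIT_LENGTHS[self.backend_id]
        if self.bits.shape[1] != expected:
            raise ValueError(
                f"{self.backend_id} descriptors must have {expected} bits, "
                f"got {self.bits.shape[1]}"
            )

    @property
    def n(self) -> int:
        return int(self.bits.shape[0])

    @property
    def bit_length(self) -> int:
        return int(self.bits.shape[1])

    def packed(self) -> np.ndarray:
        """Descriptors packed 8 bits per byte, for fast Hamming arithmetic."""
        return np.packbits(self.bits, axis=1) if self.n else np.zeros(
            (0, self.bit_length // 8), dtype=np.uint8)


@dataclass(frozen=True)
class BackendParams:
    """Backend selection plus the few knobs shared across backends.

    ``threshold`` is backend-specific (FAST intensity step for brisk/ref,
    Hessian response for akaze, relative FAST threshold for orb); ``None``
    selects the backend's default.  ``max_keypoints`` keeps the strongest
    responses; ORB defaults to a 500-keypoint cap, the others to no cap.
    """

    backend_id: str = "orb"
    max_keypoints: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "backend_id", self.backend_id.lower())
        if self.backend_id not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend_id!r}; choose from {BACKENDS}")
        if self.max_keypoints is not None and self.max_keypoints < 1:
            raise ValueError("max_keypoints must be >= 1 when set")


_DEFAULT_THRESHOLDS = {"orb": 0.08, "brisk": 30.0, "akaze": 1e-4, "ref": 20.0}
_DEFAULT_CAPS = {"orb": 500, "brisk": None, "akaze": None, "ref": None}


def default_params(backend_id: str) -> BackendParams:
    bid = backend_id.lower()
    return BackendParams(backend_id=bid, max_keypoints=_DEFAULT_CAPS[bid],
                         threshold=_DEFAULT_THRESHOLDS[bid])


def _require_8bit(img: GrayImage) -> np.ndarray:
    if img.bit_depth != 8:
        raise ValueError("feature backends require an 8-bit image; window it first")
    return img.pixels.astype(np.float32)


# ---------------------------------------------------------------------------
# FAST segment test (shared by the ref and brisk backends)
# ---------------------------------------------------------------------------

# Bresenham circle of radius 3, in circular order, as (dy, dx).
_FAST_RING = np.array(
    [(0, 3), (1, 3), (2, 2), (3, 1), (3, 0), (3, -1), (2, -2), (1, -3),
     (0, -3), (-1, -3), (-2, -2), (-3, -1), (-3, 0), (-3, 1), (-2, 2), (-1, 3)],
    dtype=np.int64,
)


def fast_corners(image: np.ndarray, threshold: float, n_contig: int = 9,
                 border: int = 4, subpixel: bool = False
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment-test corner detection with 3x3 non-maximum suppression.

    A pixel is a corner when at least ``n_contig`` contiguous pixels on the
    radius-3 Bresenham circle are all brighter than centre + threshold or all
    darker than centre - threshold.  Returns (ys, xs, responses).
    """
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape
    ring = np.stack([np.roll(img, (-dy, -dx), axis=(0, 1)) for dy, dx in _FAST_RING])
    diff = ring - img[None]
    bright = diff > threshold
    dark = diff < -threshold

    def _has_arc(flags: np.ndarray) -> np.ndarray:
        doubled = np.concatenate([flags, flags[: n_contig - 1]], axis=0)
        out = np.zeros(img.shape, dtype=bool)
        for j in range(len(_FAST_RING)):
            out |= np.logical_and.reduce(doubled[j: j + n_contig], axis=0)
        return out

    corner = _has_arc(bright) | _has_arc(dark)
    corner[:border] = corner[-border:] = False
    corner[:, :border] = corner[:, -border:] = False

    response = np.maximum(np.abs(diff) - threshold, 0.0).sum(axis=0)
    masked = np.where(corner, response, 0.0)
    local_max = masked == ndimage.maximum_filter(masked, size=3)
    keep = corner & local_max
    ys, xs = np.nonzero(keep)
    resp = response[ys, xs]
    if subpixel:
        yf, xf = subpixel_refine(response, ys, xs)
        return yf, xf, resp
    return ys, xs, resp


def subpixel_refine(response: np.ndarray, ys: np.ndarray, xs: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic sub-pixel localisation of response-map peaks.

    Fits a 1-D parabola through the peak and its two neighbours along each
    axis; offsets are clamped to [-0.5, 0.5] and fall back to 0 where the
    local curvature does not describe a maximum.  Keeps coarse-scale
    detections from being quantised to the octave grid.
    """
    def offs(minus, centre, plus):
        denom = minus - 2.0 * centre + plus
        with np.errstate(divide="ignore", invalid="ignore"):
            o = 0.5 * (minus - plus) / denom
        o = np.where((denom < 0) & np.isfinite(o), o, 0.0)
        return np.clip(o, -0.5, 0.5)

    dy = offs(response[ys - 1, xs], response[ys, xs], response[ys + 1, xs])
    dx = offs(response[ys, xs - 1], response[ys, xs], response[ys, xs + 1])
    return ys + dy, xs + dx


# ---------------------------------------------------------------------------
# ref backend: segment-test corners + BRIEF-style frozen sampling pattern
# ---------------------------------------------------------------------------

def _brief_pattern(n_bits: int = 256, half: int = 13, seed: int = 20240612):
    """Frozen pairwise sampling offsets (Gaussian, clipped to the patch)."""
    rng = np.random.default_rng(seed)
    a = np.clip(np.round(rng.normal(0.0, half / 2.5, size=(n_bits, 2))), -half, half)
    b = np.clip(np.round(rng.normal(0.0, half / 2.5, size=(n_bits, 2))), -half, half)
    return a.astype(np.int64), b.astype(np.int64)


_BRIEF_A, _BRIEF_B = _brief_pattern()
_REF_MARGIN = 16


def reference_detect_describe(
    img: GrayImage, params: BackendParams | None = None
) -> tuple[list[Keypoint], DescriptorSet]:
    """Self-contained oracle backend: FAST corners + 256-bit BRIEF-style bits.

    The descriptor compares pairs of Gaussian-smoothed intensities at frozen
    offsets, so it is invariant to a uniform intensity shift of the patch.
    No orientation or scale handling: single scale, upright descriptors.
    """
    params = params or default_params("ref")
    pix = _require_8bit(img)
    t = params.threshold if params.threshold is not None else _DEFAULT_THRESHOLDS["ref"]
    ys, xs, resp = fast_corners(pix, threshold=t, border=_REF_MARGIN)
    if len(ys) == 0:
        return [], DescriptorSet(np.zeros((0, 256), dtype=bool), "ref")

    order = np.lexsort((xs, ys))  # deterministic ordering
    ys, xs, resp = ys[order], xs[order], resp[order]
    if params.max_keypoints is not None and len(ys) > params.max_keypoints:
        top = np.argsort(-resp, kind="stable")[: params.max_keypoints]
        top.sort()
        ys, xs, resp = ys[top], xs[top], resp[top]

    smooth = ndimage.gaussian_filter(pix, sigma=2.0, mode="nearest")
    ya = ys[:, None] + _BRIEF_A[None, :, 0]
    xa = xs[:, None] + _BRIEF_A[None, :, 1]
    yb = ys[:, None] + _BRIEF_B[None, :, 0]
    xb = xs[:, None] + _BRIEF_B[None, :, 1]
    bits = smooth[ya, xa] < smooth[yb, xb]

    kps = [Keypoint(float(x), float(y), 1.0, 0.0, float(r))
           for x, y, r in zip(xs, ys, resp)]
    return kps, DescriptorSet(bits, "ref")


# ---------------------------------------------------------------------------
# brisk backend: multi-scale FAST + concentric sampling pattern
# ---------------------------------------------------------------------------

def _brisk_pattern():
    """Concentric sampling pattern: 60 points on rings, with per-ring smoothing.

    Returns (points (60,2) as (x,y), sigmas (60,), short_pairs (512,2),
    long_pairs (M,2)).  Short pairs are the 512 closest point pairs; long
    pairs (separation > 13.67) drive the orientation estimate.
    """
    radii = (0.0, 2.9, 4.9, 7.4, 10.8)
    counts = (1, 10, 14, 15, 20)
    sigmas = (0.55, 0.9, 1.25, 1.8, 2.5)
    pts, sig = [], []
    for ridx, (r, c, s) in enumerate(zip(radii, counts, sigmas)):
        ang = 2 * np.pi * np.arange(c) / c + (np.pi / c if ridx % 2 else 0.0)
        pts.append(np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1))
        sig.extend([s] * c)
    points = np.concatenate(pts, axis=0)
    sigmas_pt = np.asarray(sig)
    iu, ju = np.triu_indices(len(points), k=1)
    dist = np.hypot(*(points[iu] - points[ju]).T)
    order = np.argsort(dist, kind="stable")
    short = np.stack([iu[order[:512]], ju[order[:512]]], axis=1)
    long_mask = dist > 13.67
    long_pairs = np.stack([iu[long_mask], ju[long_mask]], axis=1)
    return points, sigmas_pt, short, long_pairs


_BRISK_PTS, _BRISK_SIGMAS, _BRISK_SHORT, _BRISK_LONG = _brisk_pattern()


def _sample_pattern(blur_cache: dict, pix: np.ndarray, xs, ys, scales, angles_rad):
    """Sample the 60-point pattern for every keypoint (vectorised per ring sigma)."""
    n = len(xs)
    values = np.zeros((n, len(_BRISK_PTS)), dtype=np.float32)
    cos, sin = np.cos(angles_rad), np.sin(angles_rad)
    for s_pat in np.unique(_BRISK_SIGMAS):
        sel = np.nonzero(_BRISK_SIGMAS == s_pat)[0]
        px, py = _BRISK_PTS[sel, 0], _BRISK_PTS[sel, 1]
        # per-keypoint rotation and scaling of the pattern offsets
        rx = scales[:, None] * (cos[:, None] * px[None] - sin[:, None] * py[None])
        ry = scales[:, None] * (sin[:, None] * px[None] + cos[:, None] * py[None])
        for s_img in np.unique(np.round(s_pat * scales, 2)):
            ksel = np.nonzero(np.round(s_pat * scales, 2) == s_img)[0]
            if s_img not in blur_cache:
                blur_cache[s_img] = ndimage.gaussian_filter(pix, sigma=float(s_img),
                                                            mode="nearest")
            blur = blur_cache[s_img]
            coords_y = ys[ksel, None] + ry[ksel]
            coords_x = xs[ksel, None] + rx[ksel]
            sampled = ndimage.map_coordinates(
                blur, [coords_y.ravel(), coords_x.ravel()], order=1, mode="nearest"
            ).reshape(len(ksel), len(sel))
            values[np.ix_(ksel, sel)] = sampled
    return values


def _brisk_detect_describe(
    img: GrayImage, params: BackendParams
) -> tuple[list[Keypoint], DescriptorSet]:
    pix = _require_8bit(img)
    t = params.threshold if params.threshold is not None else _DEFAULT_THRESHOLDS["brisk"]
    n_octaves = 4

    all_x, all_y, all_s, all_r = [], [], [], []
    level = pix
    for o in range(n_octaves):
        scale = float(2 ** o)
        margin = int(np.ceil(14 * 1.0)) + 3  # pattern radius + ring radius, octave px
        if min(level.shape) < 2 * margin + 8:
            break
        ys, xs, resp = fast_corners(level, threshold=t, border=margin,
                                    subpixel=True)
        if len(ys):
            order = np.lexsort((xs, ys))
            ys, xs, resp = ys[order], xs[order], resp[order]
            all_x.append(xs * scale)
            all_y.append(ys * scale)
            all_s.append(np.full(len(xs), scale))
            all_r.append(resp)
        level = ndimage.gaussian_filter(level, sigma=1.0, mode="nearest")[::2, ::2]

    if not all_x:
        return [], DescriptorSet(np.zeros((0, 512), dtype=bool), "brisk")
    xs = np.concatenate(all_x)
    ys = np.concatenate(all_y)
    scales = np.concatenate(all_s)
    resp = np.concatenate(all_r)

    if params.max_keypoints is not None and len(xs) > params.max_keypoints:
        top = np.argsort(-resp, kind="stable")[: params.max_keypoints]
        top.sort()
        xs, ys, scales, resp = xs[top], ys[top], scales[top], resp[top]

    blur_cache: dict = {}
    upright = _sample_pattern(blur_cache, pix, xs, ys, scales, np.zeros(len(xs)))

    # orientation from long-distance pairs: mean local gradient of the pattern
    i, j = _BRISK_LONG[:, 0], _BRISK_LONG[:, 1]
    dpts = _BRISK_PTS[j] - _BRISK_PTS[i]
    norm2 = (dpts ** 2).sum(axis=1)
    dv = (upright[:, j] - upright[:, i]) / norm2[None]
    gx = (dv * dpts[None, :, 0]).sum(axis=1)
    gy = (dv * dpts[None, :, 1]).sum(axis=1)
    angles = np.arctan2(gy, gx)

    rotated = _sample_pattern(blur_cache, pix, xs, ys, scales, angles)
    si, sj = _BRISK_SHORT[:, 0], _BRISK_SHORT[:, 1]
    bits = rotated[:, si] < rotated[:, sj]

    deg = np.degrees(angles) % 360.0
    kps = [Keypoint(float(x), float(y), float(s), float(a), float(r))
           for x, y, s, a, r in zip(xs, ys, scales, deg, resp)]
    return kps, DescriptorSet(bits, "brisk")


# ---------------------------------------------------------------------------
# akaze backend: nonlinear diffusion scale space + Hessian + M-LDB
# ---------------------------------------------------------------------------

def _pm_g2(grad_sq: np.ndarray, k: float) -> np.ndarray:
    """Perona-Malik edge-stopping conductivity g2 = 1 / (1 + |grad L|^2 / k^2)."""
    return 1.0 / (1.0 + grad_sq / (k * k))


def _diffusion_step(L: np.ndarray, g: np.ndarray, tau: float) -> np.ndarray:
    """One explicit step of L_t = div(g grad L) with Neumann borders."""
    Lp = np.pad(L, 1, mode="edge")
    gp = np.pad(g, 1, mode="edge")
    c = slice(1, -1)
    flux = (
        (gp[c, 2:] + gp[c, c]) * (Lp[c, 2:] - Lp[c, c])
        - (gp[c, c] + gp[c, :-2]) * (Lp[c, c] - Lp[c, :-2])
        + (gp[2:, c] + gp[c, c]) * (Lp[2:, c] - Lp[c, c])
        - (gp[c, c] + gp[:-2, c]) * (Lp[c, c] - Lp[:-2, c])
    )
    return L + tau * 0.5 * flux


def _contrast_factor(pix01: np.ndarray, percentile: float = 70.0) -> float:
    sm = ndimage.gaussian_filter(pix01, sigma=1.0, mode="nearest")
    gy, gx = np.gradient(sm)
    mag = np.hypot(gx, gy)
    mag = mag[mag > 0]
    if mag.size == 0:
        return 0.01
    return float(max(np.percentile(mag, percentile), 1e-6))


def _ldb_pairs(grid: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(grid * grid, k=1)
    return i, j


_LDB_GRIDS = (2, 3, 4)
_LDB_PAIRS = {g: _ldb_pairs(g) for g in _LDB_GRIDS}
_LDB_SAMPLES = 24  # divisible by 2, 3 and 4


def _akaze_descriptors(pix01, xs, ys, sigmas, angles, blur_cache):
    """M-LDB: cell means of intensity/dx/dy on 2x2, 3x3, 4x4 grids -> 486 bits."""
    n = len(xs)
    bits = np.zeros((n, BIT_LENGTHS["akaze"]), dtype=bool)
    cos, sin = np.cos(angles), np.sin(angles)
    # unrotated unit sample grid in [-1, 1]
    lin = (np.arange(_LDB_SAMPLES) + 0.5) / _LDB_SAMPLES * 2.0 - 1.0
    gy, gx = np.meshgrid(lin, lin, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()

    for s_img in np.unique(np.round(sigmas, 2)):
        ksel = np.nonzero(np.round(sigmas, 2) == s_img)[0]
        key = ("akaze", float(s_img))
        if key not in blur_cache:
            sm = ndimage.gaussian_filter(pix01, sigma=float(s_img), mode="nearest")
            dy, dx = np.gradient(sm)
            blur_cache[key] = (sm, dx, dy)
        sm, dxim, dyim = blur_cache[key]
        half = 10.0 * s_img
        rx = half * (cos[ksel, None] * gx[None] - sin[ksel, None] * gy[None])
        ry = half * (sin[ksel, None] * gx[None] + cos[ksel, None] * gy[None])
        cy = (ys[ksel, None] + ry).ravel()
        cx = (xs[ksel, None] + rx).ravel()
        shape = (len(ksel), _LDB_SAMPLES * _LDB_SAMPLES)
        vals = ndimage.map_coordinates(sm, [cy, cx], order=1, mode="nearest").reshape(shape)
        vdx = ndimage.map_coordinates(dxim, [cy, cx], order=1, mode="nearest").reshape(shape)
        vdy = ndimage.map_coordinates(dyim, [cy, cx], order=1, mode="nearest").reshape(shape)
        # rotate gradient vectors into the keypoint frame
        rdx = cos[ksel, None] * vdx + sin[ksel, None] * vdy
        rdy = -sin[ksel, None] * vdx + cos[ksel, None] * vdy

        out_col = 0
        for g in _LDB_GRIDS:
            cell = _LDB_SAMPLES // g
            def cell_means(v):
                return (v.reshape(len(ksel), g, cell, g, cell)
                        .mean(axis=(2, 4)).reshape(len(ksel), g * g))
            pi, pj = _LDB_PAIRS[g]
            for chan in (vals, rdx, rdy):
                m = cell_means(chan.reshape(len(ksel), _LDB_SAMPLES, _LDB_SAMPLES))
                bits[ksel, out_col: out_col + len(pi)] = m[:, pi] > m[:, pj]
                out_col += len(pi)
    return bits


def _akaze_detect_describe(
    img: GrayImage, params: BackendParams
) -> tuple[list[Keypoint], DescriptorSet]:
    pix = _require_8bit(img) / 255.0
    threshold = params.threshold if params.threshold is not None else _DEFAULT_THRESHOLDS["akaze"]
    n_octaves, n_sub = 4, 4
    sigma0, tau = 1.6, 0.2
    k = _contrast_factor(pix)

    cand_x, cand_y, cand_s, cand_r = [], [], [], []
    L = ndimage.gaussian_filter(pix, sigma=sigma0, mode="nearest")
    for o in range(n_octaves):
        oct_scale = float(2 ** o)
        if min(L.shape) < 40:
            break
        t_prev = sigma0 ** 2 / 2.0
        for s in range(n_sub):
            sigma_loc = sigma0 * 2 ** (s / n_sub)
            if s > 0:
                t_target = sigma_loc ** 2 / 2.0
                n_steps = max(1, int(np.ceil((t_target - t_prev) / tau)))
                step = (t_target - t_prev) / n_steps
                for _ in range(n_steps):
                    smooth = ndimage.gaussian_filter(L, sigma=1.0, mode="nearest")
                    gy, gx = np.gradient(smooth)
                    g = _pm_g2(gx * gx + gy * gy, k)
                    L = _diffusion_step(L, g, step)
                t_prev = t_target
            gy, gx = np.gradient(L)
            gxy, gxx = np.gradient(gx)
            gyy, _ = np.gradient(gy)
            resp = (sigma_loc ** 4) * (gxx * gyy - gxy * gxy)
            margin = int(np.ceil(10.0 * sigma_loc)) + 2
            if min(resp.shape) < 2 * margin + 4:
                continue
            maxed = resp == ndimage.maximum_filter(resp, size=3)
            keep = maxed & (resp > threshold)
            keep[:margin] = keep[-margin:] = False
            keep[:, :margin] = keep[:, -margin:] = False
            ys, xs = np.nonzero(keep)
            if len(ys):
                order = np.lexsort((xs, ys))
                ys, xs = ys[order], xs[order]
                rvals = resp[ys, xs]
                yf, xf = subpixel_refine(resp, ys, xs)
                cand_x.append(xf * oct_scale)
                cand_y.append(yf * oct_scale)
                cand_s.append(np.full(len(xs), sigma_loc * oct_scale))
                cand_r.append(rvals)
        L = L[::2, ::2]

    if not cand_x:
        return [], DescriptorSet(np.zeros((0, 486), dtype=bool), "akaze")
    xs = np.concatenate(cand_x)
    ys = np.concatenate(cand_y)
    sigmas = np.concatenate(cand_s)
    resp = np.concatenate(cand_r)

    # suppress duplicates found at neighbouring evolution levels
    order = np.argsort(-resp, kind="stable")
    taken = np.zeros(len(xs), dtype=bool)
    kept: list[int] = []
    from scipy.spatial import cKDTree

    tree = cKDTree(np.stack([xs, ys], axis=1))
    for idx in order:
        if taken[idx]:
            continue
        kept.append(idx)
        for nb in tree.query_ball_point([xs[idx], ys[idx]], r=3.0):
            taken[nb] = True
    kept_arr = np.sort(np.asarray(kept))
    xs, ys, sigmas, resp = xs[kept_arr], ys[kept_arr], sigmas[kept_arr], resp[kept_arr]

    # drop keypoints whose descriptor patch would leave the image
    half = 10.0 * sigmas * np.sqrt(2.0)
    h, w = pix.shape
    ok = ((xs - half >= 0) & (xs + half < w) & (ys - half >= 0) & (ys + half < h))
    xs, ys, sigmas, resp = xs[ok], ys[ok], sigmas[ok], resp[ok]

    if params.max_keypoints is not None and len(xs) > params.max_keypoints:
        top = np.argsort(-resp, kind="stable")[: params.max_keypoints]
        top.sort()
        xs, ys, sigmas, resp = xs[top], ys[top], sigmas[top], resp[top]

    if len(xs) == 0:
        return [], DescriptorSet(np.zeros((0, 486), dtype=bool), "akaze")

    blur_cache: dict = {}
    # orientation: gaussian-weighted mean gradient around the keypoint
    angles = np.zeros(len(xs))
    for s_img in np.unique(np.round(sigmas, 2)):
        ksel = np.nonzero(np.round(sigmas, 2) == s_img)[0]
        key = ("akaze", float(s_img))
        if key not in blur_cache:
            sm = ndimage.gaussian_filter(pix, sigma=float(s_img), mode="nearest")
            dy, dx = np.gradient(sm)
            blur_cache[key] = (sm, dx, dy)
        _, dxim, dyim = blur_cache[key]
        gxv = ndimage.map_coordinates(dxim, [ys[ksel], xs[ksel]], order=1, mode="nearest")
        gyv = ndimage.map_coordinates(dyim, [ys[ksel], xs[ksel]], order=1, mode="nearest")
        angles[ksel] = np.arctan2(gyv, gxv)

    bits = _akaze_descriptors(pix, xs, ys, np.round(sigmas, 2), angles, blur_cache)
    deg = np.degrees(angles) % 360.0
    kps = [Keypoint(float(x), float(y), float(s), float(a), float(r))
           for x, y, s, a, r in zip(xs, ys, sigmas, deg, resp)]
    return kps, DescriptorSet(bits, "akaze")


# ---------------------------------------------------------------------------
# orb backend (scikit-image)
# ---------------------------------------------------------------------------

def _orb_detect_describe(
    img: GrayImage, params: BackendParams
) -> tuple[list[Keypoint], DescriptorSet]:
    from skimage.feature import ORB

    pix = _require_8bit(img) / 255.0
    cap = params.max_keypoints if params.max_keypoints is not None else 500
    t = params.threshold if params.threshold is not None else _DEFAULT_THRESHOLDS["orb"]
    orb = ORB(n_keypoints=cap, fast_threshold=t)
    try:
        orb.detect_and_extract(pix)
    except RuntimeError:  # skimage raises when no keypoints survive
        return [], DescriptorSet(np.zeros((0, 256), dtype=bool), "orb")
    kp = orb.keypoints  # (N, 2) as (row, col)
    scales = orb.scales
    orients = np.degrees(orb.orientations) % 360.0
    resp = getattr(orb, "responses", np.zeros(len(kp)))
    kps = [Keypoint(float(c), float(r), float(s), float(a), float(v))
           for (r, c), s, a, v in zip(kp, scales, orients, resp)]
    return kps, DescriptorSet(orb.descriptors, "orb")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_BACKEND_FUNCS = {
    "orb": _orb_detect_describe,
    "brisk": _brisk_detect_describe,
    "akaze": _akaze_detect_describe,
    "ref": reference_detect_describe,
}


def detect_and_describe(
    img: GrayImage, params: BackendParams | str = "orb"
) -> tuple[list[Keypoint], DescriptorSet]:
    """Detect keypoints and compute binary descriptors with the chosen backend.

    The returned keypoint list and descriptor rows are index-aligned, and the
    result is deterministic for a fixed image and parameters.  A structure-free
    image yields an empty result, not an error.
    """
    if isinstance(params, str):
        params = default_params(params)
    if params.threshold is None and params.max_keypoints is None:
        params = default_params(params.backend_id)
    kps, desc = _BACKEND_FUNCS[params.backend_id](img, params)
    assert len(kps) == desc.n, "keypoints and descriptors must be index-aligned"
    return kps, desc
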