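"""Keypoint and match visualisation: side-by-side overlays.

The reference image is drawn on the left and the target on the right;
keypoints are drawn as red dots on both panels and each correspondence as a
green line joining the paired keypoints (with the target panel's x-offset
applied).  A structured list of drawing primitives backs the raster so the
rendering can be checked programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, line

from .features import Keypoint
from .image_io import GrayImage
from .matching import MatchSet

__all__ = ["OverlaySpec", "Dot", "Line", "Overlay", "render_matches"]


@dataclass(frozen=True)
class OverlaySpec:
    keypoint_color: tuple[int, int, int] = (255, 0, 0)
    line_color: tuple[int, int, int] = (0, 200, 0)
    point_radius: int = 2
    line_width: int = 1
    gap: int = 8

    def __post_init__(self) -> None:
        if self.point_radius < 1 or self.line_width < 1:
            raise ValueError("point radius and line width must be >= 1")


@dataclass(frozen=True)
class Dot:
    x: float
    y: float
    panel: str  # "ref" | "tgt"


@dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float


@dataclass
class Overlay:
    """Rendered side-by-side canvas plus the primitives that produced it."""

    raster: np.ndarray  # (H, W, 3) uint8
    dots: list[Dot] = field(default_factory=list)
    lines: list[Line] = field(default_factory=list)


def _to_rgb(img: GrayImage) -> np.ndarray:
    g = img.pixels
    if img.bit_depth == 16:
        lo, hi = g.min(), g.max()
        g = (g - lo) * (255.0 / max(1, hi - lo))
    return np.repeat(np.clip(g, 0, 255).astype(np.uint8)[..., None], 3, axis=2)


def render_matches(
    ref: GrayImage,
    tgt: GrayImage,
    kp_ref: list[Keypoint],
    kp_tgt: list[Keypoint],
    matches: MatchSet,
    spec: OverlaySpec | None = None,
) -> Overlay:
    """Render keypoints and match lines on a side-by-side canvas.

    The canvas is ``w_ref + gap + w_tgt`` wide and ``max(h_ref, h_tgt)``
    tall; input images are never mutated.  Match indices must be consistent
    with the keypoint lists.
    """
    spec = spec or OverlaySpec()
    for pair in matches.pairs:
        if pair.ref_index >= len(kp_ref) or pair.tgt_index >= len(kp_tgt):
            raise ValueError(
                f"match ({pair.ref_index}, {pair.tgt_index}) is inconsistent with "
                f"{len(kp_ref)} reference / {len(kp_tgt)} target keypoints"
            )

    h = max(ref.height, tgt.height)
    w = ref.width + spec.gap + tgt.width
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    canvas[: ref.height, : ref.width] = _to_rgb(ref)
    x_off = ref.width + spec.gap
    canvas[: tgt.height, x_off: x_off + tgt.width] = _to_rgb(tgt)

    dots = [Dot(k.x, k.y, "ref") for k in kp_ref]
    dots += [Dot(k.x + x_off, k.y, "tgt") for k in kp_tgt]
    lines = [
        Line(kp_ref[p.ref_index].x, kp_ref[p.ref_index].y,
             kp_tgt[p.tgt_index].x + x_off, kp_tgt[p.tgt_index].y)
        for p in matches.pairs
    ]

    for ln in lines:
        rr, cc = line(int(round(ln.y1)), int(round(ln.x1)),
                      int(round(ln.y2)), int(round(ln.x2)))
        for off in range(spec.line_width):
            rr2 = np.clip(rr + off, 0, h - 1)
            canvas[rr2, np.clip(cc, 0, w - 1)] = spec.line_color
    for dot in dots:
        rr, cc = disk((dot.y, dot.x), spec.point_radius, shape=(h, w))
        canvas[rr, cc] = spec.keypoint_color

    return Overlay(raster=canvas, dots=dots, lines=lines)
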