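import numpy as np
import pytest

from kpiqa import (
    BACKENDS,
    BIT_LENGTHS,
    BackendParams,
    GrayImage,
    detect_and_describe,
    reference_detect_describe,
)
from kpiqa.features import _FAST_RING, fast_corners


def _image(arr):
    return GrayImage(np.asarray(arr, dtype=np.int32), 8)


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(77)
    base = rng.integers(30, 200, size=(160, 160))
    return _image(base)


@pytest.fixture(scope="module")
def square_image():
    img = np.full((128, 128), 30, dtype=np.int32)
    img[40:88, 40:88] = 130
    return _image(img)


def naive_segment_test(img, y, x, t=20.0, n_contig=9):
    """Direct per-pixel FAST oracle: check every contiguous arc explicitly."""
    c = float(img[y, x])
    ring = [float(img[y + dy, x + dx]) for dy, dx in _FAST_RING]
    for flags in ([v > c + t for v in ring], [v < c - t for v in ring]):
        doubled = flags + flags
        for start in range(16):
            if all(doubled[start: start + n_contig]):
                return True
    return False


class TestBackendContracts:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_constant_image_yields_empty_result(self, backend):
        img = _image(np.full((96, 96), 120))
        kps, desc = detect_and_describe(img, backend)
        assert kps == []
        assert desc.n == 0
        assert desc.bit_length == BIT_LENGTHS[backend]

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_deterministic(self, textured, backend):
        kp1, d1 = detect_and_describe(textured, backend)
        kp2, d2 = detect_and_describe(textured, backend)
        assert kp1 == kp2
        assert np.array_equal(d1.bits, d2.bits)

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_index_alignment_and_bit_length(self, textured, backend):
        kps, desc = detect_and_describe(textured, backend)
        assert len(kps) == desc.n > 0
        assert desc.bits.shape[1] == BIT_LENGTHS[backend]
        assert desc.bits.dtype == bool

    @pytest.mark.parametrize("backend", BACKENDS)
    def test_keypoints_inside_image(self, textured, backend):
        kps, _ = detect_and_describe(textured, backend)
        for kp in kps:
            assert 0 <= kp.x < textured.width
            assert 0 <= kp.y < textured.height
            assert kp.scale > 0
            assert 0 <= kp.orientation < 360

    def test_non_8bit_rejected(self):
        img = GrayImage(np.zeros((32, 32), dtype=np.int32), 16)
        with pytest.raises(ValueError, match="8-bit"):
            detect_and_describe(img, "ref")

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="unknown backend"):
            BackendParams(backend_id="sift")

    def test_max_keypoints_cap(self, textured):
        kps, desc = detect_and_describe(
            textured, BackendParams(backend_id="ref", max_keypoints=10))
        assert len(kps) == desc.n <= 10


class TestCornerLocalisation:
    @pytest.mark.parametrize("backend", BACKENDS)
    def test_square_corners_found(self, square_image, backend):
        corners = [(40, 40), (40, 87), (87, 40), (87, 87)]  # (x, y)
        kps, _ = detect_and_describe(square_image, backend)
        assert len(kps) >= 4
        for cx, cy in corners:
            d = min(np.hypot(kp.x - cx, kp.y - cy) for kp in kps)
            assert d <= 3.0, f"{backend}: nearest keypoint {d:.1f} px from corner"

    def test_ref_corner_matches_bruteforce_oracle(self):
        img = np.full((64, 64), 50, dtype=np.int32)
        img[30:, 30:] = 160  # one L-shaped corner at (30, 30)
        oracle_hits = [
            (y, x)
            for y in range(3, 61)
            for x in range(3, 61)
            if naive_segment_test(img, y, x)
        ]
        assert oracle_hits, "oracle must fire somewhere near the corner"
        kps, _ = reference_detect_describe(_image(img))
        assert kps, "detector found no corner"
        oy = np.array([h[0] for h in oracle_hits], dtype=float)
        ox = np.array([h[1] for h in oracle_hits], dtype=float)
        for kp in kps:
            assert np.min(np.hypot(oy - kp.y, ox - kp.x)) <= 2.0


class TestRefDescriptor:
    def test_uniform_intensity_shift_invariance(self, textured):
        kps, desc = reference_detect_describe(textured)
        shifted = _image(np.clip(textured.pixels + 10, 0, 255))
        kps2, desc2 = reference_detect_describe(shifted)
        assert [(k.x, k.y) for k in kps] == [(k.x, k.y) for k in kps2]
        assert np.array_equal(desc.bits, desc2.bits)

    def test_fast_corners_on_constant_image(self):
        ys, xs, _ = fast_corners(np.full((40, 40), 9.0), threshold=20.0)
        assert len(ys) == 0
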