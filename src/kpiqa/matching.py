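"""Brute-force descriptor matching and the keypoint-feature quality index.

The quality index is the mean Hamming distance between the binary
descriptors of matched keypoints:

    PI = (1/N) * sum_i || F_R_i - F_T_i ||_Hamming

where the N correspondences are found by exhaustive nearest-neighbour search
over all descriptor pairs, kept only when the nearest-neighbour relation
holds in both directions (mutual cross-check), which guarantees a one-to-one
match set.  Identical images yield PI = 0; PI grows as image quality
degrades and is bounded above by the descriptor bit length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DescriptorSet

__all__ = [
    "MatchPair",
    "MatchSet",
    "PIValue",
    "NoMatchesError",
    "hamming",
    "brute_force_match",
    "proposed_index",
]


class NoMatchesError(ValueError):
    """PI is undefined when no keypoint correspondences exist (N = 0)."""

    def __init__(self, n_ref: int, n_tgt: int):
        self.n_ref = n_ref
        self.n_tgt = n_tgt
        super().__init__(
            f"no keypoint correspondences (reference has {n_ref} keypoints, "
            f"target has {n_tgt}); the quality index is undefined"
        )


@dataclass(frozen=True)
class MatchPair:
    """One correspondence: reference/target keypoint indices and their distance."""

    ref_index: int
    tgt_index: int
    distance: int  # Hamming distance in bits


@dataclass
class MatchSet:
    """One-to-one correspondences between two descriptor sets."""

    pairs: list[MatchPair]
    bit_length: int
    backend_id: str
    n_ref: int = 0
    n_tgt: int = 0

    @property
    def n(self) -> int:
        return len(self.pairs)

    def distances(self) -> np.ndarray:
        return np.asarray([p.distance for p in self.pairs], dtype=np.int64)


@dataclass(frozen=True)
class PIValue:
    """The quality index: mean Hamming distance in bits over N matched pairs."""

    value: float
    n: int
    backend_id: str
    bit_length: int

    @property
    def normalized(self) -> float:
        """Value rescaled by the descriptor bit length (for cross-backend use)."""
        return self.value / self.bit_length


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length binary vectors (bool or 0/1)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"descriptors must be 1-D and equal length, got "
                         f"{a.shape} vs {b.shape}")
    return int(np.count_nonzero(a.astype(bool) ^ b.astype(bool)))


def _distance_matrix(ref: DescriptorSet, tgt: DescriptorSet) -> np.ndarray:
    """All-pairs Hamming distances via packed bytes and popcount, chunked."""
    rp, tp = ref.packed(), tgt.packed()
    out = np.empty((ref.n, tgt.n), dtype=np.uint16)
    chunk = max(1, int(4e7 // max(1, tgt.n * rp.shape[1])))
    for start in range(0, ref.n, chunk):
        stop = min(start + chunk, ref.n)
        xor = rp[start:stop, None, :] ^ tp[None, :, :]
        out[start:stop] = np.bitwise_count(xor).sum(axis=2, dtype=np.uint16)
    return out


def brute_force_match(ref: DescriptorSet, tgt: DescriptorSet) -> MatchSet:
    """Exhaustive nearest-neighbour matching with mutual cross-check.

    Every reference descriptor is compared against every target descriptor;
    a pair is kept only when each is the other's nearest neighbour.  Ties on
    equal minimal distance are broken toward the lowest index, making the
    result deterministic.  Either set being empty yields an empty MatchSet.
    """
    if ref.backend_id != tgt.backend_id:
        raise ValueError(
            f"cannot match descriptors from different backends "
            f"({ref.backend_id} vs {tgt.backend_id})"
        )
    if ref.n == 0 or tgt.n == 0:
        return MatchSet([], ref.bit_length, ref.backend_id, ref.n, tgt.n)
    dist = _distance_matrix(ref, tgt)
    nn_of_ref = dist.argmin(axis=1)  # ties -> lowest target index
    nn_of_tgt = dist.argmin(axis=0)  # ties -> lowest reference index
    ref_idx = np.arange(ref.n)
    mutual = nn_of_tgt[nn_of_ref] == ref_idx
    pairs = [
        MatchPair(int(i), int(nn_of_ref[i]), int(dist[i, nn_of_ref[i]]))
        for i in ref_idx[mutual]
    ]
    return MatchSet(pairs, ref.bit_length, ref.backend_id, ref.n, tgt.n)


def proposed_index(matches: MatchSet) -> PIValue:
    """Mean Hamming distance over the matched pairs (the quality index).

    Raises :class:`NoMatchesError` when the match set is empty — the index is
    undefined there and must never silently become 0 or NaN.
    """
    if matches.n == 0:
        raise NoMatchesError(matches.n_ref, matches.n_tgt)
    value = float(matches.distances().mean())
    return PIValue(value=value, n=matches.n, backend_id=matches.backend_id,
                   bit_length=matches.bit_length)
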