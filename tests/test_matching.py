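import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpiqa import (
    DescriptorSet,
    NoMatchesError,
    brute_force_match,
    hamming,
    proposed_index,
)
from kpiqa.matching import MatchPair, MatchSet
from tests_oracles import oracle_match


def _dset(bits, backend="ref"):
    return DescriptorSet(np.asarray(bits, dtype=bool), backend)


def _random_dset(rng, n, backend):
    from kpiqa import BIT_LENGTHS

    return _dset(rng.integers(0, 2, size=(n, BIT_LENGTHS[backend])), backend)


class TestHamming:
    def test_identity_is_zero(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert hamming(a, a) == 0

    def test_all_bits_differ(self):
        assert hamming(np.zeros(4, dtype=bool), np.ones(4, dtype=bool)) == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=256, max_size=256),
           st.lists(st.booleans(), min_size=256, max_size=256))
    def test_matches_bit_loop_oracle(self, a, b):
        loop = sum(1 for x, y in zip(a, b) if x != y)
        assert hamming(np.array(a), np.array(b)) == loop

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=8, max_size=64),
           st.lists(st.booleans(), min_size=8, max_size=64))
    def test_symmetry(self, a, b):
        if len(a) != len(b):
            return
        assert hamming(np.array(a), np.array(b)) == hamming(np.array(b), np.array(a))


class TestBruteForceMatch:
    def test_identity_matching_distinct_rows(self, rng):
        d = _random_dset(rng, 12, "ref")
        assert len(np.unique(d.packed(), axis=0)) == 12
        m = brute_force_match(d, d)
        assert m.n == 12
        for p in m.pairs:
            assert p.ref_index == p.tgt_index
            assert p.distance == 0

    def test_single_pair(self, rng):
        a, b = _random_dset(rng, 1, "ref"), _random_dset(rng, 1, "ref")
        m = brute_force_match(a, b)
        assert m.n == 1
        assert m.pairs[0].distance == hamming(a.bits[0], b.bits[0])

    def test_empty_sets_give_empty_matchset(self, rng):
        d = _random_dset(rng, 5, "ref")
        empty = _dset(np.zeros((0, 256)), "ref")
        assert brute_force_match(empty, d).n == 0
        assert brute_force_match(d, empty).n == 0

    def test_backend_mismatch_rejected(self, rng):
        a = _random_dset(rng, 3, "ref")
        b = _random_dset(rng, 3, "orb")
        with pytest.raises(ValueError, match="backend"):
            brute_force_match(a, b)

    def test_one_to_one_invariant(self, rng):
        a, b = _random_dset(rng, 40, "brisk"), _random_dset(rng, 30, "brisk")
        m = brute_force_match(a, b)
        refs = [p.ref_index for p in m.pairs]
        tgts = [p.tgt_index for p in m.pairs]
        assert len(refs) == len(set(refs))
        assert len(tgts) == len(set(tgts))

    @pytest.mark.parametrize("backend,n_ref,n_tgt", [
        ("ref", 20, 15), ("brisk", 25, 25), ("ref", 7, 31), ("brisk", 50, 3),
    ])
    def test_agrees_with_exhaustive_oracle(self, rng, backend, n_ref, n_tgt):
        a, b = _random_dset(rng, n_ref, backend), _random_dset(rng, n_tgt, backend)
        m = brute_force_match(a, b)
        got = sorted((p.ref_index, p.tgt_index, p.distance) for p in m.pairs)
        assert got == oracle_match(a.bits, b.bits)


class TestProposedIndex:
    def _matchset(self, distances, L=256):
        pairs = [MatchPair(i, i, d) for i, d in enumerate(distances)]
        return MatchSet(pairs, L, "ref", len(distances), len(distances))

    def test_identical_images_give_zero(self, rng):
        d = _random_dset(rng, 10, "ref")
        pi = proposed_index(brute_force_match(d, d))
        assert pi.value == 0.0

    def test_arithmetic_mean(self):
        assert proposed_index(self._matchset([2, 4])).value == 3.0

    def test_matches_independent_accumulator(self, rng):
        dists = rng.integers(0, 257, size=100).tolist()
        total, count = 0, 0
        for d in dists:  # independent running-sum oracle
            total += d
            count += 1
        assert proposed_index(self._matchset(dists)).value == pytest.approx(
            total / count)

    def test_no_matches_is_an_error_with_counts(self):
        empty = MatchSet([], 256, "ref", n_ref=12, n_tgt=0)
        with pytest.raises(NoMatchesError) as exc:
            proposed_index(empty)
        assert exc.value.n_ref == 12
        assert exc.value.n_tgt == 0

    def test_bounds_and_normalisation(self, rng):
        dists = rng.integers(0, 513, size=30).tolist()
        pi = proposed_index(self._matchset(dists, L=512))
        assert 0 <= pi.value <= 512
        assert pi.normalized == pytest.approx(pi.value / 512)
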