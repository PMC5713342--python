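"""Descriptor blocks (C, T, D, triads) and CT/LD/LCTD vector assembly.

Expected values come from two routes: the hand-worked 22-residue example,
and naive loop-based recomputation (see conftest) on random sequences.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lctd.descriptors import (
    PAIR_DIMS,
    PROTEIN_DIMS,
    TRANSITION_PAIRS,
    composition,
    conjoint_triad,
    ct_protein_vector,
    distribution,
    feature_names,
    lctd_protein_vector,
    ld_protein_vector,
    normalize_triads,
    pair_vector,
    protein_vector,
    transition,
    triad_frequencies,
    triad_index,
)
from lctd.encoding import EncodedSequence, SequenceTooShortError, split_regions
from conftest import (
    naive_composition,
    naive_distribution,
    naive_transition,
    naive_triad_counts,
    naive_triad_normalized,
)

codes_strategy = st.lists(
    st.integers(min_value=0, max_value=6), min_size=1, max_size=200
).map(lambda xs: np.array(xs, dtype=np.int8))


class TestComposition:
    def test_worked_example(self, example_codes):
        C = composition(example_codes)
        assert C[0] == pytest.approx(36.36, abs=0.01)
        assert C[1] == pytest.approx(31.82, abs=0.01)
        assert C[2] == pytest.approx(31.82, abs=0.01)
        assert np.all(C[3:] == 0)

    def test_single_class_region(self):
        C = composition(np.array([5, 5, 5, 5], dtype=np.int8))
        assert C[5] == 100.0 and C.sum() == 100.0

    def test_uniform_one_of_each(self):
        C = composition(np.arange(7, dtype=np.int8))
        assert np.allclose(C, 100.0 / 7.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            composition(np.array([], dtype=np.int8))

    @given(codes_strategy)
    @settings(max_examples=100, deadline=None)
    def test_sums_to_100_and_matches_naive(self, codes):
        C = composition(codes)
        assert C.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(C, naive_composition(codes), atol=1e-12)


class TestTransition:
    def test_worked_example_class_0_1(self, example_codes):
        T = transition(example_codes)
        slot_01 = TRANSITION_PAIRS.index((0, 1))
        assert T[slot_01] == pytest.approx(100.0 * 7 / 21, abs=0.01)

    def test_worked_example_derived_rows(self, example_codes):
        # direct counting on the encoded string: 5 of 21 adjacent pairs switch
        # between classes 0 and 2, and 3 of 21 between classes 1 and 2
        T = transition(example_codes)
        assert T[TRANSITION_PAIRS.index((0, 2))] == pytest.approx(23.81, abs=0.01)
        assert T[TRANSITION_PAIRS.index((1, 2))] == pytest.approx(14.29, abs=0.01)

    def test_two_residue_region(self):
        T = transition(np.array([0, 5], dtype=np.int8))
        assert T[TRANSITION_PAIRS.index((0, 5))] == 100.0
        assert T.sum() == 100.0

    def test_length_one_region_is_zero_vector(self):
        assert np.all(transition(np.array([3], dtype=np.int8)) == 0)

    @given(codes_strategy)
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_and_bounded(self, codes):
        T = transition(codes)
        assert np.allclose(T, naive_transition(codes), atol=1e-12)
        assert T.sum() <= 100.0 + 1e-9


class TestDistribution:
    def test_worked_example_class_1(self, example_codes):
        D = distribution(example_codes)
        assert np.allclose(
            D[5:10], [9.09, 13.64, 45.45, 63.64, 95.45], atol=0.01
        )

    def test_worked_example_class_2(self, example_codes):
        D = distribution(example_codes)
        assert np.allclose(
            D[10:15], [18.18, 22.73, 54.55, 72.73, 86.36], atol=0.01
        )

    def test_worked_example_class_0_positions(self, example_codes):
        # class 0 occurs 8 times at positions 1,6,8,9,13,15,17,22; the probed
        # ordinals 1,2,4,6,8 sit at positions 1,6,9,15,22
        D = distribution(example_codes)
        assert np.allclose(
            D[0:5], [4.55, 27.27, 40.91, 68.18, 100.0], atol=0.01
        )

    def test_absent_class_gives_zeros(self):
        D = distribution(np.array([0, 0, 1], dtype=np.int8))
        assert np.all(D[10:] == 0)

    @given(codes_strategy)
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_in_range_and_monotone(self, codes):
        D = distribution(codes)
        assert np.allclose(D, naive_distribution(codes), atol=1e-12)
        assert np.all((D >= 0) & (D <= 100))
        for g in range(7):
            block = D[g * 5 : g * 5 + 5]
            if np.any(codes == g):
                assert np.all(np.diff(block) >= -1e-12)


class TestConjointTriad:
    @pytest.mark.parametrize(
        "triple,index", [((1, 0, 0), 1), ((0, 1, 0), 7), ((3, 1, 0), 10)]
    )
    def test_anchor_indices(self, triple, index):
        assert triad_index(*triple) == index

    def test_worked_example_counts(self, example_codes):
        f, d = conjoint_triad(example_codes)
        assert f[113] == 2  # triad (1,2,2)
        assert f.sum() == 20
        assert d[113] == pytest.approx(1.0)

    def test_window_conservation(self, example_codes):
        assert triad_frequencies(example_codes).sum() == len(example_codes) - 2

    def test_region_shorter_than_window(self):
        f, d = conjoint_triad(np.array([0, 1], dtype=np.int8))
        assert np.all(f == 0) and np.all(d == 0)

    def test_normalization_divides_by_max_as_specified(self):
        # two distinct triads once each, one triad twice: min=0, max=2
        f = np.zeros(343); f[[1, 7]] = 1; f[113] = 2
        d = normalize_triads(f)
        assert d[113] == 1.0 and d[1] == 0.5 and d[0] == 0.0

    def test_min_max_variant(self):
        f = np.zeros(343); f[:] = 1; f[5] = 3
        d = normalize_triads(f, min_max=True)
        assert d[5] == 1.0 and d[0] == 0.0

    @given(codes_strategy)
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_and_bounded(self, codes):
        f, d = conjoint_triad(codes)
        assert np.array_equal(f, naive_triad_counts(codes))
        assert np.allclose(d, naive_triad_normalized(codes), atol=1e-12)
        assert f.sum() == max(0, codes.size - 2)
        assert np.all((d >= 0) & (d <= 1))


class TestVectorAssembly:
    @pytest.mark.parametrize("method,dim", list(PROTEIN_DIMS.items()))
    def test_protein_dimensions(self, rng, method, dim):
        enc = EncodedSequence(rng.integers(0, 7, size=137).astype(np.int8))
        assert protein_vector(enc, method).shape == (dim,)

    @pytest.mark.parametrize("method,dim", list(PAIR_DIMS.items()))
    def test_pair_dimensions(self, rng, method, dim):
        a = EncodedSequence(rng.integers(0, 7, size=90).astype(np.int8))
        b = EncodedSequence(rng.integers(0, 7, size=260).astype(np.int8))
        assert pair_vector(a, b, method).shape == (dim,)

    def test_ct_vector_trivial_sequence(self):
        enc = EncodedSequence(np.zeros(3, dtype=np.int8))  # e.g. "AAA"
        v = ct_protein_vector(enc)
        assert v[0] == 1.0 and np.all(v[1:] == 0)

    def test_lctd_leads_with_the_ld_region_a_block(self, rng):
        enc = EncodedSequence(rng.integers(0, 7, size=61).astype(np.int8))
        lctd = lctd_protein_vector(enc)
        ld = ld_protein_vector(enc)
        assert np.array_equal(lctd[:63], ld[:63])
        start, end = split_regions(61)["A"]
        _, d = conjoint_triad(enc.codes[start:end])
        assert np.array_equal(lctd[63:406], d[:343])

    def test_zeroing_triad_subblocks_recovers_ld(self, rng):
        enc = EncodedSequence(rng.integers(0, 7, size=143).astype(np.int8))
        lctd = lctd_protein_vector(enc).reshape(10, 406)
        assert np.array_equal(lctd[:, :63].ravel(), ld_protein_vector(enc))

    def test_pair_vector_swapping_swaps_halves(self, rng):
        a = EncodedSequence(rng.integers(0, 7, size=80).astype(np.int8))
        b = EncodedSequence(rng.integers(0, 7, size=120).astype(np.int8))
        ab = pair_vector(a, b, "ct")
        ba = pair_vector(b, a, "ct")
        assert np.array_equal(ab[:343], ba[343:])
        assert np.array_equal(ab[343:], ba[:343])

    def test_self_pair_halves_agree(self, rng):
        a = EncodedSequence(rng.integers(0, 7, size=64).astype(np.int8))
        v = pair_vector(a, a, "ct")
        assert np.array_equal(v[:343], v[343:])

    def test_short_sequence_rejected_for_regional_methods(self):
        enc = EncodedSequence(np.zeros(7, dtype=np.int8))
        with pytest.raises(SequenceTooShortError):
            ld_protein_vector(enc)
        with pytest.raises(SequenceTooShortError):
            lctd_protein_vector(enc)

    def test_error_is_tagged_with_protein_id(self):
        good = EncodedSequence(np.zeros(60, dtype=np.int8), id="P1")
        bad = EncodedSequence(np.zeros(7, dtype=np.int8), id="P2")
        with pytest.raises(SequenceTooShortError, match="P2"):
            pair_vector(good, bad, "lctd")

    @pytest.mark.parametrize("method", ["ct", "ld", "lctd"])
    def test_feature_names_match_dimensions(self, method):
        assert len(feature_names(method, "protein")) == PROTEIN_DIMS[method]
        assert len(feature_names(method, "pair")) == PAIR_DIMS[method]


class TestRegionOracleEquivalence:
    """Every region block of LD/LCTD equals naive recomputation on the
    extracted substring, for a battery of seeded random sequences."""

    def test_100_random_sequences(self, rng):
        for _ in range(100):
            L = int(rng.integers(8, 501))
            codes = rng.integers(0, 7, size=L).astype(np.int8)
            enc = EncodedSequence(codes)
            ld = ld_protein_vector(enc).reshape(10, 63)
            lctd = lctd_protein_vector(enc).reshape(10, 406)
            regions = split_regions(L)
            for r, label in enumerate("ABCDEFGHIJ"):
                start, end = regions[label]
                sub = codes[start:end]
                expected_ld = np.concatenate(
                    [naive_composition(sub), naive_transition(sub), naive_distribution(sub)]
                )
                assert np.allclose(ld[r], expected_ld, atol=1e-9)
                assert np.allclose(lctd[r, :63], expected_ld, atol=1e-9)
                assert np.allclose(
                    lctd[r, 63:], naive_triad_normalized(sub), atol=1e-9
                )
                # triad conservation within the region
                assert triad_frequencies(sub).sum() == max(0, len(sub) - 2)
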