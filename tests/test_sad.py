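"""Octave binning and the raw/central/standardized moment operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sadscale import (
    AbundanceVector,
    BinnedSAD,
    DegenerateDistributionError,
    bin_abundances,
    binned_raw_moment,
    binned_skewness,
    binned_standardized_moment,
    central_moment,
    moment_summary,
    raw_moment,
    skewness,
    standardized_moment,
)

abundance_lists = st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=60)


class TestBinning:
    @pytest.mark.parametrize(
        "abundances, expected",
        [
            ([1, 1, 2, 3, 4, 7, 8], [2, 2, 2, 1]),
            ([1], [1]),
            (list(range(1, 101)), [1, 2, 4, 8, 16, 32, 37]),
        ],
    )
    def test_doubling_classes(self, abundances, expected):
        b = bin_abundances(abundances)
        assert b.class_counts.tolist() == expected
        assert b.num_classes == len(expected)

    def test_class_contains_doubling_range(self):
        # brute-force check of the class boundaries [2^i, 2^(i+1) - 1]
        for n in range(1, 300):
            b = bin_abundances([n])
            cls = int(np.argmax(b.class_counts))
            assert 2**cls <= n <= 2 ** (cls + 1) - 1

    def test_empty_vector_yields_empty_histogram(self):
        b = bin_abundances([])
        assert b.num_classes == 0

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError):
            bin_abundances([1, 0, 2])

    def test_interior_zero_classes_retained(self):
        b = bin_abundances([1, 9])  # classes 0 and 3, nothing between
        assert b.class_counts.tolist() == [1, 0, 0, 1]

    @settings(max_examples=100, derandomize=True)
    @given(abundance_lists)
    def test_counts_conserve_species_and_num_classes(self, abundances):
        b = bin_abundances(abundances)
        assert b.class_counts.sum() == len(abundances)
        assert b.num_classes == int(np.floor(np.log2(max(abundances)))) + 1
        assert abs(b.proportions.sum() - 1.0) < 1e-12


class TestVectorMoments:
    @pytest.mark.parametrize(
        "abundances, n, expected",
        [
            ([4], 3, 8.0),
            ([1, 1, 1], 5, 0.0),
            ([1, 1, 1], 0, 1.0),
            ([2, 8], 2, 5.0),
        ],
    )
    def test_raw_moment_examples(self, abundances, n, expected):
        assert raw_moment(abundances, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "abundances, n, expected",
        [
            ([1, 4], 2, 1.0),
            ([5, 17, 6, 9], 1, 0.0),
            ([1, 1, 8], 2, 2.0),
        ],
    )
    def test_central_moment_examples(self, abundances, n, expected):
        assert central_moment(abundances, n) == pytest.approx(expected, abs=1e-12)

    def test_standardized_moment_examples(self):
        assert standardized_moment([2, 8], 3) == pytest.approx(0.0, abs=1e-12)
        assert standardized_moment([1, 1, 8], 3) == pytest.approx(0.7071, abs=1e-4)
        assert standardized_moment([3, 9, 17, 2], 2) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_spread_is_flagged_not_zero(self):
        with pytest.raises(DegenerateDistributionError):
            standardized_moment([4, 4, 4], 3)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            raw_moment([], 1)

    @settings(max_examples=100, derandomize=True)
    @given(abundance_lists, st.integers(min_value=0, max_value=6))
    def test_brute_force_oracle(self, abundances, n):
        """All three moment types agree with a direct python-loop summation."""
        x = [np.log2(a) for a in abundances]
        S = len(x)
        mean = sum(x) / S
        assert raw_moment(abundances, n) == pytest.approx(
            sum(xi**n for xi in x) / S, rel=1e-10, abs=1e-10
        )
        assert central_moment(abundances, n) == pytest.approx(
            sum((xi - mean) ** n for xi in x) / S, rel=1e-10, abs=1e-10
        )
        sd = np.sqrt(sum((xi - mean) ** 2 for xi in x) / S)
        if sd > 1e-9:
            assert standardized_moment(abundances, n) == pytest.approx(
                sum(((xi - mean) / sd) ** n for xi in x) / S, rel=1e-8, abs=1e-8
            )

    @settings(max_examples=60, derandomize=True)
    @given(abundance_lists, st.integers(min_value=2, max_value=5))
    def test_skewness_invariances(self, abundances, reps):
        """Skewness ignores species labels and whole-vector duplication."""
        if len(set(abundances)) < 2:
            return
        s = skewness(abundances)
        assert skewness(list(reversed(abundances))) == pytest.approx(s, rel=1e-9)
        assert skewness(abundances * reps) == pytest.approx(s, rel=1e-9)

    def test_moment_summary_identities(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.integers(1, 500, size=rng.integers(3, 40))
            ms = moment_summary(v, n_max=6)
            assert ms.raw[0] == pytest.approx(1.0)
            assert ms.central[0] == pytest.approx(1.0)
            assert ms.central[1] == pytest.approx(0.0, abs=1e-12)
            if not ms.degenerate:
                assert ms.standardized[2] == pytest.approx(1.0, abs=1e-9)
                assert ms.skewness == pytest.approx(skewness(v), rel=1e-9)


class TestBinnedMoments:
    @pytest.mark.parametrize(
        "proportions, n, expected",
        [
            ([0.5, 0.5], 1, 0.5),
            ([1.0, 0.0, 0.0], 4, 0.0),
            ([0.5, 0.25, 0.25], 2, 1.25),
        ],
    )
    def test_binned_raw_moment_examples(self, proportions, n, expected):
        b = BinnedSAD(np.asarray(proportions) * 40)
        assert binned_raw_moment(b, n) == pytest.approx(expected, abs=1e-12)

    def test_binned_raw_moment_order_zero_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = rng.integers(1, 200, size=15)
            assert binned_raw_moment(bin_abundances(v), 0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "proportions, n, expected",
        [
            ([0.5, 0.0, 0.5], 3, 0.0),
            ([2 / 3, 0.0, 1 / 3], 3, 0.7071),
            ([0.5, 0.5], 2, 1.0),
        ],
    )
    def test_binned_standardized_examples(self, proportions, n, expected):
        b = BinnedSAD(np.asarray(proportions) * 12)
        assert binned_standardized_moment(b, n) == pytest.approx(expected, abs=1e-4)

    def test_single_class_flagged_undefined(self):
        with pytest.raises(DegenerateDistributionError):
            binned_skewness(BinnedSAD(np.array([0.0, 5.0, 0.0])))

    def test_mirror_negates_odd_standardized_moments(self):
        """Reflecting the class distribution about its mean flips T_odd."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            p = rng.random(rng.integers(2, 12))
            b = BinnedSAD(p)
            b_rev = BinnedSAD(p[::-1].copy())
            for n in (3, 5):
                assert binned_standardized_moment(
                    b_rev, n
                ) == pytest.approx(-binned_standardized_moment(b, n), rel=1e-8, abs=1e-10)
            assert binned_standardized_moment(b_rev, 2) == pytest.approx(
                binned_standardized_moment(b, 2), rel=1e-9
            )

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            binned_raw_moment(BinnedSAD(np.zeros(0)), 1)


def test_histogram_text_round_trip(tmp_path):
    b = bin_abundances([1, 1, 2, 3, 4, 7, 8, 200])
    path = tmp_path / "sad.csv"
    b.to_text(path)
    b2 = BinnedSAD.from_text(path)
    assert np.array_equal(b.class_counts, b2.class_counts)


def test_abundance_vector_fields():
    v = AbundanceVector(np.array([1, 2, 8]))
    assert v.species_count == 3
    assert v.total_individuals == 11
    assert v.max_abundance == 8
    assert np.allclose(v.log2_abundances, [0.0, 1.0, 3.0])
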