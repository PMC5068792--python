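import itertools

import numpy as np
import pytest

from conftest import brute_nodf, brute_wnodf
from nestgrad.nestedness import (
    nestedness_test,
    nodf,
    paired_nodf,
    paired_wnodf,
    sample_fixed_fixed,
    sample_weighted_null,
    wnodf,
)


class TestPairedTerms:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ((1, 1, 1), (1, 1, 0), 100.0),  # perfect subset, smaller fill
            ((1, 0), (0, 1), 0.0),  # equal fills -> decreasing-fill condition
            ((1, 1, 0, 1), (1, 0, 1, 0), 50.0),  # 1 of right's 2 ones shared
            ((1, 1), (0, 0), 0.0),  # degenerate empty right
        ],
    )
    def test_paired_nodf(self, left, right, expected):
        assert paired_nodf(left, right) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ((4, 2, 1), (3, 1, 0), 100.0),  # both nonzero right cells smaller
            ((4, 2, 1), (3, 2, 0), 50.0),  # positive tie does not count
            ((1, 1), (2, 2), 0.0),  # right total not smaller
            ((1, 1), (0, 0), 0.0),  # degenerate
        ],
    )
    def test_paired_wnodf(self, left, right, expected):
        assert paired_wnodf(left, right) == pytest.approx(expected)


class TestMatrixIndices:
    def test_fully_nested_triangular_is_100(self, nested_matrix):
        assert nodf(nested_matrix, axis="columns") == pytest.approx(100.0)

    def test_checkerboard_is_0(self):
        assert nodf(np.array([[1.0, 0.0], [0.0, 1.0]]), axis="columns") == 0.0

    def test_wnodf_identical_columns_is_0(self):
        m = np.array([[3.0, 3.0], [1.0, 1.0]])
        assert wnodf(m, axis="columns") == 0.0

    def test_wnodf_strictly_decreasing_nested_is_100(self):
        m = np.array([[9.0, 5.0, 2.0], [6.0, 3.0, 0.0], [4.0, 0.0, 0.0]])
        assert wnodf(m, axis="columns") == pytest.approx(100.0)
        assert nodf((m > 0).astype(float), axis="columns") == pytest.approx(100.0)

    def test_single_axis_element_errors(self):
        with pytest.raises(ValueError):
            nodf(np.ones((3, 1)), axis="columns")

    def test_nodf_requires_binary(self):
        with pytest.raises(ValueError, match="binary"):
            nodf(np.array([[2.0, 1.0], [1.0, 0.0]]))

    @pytest.mark.parametrize("axis", ["columns", "rows", "both"])
    def test_matches_bruteforce_oracle_random(self, axis):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = rng.integers(2, 7, size=2)
            binary = (rng.random(shape) < 0.5).astype(float)
            counts = rng.integers(0, 9, size=shape).astype(float)
            assert nodf(binary, axis=axis) == pytest.approx(brute_nodf(binary, axis))
            assert wnodf(counts, axis=axis) == pytest.approx(brute_wnodf(counts, axis))

    def test_packed_ordering_invariant_to_input_permutation(self):
        rng = np.random.default_rng(3)
        m = (rng.random((6, 5)) < 0.45).astype(float)
        base = nodf(m, axis="both", ordering="by_marginal_total")
        for _ in range(5):
            pm = m[rng.permutation(6)][:, rng.permutation(5)]
            assert nodf(pm, axis="both", ordering="by_marginal_total") == pytest.approx(base)


def enumerate_fixed_fixed(row_sums, col_sums):
    """All binary matrices with the given margins (brute force)."""
    n_cols = len(col_sums)
    rows_choices = [
        [
            np.array(v)
            for v in itertools.product((0, 1), repeat=n_cols)
            if sum(v) == r
        ]
        for r in row_sums
    ]
    out = []
    for combo in itertools.product(*rows_choices):
        m = np.array(combo, dtype=float)
        if (m.sum(axis=0) == np.asarray(col_sums)).all():
            out.append(m)
    return out


class TestFixedFixedSampler:
    @pytest.mark.parametrize("algorithm", ["curveball", "swap"])
    def test_margins_preserved_on_every_sample(self, algorithm):
        rng = np.random.default_rng(11)
        m = (rng.random((8, 6)) < 0.4).astype(float)
        m = m[m.sum(1) > 0][:, m[m.sum(1) > 0].sum(0) > 0]
        for s in sample_fixed_fixed(m, 50, seed=1, algorithm=algorithm):
            np.testing.assert_array_equal(s.sum(axis=1), m.sum(axis=1))
            np.testing.assert_array_equal(s.sum(axis=0), m.sum(axis=0))
            assert set(np.unique(s)) <= {0.0, 1.0}

    def test_checkerboard_visits_both_states(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        seen = {tuple(s.ravel()) for s in sample_fixed_fixed(m, 60, seed=0)}
        assert len(seen) == 2

    def test_full_matrix_warns_and_returns_copies(self):
        m = np.ones((3, 3))
        with pytest.warns(UserWarning, match="singleton"):
            samples = list(sample_fixed_fixed(m, 4, seed=0))
        assert all((s == m).all() for s in samples)

    @pytest.mark.parametrize("algorithm", ["curveball", "swap"])
    def test_uniform_over_enumerable_ensemble(self, algorithm):
        """Chi-square uniformity over all matrices with margins (2,2,1,1)^2."""
        margins = (2, 2, 1, 1)
        ensemble = enumerate_fixed_fixed(margins, margins)
        start = ensemble[0]
        counts = {tuple(e.ravel()): 0 for e in ensemble}
        for s in sample_fixed_fixed(start, 10000, seed=5, algorithm=algorithm, thin=20):
            counts[tuple(s.ravel())] += 1
        observed = np.array(list(counts.values()))
        assert (observed > 0).all()
        from scipy.stats import chisquare

        stat, p = chisquare(observed)
        assert p > 1e-3


class TestWeightedNull:
    def test_margins_fixed_preserves_both_margins(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 6, size=(6, 5)).astype(float)
        for s in sample_weighted_null(m, 30, seed=3, scheme="margins_fixed"):
            np.testing.assert_allclose(s.sum(axis=1), m.sum(axis=1))
            np.testing.assert_allclose(s.sum(axis=0), m.sum(axis=0))
            assert (s >= 0).all()

    def test_margins_fixed_rejects_non_integer(self):
        with pytest.raises(ValueError, match="integer"):
            next(iter(sample_weighted_null(np.array([[0.5, 1.0], [1.0, 0.5]]), 1)))

    def test_skeleton_shuffle_preserves_value_multiset_and_fill(self):
        rng = np.random.default_rng(4)
        m = rng.integers(0, 5, size=(5, 4)).astype(float)
        m = m[m.sum(1) > 0][:, m[m.sum(1) > 0].sum(0) > 0]
        values = sorted(m[m > 0])
        for s in sample_weighted_null(m, 20, seed=5, scheme="skeleton_shuffle"):
            assert sorted(s[s > 0]) == values
            assert (s == 0).sum() == (m == 0).sum()

    def test_permute_within_rows_preserves_row_multisets(self):
        m = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 6.0]])
        for s in sample_weighted_null(m, 10, seed=6, scheme="cell_permute_within_rows"):
            for i in range(2):
                assert sorted(s[i]) == sorted(m[i])

    def test_margins_fixed_mean_matches_exhaustive_small_ensemble(self):
        """Null WNODF mean agrees with the exhaustive margin-constrained
        ensemble on a tiny matrix (within Monte-Carlo error)."""
        m = np.array([[2.0, 1.0], [1.0, 2.0]])
        # exhaustive: all non-negative integer 2x2 tables with margins (3,3)/(3,3)
        tables = [
            np.array([[a, 3 - a], [3 - a, a]], dtype=float) for a in range(4)
        ]
        exact = np.mean([wnodf(t, axis="rows") for t in tables])
        vals = [
            wnodf(s, axis="rows")
            for s in sample_weighted_null(m, 2000, seed=7, scheme="margins_fixed")
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - exact) < max(3 * se, 1.0)


class TestNestednessTest:
    def test_nested_matrix_direction(self):
        """A strongly nested (but not margin-degenerate) matrix scores at or
        above the bulk of its fixed-fixed null ensemble."""
        rng = np.random.default_rng(1)
        thr = rng.integers(0, 5, 30)
        m = np.zeros((30, 5))
        for i, t in enumerate(thr):
            m[i] = (np.arange(5) <= (4 - t)) & (rng.random(5) < 0.85)
        m = m[m.sum(1) > 0]
        res = nestedness_test(m, metric="nodf", axis="columns", n_null=300, seed=2)
        assert res.z is None or res.z > -0.5
        assert res.p_upper <= 0.6

    def test_z_definition_and_p_floor(self):
        rng = np.random.default_rng(9)
        m = (rng.random((8, 6)) < 0.5).astype(float)
        m = m[m.sum(1) > 0][:, m[m.sum(1) > 0].sum(0) > 0]
        res = nestedness_test(m, metric="nodf", axis="columns", n_null=99, seed=1)
        if res.null_sd > 0:
            assert res.z == pytest.approx((res.observed - res.null_mean) / res.null_sd)
        assert res.p_upper >= 1 / 100
        assert res.p_lower >= 1 / 100

    def test_degenerate_null_reports_z_none(self):
        with pytest.warns(UserWarning, match="singleton"):
            res = nestedness_test(np.ones((3, 3)), metric="nodf", n_null=20, seed=0)
        assert res.z is None
        assert res.p_upper == 1.0

    def test_custom_null_stream(self):
        m = np.array([[3.0, 1.0], [1.0, 3.0]])
        nulls = iter([m.copy() for _ in range(10)])
        res = nestedness_test(
            m, metric="wnodf", axis="rows", n_null=10, nulls=nulls, sampler_label="custom"
        )
        assert res.sampler == "custom"
        assert res.null_sd == 0.0
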