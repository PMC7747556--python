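"""Pointwise F statistics, permutation inference and interval extraction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from actiflm.flm import (
    DesignError,
    FLMResult,
    RegressionDesign,
    permutation_test,
    pointwise_F,
    significant_intervals,
)
from actiflm.fourier import CurveMatrix


def curve_matrix(values):
    values = np.asarray(values, dtype=float)
    return CurveMatrix(
        [f"s{i}" for i in range(values.shape[0])], np.arange(values.shape[1]), values
    )


def binary_design(groups):
    groups = np.asarray(groups, dtype=float)
    return RegressionDesign(
        ["intercept", "group"],
        np.column_stack([np.ones(groups.size), groups]),
        test_columns=[1],
    )


class TestPointwiseF:
    def test_identical_group_curves_give_zero(self):
        base = np.tile(np.sin(np.arange(20)), (3, 1))
        Y = np.vstack([base, base])  # group 0 == group 1 curve sets
        F = pointwise_F(curve_matrix(Y), binary_design([0, 0, 0, 1, 1, 1]))
        assert np.allclose(F, 0.0, atol=1e-18)

    def test_matches_one_way_anova_oracle(self):
        """scipy.stats.f_oneway on 6 hand-made curves, every grid point."""
        rng = np.random.default_rng(12)
        Y = rng.normal(50, 10, size=(6, 40))
        groups = np.array([0, 0, 0, 1, 1, 1])
        F = pointwise_F(curve_matrix(Y), binary_design(groups))
        expected = np.array(
            [stats.f_oneway(Y[groups == 0, j], Y[groups == 1, j]).statistic for j in range(40)]
        )
        assert np.max(np.abs(F - expected)) < 1e-10

    def test_continuous_covariate_slope_test(self):
        """1-df slope F equals the squared t of the OLS slope."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=10)
        Y = np.outer(2 * x, np.ones(5)) + rng.normal(0, 1, size=(10, 5))
        design = RegressionDesign(
            ["intercept", "x"], np.column_stack([np.ones(10), x]), [1]
        )
        F = pointwise_F(curve_matrix(Y), design)
        for j in range(5):
            res = stats.linregress(x, Y[:, j])
            t2 = (res.slope / res.stderr) ** 2
            assert F[j] == pytest.approx(t2, rel=1e-9)

    def test_perfect_fit_reports_infinite_F(self):
        x = np.arange(6, dtype=float)
        Y = np.outer(x, np.ones(4)) * 3.0 + 1.0  # exact linear function of x
        design = RegressionDesign(
            ["intercept", "x"], np.column_stack([np.ones(6), x]), [1]
        )
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            F = pointwise_F(curve_matrix(Y), design)
        assert np.isinf(F).all()

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(DesignError, match="collinear"):
            RegressionDesign(
                ["intercept", "x", "x2"],
                np.column_stack([np.ones(6), x, 2 * x]),
                [1],
            )

    def test_needs_more_subjects_than_columns(self):
        Y = np.ones((2, 5))
        with pytest.raises(DesignError):
            pointwise_F(curve_matrix(Y), binary_design([0, 1]))


def enumeration_p_curve(Y, groups):
    """Exhaustive-permutation oracle: p(t) over all distinct assignments."""
    n = len(groups)
    k = int(np.sum(groups))
    obs = pointwise_F(curve_matrix(Y), binary_design(groups))
    all_F = []
    for ones in itertools.combinations(range(n), k):
        g = np.zeros(n)
        g[list(ones)] = 1
        all_F.append(pointwise_F(curve_matrix(Y), binary_design(g)))
    all_F = np.array(all_F)
    return np.mean(all_F >= obs[None, :], axis=0)


class TestPermutationTest:
    def test_sampled_p_matches_exhaustive_enumeration(self):
        """n=5, 2-level factor: 10 distinct assignments enumerated exactly."""
        rng = np.random.default_rng(21)
        Y = rng.normal(30, 8, size=(5, 30))
        groups = np.array([1, 1, 0, 0, 0])
        exact = enumeration_p_curve(Y, groups)
        res = permutation_test(
            curve_matrix(Y), binary_design(groups), n_permutations=10_000, seed=5
        )
        assert np.max(np.abs(res.pointwise_p - exact)) < 0.02

    def test_p_bounded_below_by_identity_inclusion(self):
        rng = np.random.default_rng(22)
        Y = rng.normal(size=(8, 16))
        res = permutation_test(
            curve_matrix(Y), binary_design([0, 0, 0, 0, 1, 1, 1, 1]), 200, seed=2
        )
        assert (res.pointwise_p >= 1 / 200).all()
        assert (res.pointwise_p <= 1).all()
        assert (res.observed_F >= 0).all()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(23)
        Y = rng.normal(size=(10, 12))
        d = binary_design([0] * 5 + [1] * 5)
        a = permutation_test(curve_matrix(Y), d, 100, seed=7)
        b = permutation_test(curve_matrix(Y), d, 100, seed=7)
        assert np.array_equal(a.critical_curve, b.critical_curve)
        assert np.array_equal(a.pointwise_p, b.pointwise_p)

    def test_subject_relabeling_invariance(self):
        """Moving curves and covariates together leaves the F curve fixed."""
        rng = np.random.default_rng(24)
        Y = rng.normal(size=(12, 20))
        g = np.array([0, 1] * 6, dtype=float)
        F1 = pointwise_F(curve_matrix(Y), binary_design(g))
        order = rng.permutation(12)
        F2 = pointwise_F(curve_matrix(Y[order]), binary_design(g[order]))
        assert np.allclose(F1, F2, atol=1e-10)

    def test_tiny_factor_level_rejected(self):
        rng = np.random.default_rng(25)
        Y = rng.normal(size=(5, 8))
        with pytest.raises(DesignError, match="< 2 subjects"):
            permutation_test(curve_matrix(Y), binary_design([1, 0, 0, 0, 0]), 50, seed=1)

    def test_adjusted_design_permutes_only_tested_column(self):
        rng = np.random.default_rng(26)
        n = 16
        x = rng.normal(size=n)
        g = np.array([0, 1] * (n // 2), dtype=float)
        Y = np.outer(x, np.ones(10)) + rng.normal(0, 0.1, size=(n, 10))
        design = RegressionDesign(
            ["intercept", "group", "x"],
            np.column_stack([np.ones(n), g, x]),
            test_columns=[1],
        )
        res = permutation_test(curve_matrix(Y), design, 200, seed=3)
        # x explains the curves, the permuted group does not: p stays null-like
        assert np.median(res.pointwise_p) > 0.1


def result_with(sig_mask, grid=None):
    sig_mask = np.asarray(sig_mask, dtype=bool)
    G = sig_mask.size
    grid = np.arange(G) if grid is None else grid
    obs = np.where(sig_mask, 2.0, 0.5)
    return FLMResult(
        grid=grid,
        observed_F=obs,
        critical_curve=np.ones(G),
        pointwise_p=np.where(sig_mask, 0.01, 0.5),
        n_permutations=500,
        alpha=0.05,
        seed=0,
    )


class TestSignificantIntervals:
    def test_no_significance_empty_list(self):
        assert significant_intervals(result_with(np.zeros(1440))) == []

    def test_single_run_reported_in_clock_time(self):
        mask = np.zeros(1440)
        mask[100:200] = 1
        (iv,) = significant_intervals(result_with(mask))
        assert iv["start_clock"] == "01:40"
        assert iv["end_clock"] == "03:20"
        assert iv["duration_minutes"] == 100

    def test_midnight_wrap_is_one_interval(self):
        mask = np.zeros(1440)
        mask[1430:] = 1
        mask[:10] = 1
        (iv,) = significant_intervals(result_with(mask))
        assert iv["start_clock"] == "23:50"
        assert iv["end_clock"] == "00:10"
        assert iv["duration_minutes"] == 20

    def test_all_significant_is_full_day(self):
        (iv,) = significant_intervals(result_with(np.ones(1440)))
        assert iv["duration_minutes"] == 1440

    def test_coarse_grid_durations_scale_with_step(self):
        mask = np.zeros(144)
        mask[6:12] = 1  # 01:00-02:00 on a 10-min grid
        (iv,) = significant_intervals(result_with(mask, grid=np.arange(0, 1440, 10)))
        assert iv["start_clock"] == "01:00"
        assert iv["duration_minutes"] == 60

    def test_intervals_match_mask_exactly(self):
        rng = np.random.default_rng(31)
        mask = rng.random(1440) < 0.2
        res = result_with(mask)
        rebuilt = np.zeros(1440, dtype=bool)
        for iv in significant_intervals(res):
            for m in range(iv["start_minute"], iv["end_minute"]):
                rebuilt[m % 1440] = True
        assert np.array_equal(rebuilt, mask.astype(bool))
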