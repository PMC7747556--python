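"""Day/night mixed models, all-subsets candidates and conditional averaging."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actiflm.io import cohort_summaries
from actiflm.lmm import (
    DEFAULT_TERMS,
    ModelError,
    build_summary_table,
    conditional_average,
    dredge_and_average,
    fit_random_intercept_model,
    simulate_summary_table,
)


def fake_summaries(n_subjects=42, n_days=14):
    dates = pd.date_range("2020-01-06", periods=n_days, freq="D")
    rows = []
    for i in range(n_subjects):
        for d in dates:
            rows.append(
                {
                    "subject_id": f"dog{i:03d}",
                    "date": d.date(),
                    "day_type": "weekend" if d.weekday() >= 5 else "weekday",
                    "daytime_mean_count": 100.0 + i,
                    "nighttime_mean_count": 10.0 + i,
                }
            )
    return pd.DataFrame(rows)


def fake_metadata(n_subjects=42, seed=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": [f"dog{i:03d}" for i in range(n_subjects)],
            "age": rng.uniform(2, 9, n_subjects),
            "sex": ["F", "M"] * (n_subjects // 2),
            "mass": rng.uniform(3, 45, n_subjects),
        }
    )


class TestBuildSummaryTable:
    def test_log_transform_with_offset(self):
        summ = fake_summaries(4, 2)
        summ["daytime_mean_count"] = 7.0
        t = build_summary_table(summ, fake_metadata(4), "daytime")
        assert np.allclose(t["log_activity"], np.log(8.0))

    def test_study_size_gives_588_rows(self):
        t = build_summary_table(fake_summaries(42, 14), fake_metadata(42), "daytime")
        assert len(t) == 588  # 42 x 14

    def test_missing_night_dropped_from_night_table_only(self):
        summ = fake_summaries(4, 3)
        summ.loc[0, "nighttime_mean_count"] = np.nan
        day = build_summary_table(summ, fake_metadata(4), "daytime")
        night = build_summary_table(summ, fake_metadata(4), "nighttime")
        assert len(day) == 12
        assert len(night) == 11

    def test_standardized_columns(self):
        t = build_summary_table(fake_summaries(10, 7), fake_metadata(10), "daytime")
        assert abs(t["age_z"].mean()) < 1e-12
        assert t["age_z"].std(ddof=1) == pytest.approx(1.0)
        assert set(t["day_type_dummy"]) == {0.0, 1.0}

    def test_bad_offset_rejected(self):
        with pytest.raises(ModelError):
            build_summary_table(fake_summaries(4, 2), fake_metadata(4), "daytime", log_offset=0)


class TestFitRandomInterceptModel:
    def test_matches_ols_when_no_group_variance(self):
        """OLS oracle: with zero true random-intercept variance the ML fixed
        effects coincide with ordinary least squares."""
        table = simulate_summary_table(
            30, 20, {"day_type": 0.3, "age": -0.2}, random_intercept_sd=0.0, seed=3
        )
        fit = fit_random_intercept_model(table, ("day_type", "age"))
        X = sm.add_constant(table[["day_type_dummy", "age_z"]].to_numpy())
        ols = sm.OLS(table["log_activity"].to_numpy(), X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-5)
        assert fit.boundary

    def test_recovers_known_coefficients(self):
        hits = 0
        truth = {"day_type": 0.25, "age": -0.3}
        for rep in range(20):
            table = simulate_summary_table(42, 14, truth, seed=100 + rep)
            fit = fit_random_intercept_model(table, ("day_type", "age"))
            ok = all(
                abs(fit.params[k] - v) < 1.96 * fit.bse[k] for k, v in truth.items()
            )
            hits += ok
        assert hits >= 17  # ~95% nominal coverage of both CIs jointly

    def test_intercept_only_nested_sanity(self):
        table = simulate_summary_table(30, 14, {"day_type": 0.5}, seed=5)
        full = fit_random_intercept_model(table, ("day_type",))
        null = fit_random_intercept_model(table, ())
        assert np.isfinite(null.aic)
        assert null.aic > full.aic

    def test_aic_invariant_to_predictor_scaling(self):
        table = simulate_summary_table(20, 10, {"age": -0.3, "mass": 0.1}, seed=6)
        fit_std = fit_random_intercept_model(table, ("age", "mass"))
        raw = table.copy()
        raw["age_z"] = raw["age"]  # undo standardization: pure reparametrization
        raw["mass_z"] = raw["mass"]
        fit_raw = fit_random_intercept_model(raw, ("age", "mass"))
        assert fit_std.llf == pytest.approx(fit_raw.llf, abs=1e-4)
        assert fit_std.aic == pytest.approx(fit_raw.aic, abs=1e-4)

    def test_constant_predictor_rejected(self):
        table = simulate_summary_table(10, 5, seed=7)
        table["day_type_dummy"] = 0.0
        with pytest.raises(ModelError, match="constant"):
            fit_random_intercept_model(table, ("day_type",))


class TestConditionalAverage:
    def test_two_model_hand_computation(self):
        """Hand-worked average of two models with weights 0.75/0.25."""
        est, se = conditional_average([0.4, 0.8], [0.1, 0.2], [0.75, 0.25])
        expected_est = 0.75 * 0.4 + 0.25 * 0.8  # 0.5
        assert est == pytest.approx(expected_est)
        expected_var = 0.75 * (0.1**2 + (0.4 - 0.5) ** 2) + 0.25 * (0.2**2 + (0.8 - 0.5) ** 2)
        assert se == pytest.approx(np.sqrt(expected_var))

    def test_weights_renormalized(self):
        a = conditional_average([1.0, 2.0], [0.1, 0.1], [2.0, 6.0])
        b = conditional_average([1.0, 2.0], [0.1, 0.1], [0.25, 0.75])
        assert a == pytest.approx(b)

    def test_single_model_passthrough(self):
        est, se = conditional_average([0.3], [0.07], [1.0])
        assert (est, se) == pytest.approx((0.3, 0.07))


class TestDredgeAndAverage:
    def test_candidate_set_is_all_subsets(self):
        table = simulate_summary_table(20, 10, {"day_type": 0.3}, seed=8)
        res = dredge_and_average(table, DEFAULT_TERMS)
        assert len(res.candidates) == 16
        assert res.candidates["delta_AIC"].min() == 0.0
        retained = res.candidates[res.candidates["retained"]]
        assert retained["weight"].sum() == pytest.approx(1.0)

    def test_dominant_model_recovers_its_coefficients(self):
        """With overwhelming signal one model takes ~all the weight and the
        averaged coefficients collapse onto its estimates."""
        table = simulate_summary_table(
            42, 14,
            {"day_type": 1.0, "age": -1.0, "sex": 0.8, "mass": 0.9},
            resid_sd=0.05, random_intercept_sd=0.05, seed=9,
        )
        res = dredge_and_average(table, DEFAULT_TERMS)
        best = fit_random_intercept_model(table, DEFAULT_TERMS)
        top_weight = res.candidates["weight"].max()
        assert top_weight > 0.999
        for _, row in res.terms_table.iterrows():
            assert abs(row["estimate"] - best.params[row["term"]]) < 1e-3

    def test_estimates_are_convex_combinations(self):
        table = simulate_summary_table(30, 10, {"age": -0.2}, seed=10)
        res = dredge_and_average(table, DEFAULT_TERMS)
        fits = {}
        for r in range(5):
            for combo in itertools.combinations(DEFAULT_TERMS, r):
                fits[combo] = fit_random_intercept_model(table, combo)
        for _, row in res.terms_table.iterrows():
            betas = [f.params[row["term"]] for c, f in fits.items() if row["term"] in c]
            assert min(betas) - 1e-9 <= row["estimate"] <= max(betas) + 1e-9

    def test_table1_style_layout(self):
        table = simulate_summary_table(20, 10, {"day_type": 0.3}, seed=11)
        res = dredge_and_average(table, DEFAULT_TERMS)
        styled = res.table1_style()
        assert list(styled.columns) == [
            "Predictor variable",
            "Estimate (SE)",
            "z-value",
            "p value",
            "95% CI",
        ]
        assert "Day type (weekend)" in set(styled["Predictor variable"])

    def test_bad_delta_rejected(self):
        table = simulate_summary_table(10, 6, seed=12)
        with pytest.raises(ModelError):
            dredge_and_average(table, ("day_type",), delta_max=0.0)


class TestEndToEndFromCohort(object):
    def test_cohort_summaries_feed_the_models(self, small_cohort, tmp_path):
        from actiflm.io import load_cohort

        small_cohort.write(tmp_path)
        cohort = load_cohort(tmp_path)
        summ = cohort_summaries(cohort)
        day = build_summary_table(summ, cohort.subjects, "daytime")
        fit = fit_random_intercept_model(day, DEFAULT_TERMS)
        assert np.isfinite(fit.aic)
        assert fit.params["day_type"] > 0  # weekends are busier by construction
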