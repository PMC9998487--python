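"""Additive mixed model: fitting, AIC comparison, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oryxhr.errors import FittingError, SingularDesignError
from oryxhr.model import (Factor, Linear, ModelSpec, Smooth, SmoothByFactor,
                          compare_models, fit_additive_model,
                          partial_effect_table, residual_acf, standard_ladder,
                          subsample_refit)
from oryxhr.synth import generate_hourly_ar1_series


def grouped_frame(rng, n, effects=None, sd=1.0, n_groups=5):
    g = rng.integers(0, n_groups, n)
    offsets = np.linspace(-2, 2, n_groups)
    df = pd.DataFrame({"animal_id": [f"a{i}" for i in g]})
    df["hr_mean"] = 60.0 + offsets[g] + rng.normal(0, sd, n)
    if effects:
        for col, fn in effects.items():
            x = rng.uniform(0, 60, n)
            df[col] = x
            df["hr_mean"] += fn(x)
    return df


class TestFitting:
    def test_linear_activity_slope_recovered(self):
        rng = np.random.default_rng(1)
        df = grouped_frame(rng, 5000, {"activity_minutes": lambda x: 10.0 * x / 60.0})
        fit = fit_additive_model(
            df, ModelSpec("lin", (Linear("activity_minutes"),), "animal_id"))
        slope = fit.coef_table.set_index("term").loc["activity_minutes", "estimate"]
        assert slope == pytest.approx(10.0 / 60.0, rel=0.05)

    def test_constant_response_intercept_only(self):
        df = pd.DataFrame({"hr_mean": np.full(100, 60.0),
                           "animal_id": ["a", "b"] * 50})
        fit = fit_additive_model(df, ModelSpec("null", (), "animal_id"))
        assert fit.coef_table["estimate"].iloc[0] == pytest.approx(60.0)
        assert fit.r2_generalized == pytest.approx(0.0, abs=1e-9)

    def test_log_likelihood_matches_brute_force_normal_density(self):
        rng = np.random.default_rng(2)
        df = grouped_frame(rng, 500, {"activity_minutes": lambda x: x / 10.0})
        fit = fit_additive_model(
            df, ModelSpec("m", (Smooth("activity_minutes", 3),), "animal_id"))
        s2_ml = np.mean(fit.residuals ** 2)
        brute = stats.norm.logpdf(fit.residuals, 0.0, np.sqrt(s2_ml)).sum()
        assert fit.log_likelihood == pytest.approx(brute, abs=1e-8)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.edf, abs=1e-8)

    def test_smooth_fitted_values_sum_to_zero(self, full_fit):
        fit = full_fit
        for term in ("s(activity_minutes)", "s(hour)", "s(temp_f)"):
            sl = fit.design.slices[term]
            contrib = fit.design.X[:, sl] @ fit.beta[sl.start:sl.stop]
            assert abs(contrib.sum()) < 1e-6 * max(1.0, np.abs(contrib).max()) + 1e-8

    def test_random_intercepts_track_group_offsets(self):
        rng = np.random.default_rng(3)
        df = grouped_frame(rng, 4000, sd=1.0)
        fit = fit_additive_model(df, ModelSpec("null", (), "animal_id"))
        re = fit.random_effects.sort_index()
        assert np.corrcoef(re.to_numpy(), np.linspace(-2, 2, 5))[0, 1] > 0.99

    def test_collinear_design_raises_singular_error(self):
        rng = np.random.default_rng(4)
        df = grouped_frame(rng, 200, {"activity_minutes": lambda x: 0.1 * x})
        df["copy"] = df["activity_minutes"]
        spec = ModelSpec("bad", (Linear("activity_minutes"), Linear("copy")), None)
        with pytest.raises(SingularDesignError):
            fit_additive_model(df, spec)

    def test_missing_covariate_rows_dropped_and_reported(self):
        rng = np.random.default_rng(5)
        df = grouped_frame(rng, 300, {"activity_minutes": lambda x: 0.1 * x})
        df.loc[df.index[:25], "activity_minutes"] = np.nan
        fit = fit_additive_model(
            df, ModelSpec("m", (Linear("activity_minutes"),), "animal_id"))
        assert fit.dropped_rows == 25
        assert fit.n == 275

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"hr_mean": np.arange(10.0), "animal_id": ["a", "b"] * 5})
        with pytest.raises(FittingError, match="50"):
            fit_additive_model(df, ModelSpec("m", (), "animal_id"))


class TestPartialEffects:
    def test_linear_partial_is_centered_line(self):
        rng = np.random.default_rng(6)
        df = grouped_frame(rng, 2000, {"activity_minutes": lambda x: 0.2 * x}, sd=0.5)
        fit = fit_additive_model(
            df, ModelSpec("m", (Linear("activity_minutes"),), "animal_id"))
        xbar = df["activity_minutes"].mean()
        pe = partial_effect_table(fit, "activity_minutes", [xbar, xbar + 10.0])
        assert pe["estimate"].iloc[0] == pytest.approx(0.0, abs=0.05)
        assert pe["estimate"].iloc[1] == pytest.approx(2.0, abs=0.1)

    def test_smooth_recovers_sinusoid_within_3_se(self):
        rng = np.random.default_rng(7)
        n = 4000
        x = rng.uniform(0, 24, n)
        true = 5.0 * np.cos(2 * np.pi * (x - 17.0) / 24.0)
        df = pd.DataFrame({"hr_mean": 60.0 + true + rng.normal(0, 1.0, n),
                           "hour": x, "animal_id": "a"})
        fit = fit_additive_model(df, ModelSpec("m", (Smooth("hour", 8),), None))
        grid = np.linspace(0.5, 23.5, 47)
        pe = partial_effect_table(fit, "s(hour)", grid)
        truth = 5.0 * np.cos(2 * np.pi * (grid - 17.0) / 24.0)
        truth = truth - truth.mean()
        dev = np.abs(pe["estimate"].to_numpy() - truth)
        assert np.all(dev < 3 * pe["std_error"].to_numpy() + 0.15)

    def test_single_point_grid_and_unknown_term(self, full_fit):
        pe = partial_effect_table(full_fit, "s(hour)", [12.0])
        assert len(pe) == 1
        with pytest.raises(KeyError):
            partial_effect_table(full_fit, "s(nope)", [0.0])

    def test_interaction_deviations_sum_to_zero_across_levels(self, full_fit):
        grid = np.arange(24.0)
        levels = ["spring", "summer", "winter"]
        total = sum(partial_effect_table(full_fit, "s(hour):season", grid,
                                         level=lev)["estimate"].to_numpy()
                    for lev in levels)
        assert np.allclose(total, 0.0, atol=1e-8)


class TestModelComparison:
    def test_single_spec_daic_zero(self):
        rng = np.random.default_rng(8)
        df = grouped_frame(rng, 500)
        tab = compare_models(df, [ModelSpec("only", (), "animal_id")])
        assert tab["daic"].iloc[0] == 0.0

    def test_null_data_prefers_parsimonious_model(self):
        rng = np.random.default_rng(9)
        df = grouped_frame(rng, 2000)
        df["junk"] = rng.normal(0, 1, len(df))
        tab = compare_models(df, [
            ModelSpec("null", (), "animal_id"),
            ModelSpec("junk", (Smooth("junk", 3),), "animal_id")])
        null_aic = tab.set_index("model").loc["null", "aic"]
        assert null_aic - tab["aic"].min() < 10.0

    def test_noise_covariate_rarely_lowers_aic(self):
        # pure-noise smooth should cost its edf: mean AIC improvement ~ 0
        diffs = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            df = grouped_frame(rng, 1500)
            df["junk"] = rng.normal(0, 1, len(df))
            f0 = fit_additive_model(df, ModelSpec("null", (), "animal_id"))
            f1 = fit_additive_model(df, ModelSpec("junk", (Smooth("junk", 3),),
                                                  "animal_id"))
            diffs.append(f0.aic - f1.aic)
        assert np.mean(diffs) < 3.0

    def test_failed_spec_is_marked_and_comparison_proceeds(self):
        rng = np.random.default_rng(10)
        df = grouped_frame(rng, 300)
        df["season"] = "winter"  # single level -> factor cannot be coded
        with pytest.warns(UserWarning, match="failed"):
            tab = compare_models(df, [ModelSpec("null", (), "animal_id"),
                                      ModelSpec("bad", (Factor("season"),),
                                                "animal_id")])
        assert bool(tab.set_index("model").loc["bad", "failed"]) is True
        assert bool(tab.set_index("model").loc["null", "failed"]) is False


class TestResidualAcf:
    def test_iid_residuals_have_no_lag1_structure(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "hr_mean": 60.0 + rng.normal(0, 3, 10_000),
            "animal_id": "a",
            "hour_start": pd.date_range("2019-01-01", periods=10_000, freq="h")})
        fit = fit_additive_model(df, ModelSpec("null", (), None))
        rep = residual_acf(fit, max_lag=5)
        assert abs(rep.within(1)) < 0.05

    def test_ar1_residuals_recover_coefficient(self):
        df = generate_hourly_ar1_series(n_animals=1, n_days=400,
                                        circadian_amplitude=0.0,
                                        ar1_coefficient=0.7, seed=12)
        fit = fit_additive_model(
            df.assign(animal_id="a", extra="b"),
            ModelSpec("null", (), None))
        rep = residual_acf(fit, max_lag=3)
        assert rep.pooled(1) == pytest.approx(0.70, abs=0.03)

    def test_unmodeled_circadian_signal_peaks_at_lag_24(self):
        df = generate_hourly_ar1_series(seed=13)
        fit = fit_additive_model(df, ModelSpec("null", (), "animal_id"))
        rep = residual_acf(fit, max_lag=30)
        assert rep.within(24) > rep.within(12)

    def test_constant_residuals_rejected(self):
        df = pd.DataFrame({"hr_mean": np.full(100, 60.0),
                           "animal_id": ["a", "b"] * 50})
        fit = fit_additive_model(df, ModelSpec("null", (), "animal_id"))
        with pytest.raises(FittingError):
            residual_acf(fit)


class TestSubsampleRefit:
    def test_deterministic_given_seed(self, full_frame_truth):
        frame, _ = full_frame_truth
        spec = standard_ladder()[-1]
        a = subsample_refit(frame, spec, 500, seed=3)
        b = subsample_refit(frame, spec, 500, seed=3)
        pd.testing.assert_frame_equal(a.comparison, b.comparison)

    def test_full_sized_subsample_reproduces_full_fit(self):
        rng = np.random.default_rng(14)
        df = grouped_frame(rng, 400, {"activity_minutes": lambda x: 0.1 * x})
        spec = ModelSpec("m", (Linear("activity_minutes"),), "animal_id")
        with pytest.warns(UserWarning, match="using all"):
            res = subsample_refit(df, spec, n_per_group=10_000, seed=0)
        np.testing.assert_allclose(res.comparison["estimate_full"],
                                   res.comparison["estimate_sub"], atol=1e-10)

    def test_estimates_consistent_between_full_and_subsample(self, full_frame_truth):
        frame, _ = full_frame_truth
        res = subsample_refit(frame, standard_ladder()[-1], 500, seed=1)
        z = res.comparison["std_diff"].abs()
        assert (z < 4.0).all()
        assert (z < 2.0).mean() >= 0.8
        # covariate importance unchanged: same signs for clearly
        # significant terms
        sig = res.comparison[res.comparison["p_full"] < 1e-6]
        assert (np.sign(sig["estimate_full"]) == np.sign(sig["estimate_sub"])).all()
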