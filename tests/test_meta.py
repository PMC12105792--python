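"""Logit transform, SE imputation, and the weighted mixed meta-regression."""

import numpy as np
import pandas as pd
import pytest

from feederdiff import (
    fit_weighted_lmm,
    impute_fixed_zero_se,
    logit_and_se,
    run_meta_regression,
)


class TestLogitAndSe:
    def test_symmetric_ci_hand_example(self):
        lp, se = logit_and_se(0.5, 0.25, 0.75)
        assert lp == 0.0
        assert se == pytest.approx(2 * np.log(3) / 3.92, abs=1e-12)

    def test_boundary_zero_adjusted(self):
        lp, _ = logit_and_se(0.0, 0.0, 0.5)
        assert lp == pytest.approx(np.log(1e-5 / (1 - 1e-5)), abs=1e-12)

    def test_reflection_negates_logit_preserves_se(self, rng):
        for _ in range(20):
            lo, p, hi = np.sort(rng.random(3))
            lp, se = logit_and_se(p, lo, hi)
            lp_r, se_r = logit_and_se(1 - p, 1 - hi, 1 - lo)
            assert lp_r == pytest.approx(-lp, abs=1e-12)
            assert se_r == pytest.approx(se, abs=1e-12)

    def test_invalid_interval_errors(self):
        with pytest.raises(ValueError):
            logit_and_se(0.5, 0.8, 0.2)


class TestImputeFixedZeroSe:
    def _table(self, sources, ses):
        return pd.DataFrame(
            {
                "source": sources,
                "logit_se": ses,
                "logit_pst": 0.0,
                "feeder_id": "F1",
            }
        )

    def test_mean_of_social_ses(self):
        t = self._table(
            ["social_fit", "social_fit", "fixed_zero"], [0.5, 1.5, np.nan]
        )
        out = impute_fixed_zero_se(t)
        assert out.loc[2, "logit_se"] == pytest.approx(1.0)
        assert out.loc[2, "weight"] == pytest.approx(1.0)

    def test_no_fixed_zero_rows_unchanged(self):
        t = self._table(["social_fit", "social_fit"], [0.5, 1.5])
        out = impute_fixed_zero_se(t)
        np.testing.assert_allclose(out["logit_se"], [0.5, 1.5])

    def test_constant_ses_impute_constant(self):
        t = self._table(["social_fit", "fixed_zero", "fixed_zero"], [0.7, np.nan, np.nan])
        out = impute_fixed_zero_se(t)
        np.testing.assert_allclose(out["logit_se"], 0.7)

    def test_no_social_estimates_errors(self):
        with pytest.raises(ValueError, match="impute"):
            impute_fixed_zero_se(self._table(["fixed_zero"], [np.nan]))


def _sim_data(rng, n=29, b=(1.0, -0.6, 0.2), sigma2_feeder=0.0, n_feeders=8):
    temp = rng.uniform(-12, 6, n)
    dp = rng.integers(1, 5, n).astype(float)
    feeder = rng.integers(0, n_feeders, n)
    se = rng.uniform(0.3, 2.0, n)
    w = 1.0 / se**2
    u = rng.normal(0, np.sqrt(sigma2_feeder), n_feeders)
    y = b[0] + b[1] * temp + b[2] * dp + u[feeder] + rng.normal(0, se)
    return pd.DataFrame(
        {
            "logit_pst": y,
            "temp": temp,
            "dp": dp,
            "feeder_id": [f"F{f}" for f in feeder],
            "weight": w,
        }
    )


class TestFitWeightedLmm:
    def test_zero_feeder_variance_equals_closed_form_wls(self, rng):
        df = _sim_data(rng)
        fit = fit_weighted_lmm(df, fix_group_var=0.0)
        X = np.column_stack([np.ones(len(df)), df["temp"], df["dp"]])
        W = np.diag(df["weight"].to_numpy())
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ df["logit_pst"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert fit.sigma2_feeder == 0.0

    def test_equal_weights_no_grouping_matches_ols(self, rng):
        df = _sim_data(rng)
        df["weight"] = 1.0
        df["feeder_id"] = [f"G{i}" for i in range(len(df))]  # one obs per level
        fit = fit_weighted_lmm(df, fix_group_var=0.0)
        X = np.column_stack([np.ones(len(df)), df["temp"], df["dp"]])
        beta, *_ = np.linalg.lstsq(X, df["logit_pst"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_weight_rescaling_leaves_coefficients_unchanged(self, rng):
        df = _sim_data(rng, sigma2_feeder=0.5)
        fit1 = fit_weighted_lmm(df)
        df2 = df.assign(weight=df["weight"] * 7.3)
        fit2 = fit_weighted_lmm(df2)
        np.testing.assert_allclose(
            fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-5
        )

    def test_reml_and_ml_agree_with_zero_feeder_variance(self, rng):
        df = _sim_data(rng)
        reml = fit_weighted_lmm(df, method="REML", fix_group_var=0.0)
        ml = fit_weighted_lmm(df, method="ML", fix_group_var=0.0)
        np.testing.assert_allclose(
            reml.params.to_numpy(), ml.params.to_numpy(), atol=1e-6
        )

    def test_recovers_feeder_variance_when_present(self, rng):
        df = _sim_data(rng, n=160, sigma2_feeder=4.0, n_feeders=8)
        fit = fit_weighted_lmm(df)
        assert fit.sigma2_feeder > 0.5

    def test_singular_design_errors_naming_columns(self, rng):
        df = _sim_data(rng)
        df["dp"] = 2 * df["temp"]
        with pytest.raises(ValueError, match="singular"):
            fit_weighted_lmm(df)


class TestRunMetaRegression:
    def _tables(self, psts, sources, dps, feeders):
        pst_table = pd.DataFrame(
            {
                "feeder_id": feeders,
                "dp_index": dps,
                "pst": psts,
                "pst_lower": [max(0.0, p - 0.2) if s == "social_fit" else np.nan
                              for p, s in zip(psts, sources)],
                "pst_upper": [min(1.0, p + 0.2) if s == "social_fit" else np.nan
                              for p, s in zip(psts, sources)],
                "source": sources,
            }
        )
        temps = pd.DataFrame(
            {"dp_index": [1, 2, 3, 4], "daytime_avg_temp": [-9.0, -11.0, 4.0, -2.0]}
        )
        return pst_table, temps

    def test_constant_response_gives_zero_slopes(self):
        n = 12
        pst_table, temps = self._tables(
            [0.5] * n, ["social_fit"] * n, [1, 2, 3, 4] * 3,
            [f"F{i//4}" for i in range(n)],
        )
        fit, tidy = run_meta_regression(pst_table, temps)
        assert fit.params["temp"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["dp"] == pytest.approx(0.0, abs=1e-8)

    def test_missing_temperature_errors(self):
        pst_table, temps = self._tables(
            [0.5, 0.4], ["social_fit", "social_fit"], [1, 2], ["F1", "F1"]
        )
        with pytest.raises(ValueError, match="missing temperature"):
            run_meta_regression(pst_table, temps[temps.dp_index != 2])

    def test_dropping_dp_covariate_changes_predictors(self):
        n = 12
        pst_table, temps = self._tables(
            list(np.linspace(0.2, 0.9, n)), ["social_fit"] * n,
            [1, 2, 3, 4] * 3, [f"F{i//4}" for i in range(n)],
        )
        _, tidy_full = run_meta_regression(pst_table, temps)
        _, tidy_reduced = run_meta_regression(pst_table, temps, include_dp=False)
        assert "dp" in set(tidy_full["predictor"])
        assert "dp" not in set(tidy_reduced["predictor"])

    def test_tidy_report_round_trips_through_csv(self, tmp_path, rng):
        n = 16
        pst_table, temps = self._tables(
            list(rng.uniform(0.2, 0.9, n)),
            ["social_fit"] * (n - 2) + ["fixed_zero"] * 2,
            [1, 2, 3, 4] * 4, [f"F{i//4}" for i in range(n)],
        )
        pst_table.loc[pst_table["source"] == "fixed_zero", "pst"] = 0.0
        fit, tidy = run_meta_regression(pst_table, temps)
        path = tmp_path / "coef.csv"
        tidy.to_csv(path, index=False)
        back = pd.read_csv(path, float_precision="round_trip")
        pd.testing.assert_frame_equal(back, tidy)
        row = back[back["predictor"] == "temp"].iloc[0]
        assert row["estimate"] == fit.params["temp"]
        assert row["se"] == fit.bse["temp"]
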