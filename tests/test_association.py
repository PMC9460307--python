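import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdpatterns.association import (
    SurveyDesign,
    compute_eer,
    fit_adjusted_model,
    misreporting_ratio,
    tukey_kramer_adjust,
)

from _oracles import studentized_range_sf


class TestEER:
    def test_adult_male_reference_value(self):
        assert compute_eer("male", 30, 80, 1.80) == pytest.approx(2620.18)

    def test_adult_female_reference_value(self):
        assert compute_eer("female", 30, 65, 1.65) == pytest.approx(1953.00)

    def test_monotone_in_weight_height_age(self):
        base = compute_eer("male", 40, 80, 1.80)
        assert compute_eer("male", 40, 85, 1.80) > base
        assert compute_eer("male", 40, 80, 1.85) > base
        assert compute_eer("male", 50, 80, 1.80) < base

    def test_non_adult_age_rejected(self):
        with pytest.raises(ValueError):
            compute_eer("female", 17, 60, 1.6)


class TestMisreporting:
    @pytest.mark.parametrize("ei,eer,expected", [(2000, 2500, 0.8), (2500, 2500, 1.0), (3000, 2000, 1.5)])
    def test_ratio(self, ei, eer, expected):
        assert misreporting_ratio(ei, eer) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            misreporting_ratio(0, 2000)


class TestTukeyKramer:
    def test_two_groups_reduce_to_t_test(self):
        diff, se, df = 1.7, 0.6, 37.0
        p_adj = tukey_kramer_adjust([diff], [se], df=df, n_groups=2)[0]
        p_t = 2 * stats.t.sf(abs(diff) / se, df)
        assert p_adj == pytest.approx(p_t, abs=1e-6)

    def test_zero_difference_gives_p_one(self):
        assert tukey_kramer_adjust([0.0], [1.0], df=10, n_groups=4)[0] == 1.0

    def test_matches_quadrature_oracle_four_groups(self):
        p = tukey_kramer_adjust([3.0], [1.0], df=100, n_groups=4)[0]
        expected = studentized_range_sf(3.0 * np.sqrt(2), 4, 100)
        assert p == pytest.approx(expected, abs=1e-5)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            diff, se = rng.normal(0, 2), rng.uniform(0.2, 2)
            p_adj = tukey_kramer_adjust([diff], [se], df=25, n_groups=4)[0]
            p_t = 2 * stats.t.sf(abs(diff) / se, 25)
            assert p_adj >= p_t - 1e-12

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer_adjust([1.0], [0.0], df=10, n_groups=3)


def _toy_records(n=12, seed=0, beta_cluster=(0.0, 2.0), noise=0.0):
    rng = np.random.default_rng(seed)
    cluster = np.array([1, 2] * (n // 2))
    x = rng.uniform(0, 1, n)
    w = rng.uniform(0.5, 2.0, n)
    y = 1.0 + np.take(beta_cluster, cluster - 1) + 0.5 * x
    if noise:
        y = y + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "cluster": cluster,
            "x": x,
            "y": y,
            "weight": w,
            "stratum": np.arange(n) % 3,
            "psu": (np.arange(n) // 3) % 2,
        }
    )


class TestFitAdjustedModel:
    def test_exact_recovery_with_zero_noise(self):
        records = _toy_records()
        fit = fit_adjusted_model(records, "y", covariates=["x"])
        beta = fit.coefficients
        assert beta["(Intercept)"] == pytest.approx(1.0, abs=1e-10)
        assert beta["cluster[2]"] == pytest.approx(2.0, abs=1e-10)
        assert beta["x"] == pytest.approx(0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_weighted_solve(self):
        """Coefficients equal a QR-based solve of the weighted LS problem."""
        records = _toy_records(noise=0.8, seed=3)
        fit = fit_adjusted_model(records, "y", covariates=["x"])
        X = np.column_stack(
            [
                np.ones(len(records)),
                (records["cluster"] == 2).astype(float),
                records["x"],
            ]
        )
        sw = np.sqrt(records["weight"].to_numpy())
        expected, *_ = np.linalg.lstsq(X * sw[:, None], records["y"] * sw, rcond=None)
        assert np.allclose(fit.coefficients.to_numpy(), expected, atol=1e-8)

    def test_matches_statsmodels_wls(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        records = _toy_records(n=40, noise=1.0, seed=4)
        fit = fit_adjusted_model(records, "y", covariates=["x"])
        X = np.column_stack(
            [
                np.ones(len(records)),
                (records["cluster"] == 2).astype(float),
                records["x"],
            ]
        )
        sm_fit = statsmodels.WLS(records["y"], X, weights=records["weight"]).fit()
        assert np.allclose(fit.coefficients.to_numpy(), sm_fit.params, atol=1e-8)

    def test_weight_rescaling_invariance(self):
        records = _toy_records(n=24, noise=0.5, seed=5)
        fit1 = fit_adjusted_model(records, "y", covariates=["x"])
        scaled = records.assign(weight=records["weight"] * 7.3)
        fit2 = fit_adjusted_model(scaled, "y", covariates=["x"])
        assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-10)
        assert np.allclose(fit1.lsmeans["lsmean"], fit2.lsmeans["lsmean"], atol=1e-10)
        assert np.allclose(fit1.lsmeans["se"], fit2.lsmeans["se"], atol=1e-10)
        assert np.allclose(fit1.pairwise["se"], fit2.pairwise["se"], atol=1e-10)

    def test_pairwise_antisymmetry_and_ci(self):
        records = _toy_records(n=36, noise=1.0, seed=6)
        records["cluster"] = np.array([1, 2, 3] * 12)
        fit = fit_adjusted_model(records, "y", covariates=["x"])
        for _, row in fit.pairwise.iterrows():
            assert row["ci_low"] <= row["estimate"] <= row["ci_high"]
            assert 0 < row["p_adj"] <= 1
        means = dict(zip(fit.lsmeans["cluster"], fit.lsmeans["lsmean"]))
        for _, row in fit.pairwise.iterrows():
            assert row["estimate"] == pytest.approx(
                means[row["cluster_a"]] - means[row["cluster_b"]], abs=1e-10
            )

    def test_lonely_psu_errors_unless_centered(self):
        records = _toy_records(n=24, noise=0.5, seed=7)
        records.loc[records.index[-1], "stratum"] = 99  # singleton stratum/PSU
        with pytest.raises(ValueError, match="single PSU"):
            fit_adjusted_model(records, "y", covariates=["x"])
        fit = fit_adjusted_model(
            records, "y", covariates=["x"],
            design=SurveyDesign(lonely_psu="center"),
        )
        assert np.isfinite(fit.pairwise["se"]).all()

    def test_single_cluster_rejected(self):
        records = _toy_records()
        records["cluster"] = 1
        with pytest.raises(ValueError):
            fit_adjusted_model(records, "y", covariates=["x"])

    def test_linearized_se_close_to_robust_se_without_design(self):
        """With one stratum and unit weights the linearized variance is the
        robust (HC) sandwich up to a PSU-count factor; compare on n=2000."""
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        n = 2000
        cluster = rng.integers(1, 5, n)
        x = rng.uniform(0, 1, n)
        y = 1.0 + 0.5 * cluster + x + rng.normal(0, 1, n)
        records = pd.DataFrame(
            {
                "cluster": cluster,
                "x": x,
                "y": y,
                "weight": np.ones(n),
                "stratum": np.zeros(n, dtype=int),
                "psu": np.arange(n),  # each unit its own PSU
            }
        )
        fit = fit_adjusted_model(records, "y", covariates=["x"])
        X = np.column_stack(
            [np.ones(n)]
            + [(cluster == c).astype(float) for c in (2, 3, 4)]
            + [x]
        )
        hc = statsmodels.OLS(y, X).fit(cov_type="HC0")
        ours = np.sqrt(np.diag(fit.covariance.to_numpy()))
        assert np.allclose(ours, hc.bse, rtol=0.10)

    def test_empty_covariate_level_detected(self):
        records = _toy_records(n=24, noise=0.5, seed=9)
        records["grp"] = "only_level"  # constant dummy-source column
        records["dup"] = records["x"]
        with pytest.raises(ValueError):
            fit_adjusted_model(records, "y", covariates=["x", "dup"])
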