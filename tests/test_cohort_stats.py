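"""Mixed models, likelihood-ratio tests, rhythmicity GLM, phase-τ regression
and latitudinal cline summaries."""

import numpy as np
import pandas as pd
import pytest

from circaclock import (
    build_design,
    fit_random_intercept,
    likelihood_ratio_test,
    phase_tau_regression,
    rhythmicity_glm,
    summarize_cline,
)


def sim_lmm(rng, n_lines=10, per_line=6, beta=(24.0, 0.0), sigma_u=0.3,
            sigma=0.4, x_sd=5.0):
    """Random-intercept data: y = b0 + b1*x + u_line + eps."""
    lines = np.repeat(np.arange(n_lines), per_line)
    x = rng.normal(0.0, x_sd, n_lines * per_line)
    u = rng.normal(0.0, sigma_u, n_lines)
    y = beta[0] + beta[1] * x + u[lines] + rng.normal(0.0, sigma, len(x))
    X = np.column_stack([np.ones(len(x)), x])
    return y, X, lines


class TestRandomInterceptFit:
    def test_zero_group_variance_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        y, X, g = sim_lmm(rng, sigma_u=0.0, beta=(24.0, 0.05))
        fit = fit_random_intercept(y, X, g)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)
        assert fit.sigma2_u <= 0.05

    def test_balanced_two_group_closed_form(self):
        """With a saturated group mean design the GLS solution equals the
        plain group means for every variance ratio."""
        y = np.array([1.0, 3.0, 2.0, 10.0, 14.0, 12.0])
        X = np.column_stack([np.ones(6), np.r_[np.zeros(3), np.ones(3)]])
        g = np.array(["a"] * 3 + ["b"] * 3)
        fit = fit_random_intercept(y, X, g)
        assert fit.beta[0] == pytest.approx(2.0, abs=1e-8)       # mean of group a
        assert fit.beta[1] == pytest.approx(10.0, abs=1e-8)      # mean diff

    def test_matches_statsmodels_mixedlm(self):
        """Independent cross-check: ML loglik and coefficients agree with
        statsmodels MixedLM on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        y, X, g = sim_lmm(rng, beta=(24.0, 0.03), sigma_u=0.4)
        ours = fit_random_intercept(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert np.allclose(ours.beta, ref.fe_params, atol=1e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert ours.sigma2 == pytest.approx(ref.scale, rel=0.01)

    def test_planted_slope_recovered_without_bias(self):
        """Planted latitude slope 0.03 h/°N, 20 lines × 6: mean estimate over
        replicates within 3 MC-SE (reduced replicate count; the full run is
        in the acceptance suite)."""
        rng = np.random.default_rng(11)
        est = []
        for _ in range(100):
            y, X, g = sim_lmm(rng, n_lines=20, per_line=6, beta=(24.0, 0.03))
            est.append(fit_random_intercept(y, X, g).beta[1])
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.03) <= 3 * mc_se

    def test_singular_design_rejected(self):
        y = np.arange(6.0)
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="singular"):
            fit_random_intercept(y, X, np.array([0, 0, 0, 1, 1, 1]))

    def test_single_group_falls_back_to_ols(self):
        rng = np.random.default_rng(2)
        y, X, _ = sim_lmm(rng, n_lines=1, per_line=30, sigma_u=0.0)
        fit = fit_random_intercept(y, X, np.zeros(30))
        assert fit.sigma2_u == 0.0


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(3)
        y, X, g = sim_lmm(rng)
        fit = fit_random_intercept(y, X, g)
        lrt, df, p = likelihood_ratio_test(fit, fit)
        assert lrt == 0.0 and df == 0 and p == 1.0

    def test_nesting_monotonicity(self):
        """Adding a covariate never lowers the ML loglikelihood."""
        rng = np.random.default_rng(4)
        y, X, g = sim_lmm(rng, beta=(24.0, 0.0))
        full = fit_random_intercept(y, X, g)
        red = fit_random_intercept(y, X[:, :1], g)
        assert full.loglik >= red.loglik - 1e-8
        lrt, df, p = likelihood_ratio_test(full, red)
        assert df == 1 and lrt >= 0 and 0 <= p <= 1

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            y, X, g = sim_lmm(rng, n_lines=20, per_line=6, beta=(24.0, 0.05))
            full = fit_random_intercept(y, X, g)
            red = fit_random_intercept(y, X[:, :1], g)
            _, _, p = likelihood_ratio_test(full, red)
            hits += p < 0.05
        assert hits / 40 >= 0.95

    def test_differing_n_rejected(self):
        rng = np.random.default_rng(6)
        y, X, g = sim_lmm(rng)
        a = fit_random_intercept(y, X, g)
        b = fit_random_intercept(y[:-6], X[:-6], g[:-6])
        with pytest.raises(ValueError, match="different numbers"):
            likelihood_ratio_test(a, b)


def cohort_table(rng, n=200, p_f=0.68, p_m=0.90):
    sex = np.r_[["F"] * (n // 2), ["M"] * (n // 2)]
    p = np.where(sex == "F", p_f, p_m)
    return pd.DataFrame({
        "individual_id": [f"w{i}" for i in range(n)],
        "population": ["COR"] * (n // 2) + ["OUL"] * (n // 2),
        "latitude": [42.4] * (n // 2) + [65.1] * (n // 2),
        "line": [f"L{i % 10}" for i in range(n)],
        "sex": sex,
        "mating": ["virgin"] * n,
        "rhythmic": rng.random(n) < p,
        "tau_hat_h": rng.normal(24.5, 0.5, n),
    })


class TestRhythmicityGLM:
    def test_identical_proportions_give_null_chi2(self):
        rng = np.random.default_rng(7)
        t = cohort_table(rng, n=400, p_f=0.8, p_m=0.8)
        # force exactly equal counts per sex
        t["rhythmic"] = np.tile(np.r_[np.ones(160, bool), np.zeros(40, bool)], 2)
        res = rhythmicity_glm(t, ["sex"])
        assert res.loc[res["factor"] == "sex", "chi2"].iloc[0] == pytest.approx(
            0.0, abs=1e-8)

    def test_two_by_two_table_matches_binomial_deviance_oracle(self):
        """Deviance χ² for a 90/10 vs 68/32 split equals the closed-form
        2·(ll_groupwise − ll_pooled) binomial computation."""
        t = cohort_table(np.random.default_rng(0), n=200)
        t["rhythmic"] = np.r_[np.ones(68, bool), np.zeros(32, bool),
                              np.ones(90, bool), np.zeros(10, bool)]
        res = rhythmicity_glm(t, ["sex"])

        def ll(y_count, n, p):
            return y_count * np.log(p) + (n - y_count) * np.log(1 - p)

        g = 2 * (ll(68, 100, 0.68) + ll(90, 100, 0.90) - ll(158, 200, 0.79))
        got = res.loc[res["factor"] == "sex", "chi2"].iloc[0]
        assert got == pytest.approx(g, rel=1e-6)

    def test_planted_sex_effect_detected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            res = rhythmicity_glm(cohort_table(rng, n=300), ["sex"])
            hits += res["p"].iloc[0] < 0.01
        assert hits / 40 >= 0.95

    def test_complete_separation_flagged(self):
        t = cohort_table(np.random.default_rng(1), n=40)
        t["rhythmic"] = t["sex"] == "M"
        res = rhythmicity_glm(t, ["sex"])
        assert not res["reliable"].any()


class TestPhaseTauRegression:
    def _table(self, rng, slope=0.2, n=120, noise=0.15):
        peak = (5.0 + rng.normal(0, 1.2, n)) % 24.0
        dev = ((peak - 5.0 + 12) % 24) - 12
        tau = 24.0 + slope * dev + rng.normal(0, noise, n)
        return pd.DataFrame({
            "individual_id": [f"w{i}" for i in range(n)],
            "population": "COR", "latitude": 42.4,
            "line": [f"L{i % 8}" for i in range(n)],
            "sex": "F", "mating": "virgin",
            "rhythmic": True, "tau_hat_h": tau, "peak_zt": peak,
        })

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(12)
        est = np.array([
            phase_tau_regression(self._table(rng)).beta[1] for _ in range(60)
        ])
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.2) <= 3 * mc_se

    def test_wrap_around_midnight_handled(self):
        """Peaks straddling ZT 0 (23.x vs 0.x) regress on the unwrapped
        covariate, not on raw 24-h-discontinuous values."""
        rng = np.random.default_rng(13)
        t = self._table(rng, slope=0.2, n=200)
        t["peak_zt"] = (t["peak_zt"] - 5.0) % 24.0  # recentre cluster at ZT 0
        fit = phase_tau_regression(t)
        assert fit.beta[1] == pytest.approx(0.2, abs=0.1)

    def test_constant_phase_rejected(self):
        t = self._table(np.random.default_rng(2))
        t["peak_zt"] = 6.0
        with pytest.raises(ValueError, match="constant"):
            phase_tau_regression(t)

    def test_too_few_rows_rejected(self):
        t = self._table(np.random.default_rng(2)).iloc[:2]
        with pytest.raises(ValueError, match="at least 3"):
            phase_tau_regression(t)

    def test_null_slope_ci_coverage(self):
        """Independent τ and phase: the 95% CI covers 0 in ≈95% of replicates."""
        rng = np.random.default_rng(14)
        cover = 0
        n_rep = 150
        for _ in range(n_rep):
            fit = phase_tau_regression(self._table(rng, slope=0.0))
            lo = fit.beta[1] - 1.96 * fit.se[1]
            hi = fit.beta[1] + 1.96 * fit.se[1]
            cover += lo <= 0.0 <= hi
        assert 0.90 <= cover / n_rep <= 0.99


class TestCline:
    def _two_pop_table(self, rng, delta=0.82, n_per=60):
        rows = []
        for pop, lat, mean in [("COR", 42.4, 24.2), ("OUL", 65.1, 24.2 + delta)]:
            for i in range(n_per):
                rows.append({
                    "individual_id": f"{pop}{i}", "population": pop,
                    "latitude": lat, "line": f"{pop}_L{i % 6}",
                    "sex": "F", "mating": "virgin", "rhythmic": True,
                    "tau_hat_h": mean + rng.normal(0, 0.3),
                })
        return pd.DataFrame(rows)

    def test_planted_population_difference_recovered(self):
        rng = np.random.default_rng(15)
        cline = summarize_cline(self._two_pop_table(rng))
        pp = cline.per_population.set_index("population")
        diff = pp.loc["OUL", "mean_tau_h"] - pp.loc["COR", "mean_tau_h"]
        assert diff == pytest.approx(0.82, abs=0.2)
        assert list(cline.per_population["population"]) == ["COR", "OUL"]

    def test_flat_cline_has_zero_slope(self):
        rng = np.random.default_rng(16)
        t = self._two_pop_table(rng, delta=0.0)
        cline = summarize_cline(t)
        assert abs(cline.slope_h_per_degN) <= 3 * cline.slope_se + 1e-6

    def test_subgroup_filter_and_empty_rejected(self):
        t = self._two_pop_table(np.random.default_rng(17))
        with pytest.raises(ValueError, match="empty"):
            summarize_cline(t, {"sex": "M"})
        cline = summarize_cline(t, {"sex": "F", "mating": "virgin"})
        assert cline.per_population["n"].sum() == len(t)


def test_build_design_expands_categoricals():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a", "b", "a"]})
    X, names = build_design(df, ["x", "g"])
    assert names == ["Intercept", "x", "g[b]"]
    assert X[:, 2].tolist() == [0.0, 1.0, 0.0]
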