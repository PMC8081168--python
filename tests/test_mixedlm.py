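"""Random-intercept logistic model, pseudo-R2 and calibration test."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from clipcontext.mixedlm import (
    LATENT_RESIDUAL_VAR,
    RandomInterceptLogit,
    fit_random_intercept_logit,
    hosmer_lemeshow_ml,
    mz_r2_fixed,
    table3_report,
)


def _simulate(rng, beta, sigma_u, n_clusters=100, m=10, intercept=0.0, k_x=None):
    beta = np.atleast_1d(beta)
    k = beta.size if k_x is None else k_x
    n = n_clusters * m
    g = np.repeat(np.arange(n_clusters), m)
    X = rng.standard_normal((n, k))
    u = sigma_u * rng.standard_normal(n_clusters)
    eta = intercept + X[:, : beta.size] @ beta + u[g]
    y = (rng.random(n) < expit(eta)).astype(float)
    return y, X, g


class TestFit:
    def test_sigma_zero_recovers_ordinary_logit(self, rng):
        y, X, g = _simulate(rng, [0.8, -0.5], sigma_u=0.0, n_clusters=150)
        fit = fit_random_intercept_logit(y, X, g)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.sigma_u == pytest.approx(0.0, abs=0.05)
        assert np.allclose(fit.params[:-1], ref.params, atol=1e-3)

    def test_lme4_oracle(self, rng, tmp_path):
        """Coefficients, sigma_u and log-likelihood match glmer (nAGQ=15)."""
        y, X, g = _simulate(rng, [1.0], sigma_u=0.8, n_clusters=30, m=8, intercept=0.5)
        fit = fit_random_intercept_logit(y, X[:, :1], g, exog_names=["x"])
        csv = tmp_path / "mm.csv"
        pd.DataFrame({"y": y.astype(int), "x": X[:, 0], "g": g}).to_csv(csv, index=False)
        r_code = (
            f'd <- read.csv("{csv}"); suppressMessages(library(lme4)); '
            "f <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15); "
            'cat(fixef(f), sqrt(unlist(VarCorr(f))), logLik(f), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, sig, llf = map(float, out.stdout.split())
        assert fit.param_series["const"] == pytest.approx(b0, abs=2e-3)
        assert fit.param_series["x"] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma_u == pytest.approx(sig, abs=5e-3)
        assert fit.llf == pytest.approx(llf, abs=1e-3)

    def test_or_recovery_private_places_magnitude(self, rng):
        # generating OR 3.22 for loudness, sigma_u = 1
        beta = np.log(3.22)
        ors = []
        for _ in range(20):
            y, X, g = _simulate(rng, [beta], sigma_u=1.0, n_clusters=200, m=10)
            fit = fit_random_intercept_logit(y, X, g, exog_names=["loudness"])
            ors.append(fit.odds_ratios().set_index("term").loc["loudness", "OR"])
        assert 2.9 <= np.mean(ors) <= 3.6

    def test_null_model_ci_contains_one(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            y, X, g = _simulate(rng, [0.0], sigma_u=0.7, n_clusters=80, m=8)
            fit = fit_random_intercept_logit(y, X, g)
            orr = fit.odds_ratios().iloc[0]
            hits += orr["ci_lo"] <= 1.0 <= orr["ci_hi"]
        assert hits / reps >= 0.85  # ~95% nominal, wide band for 40 reps

    def test_input_validation(self, rng):
        y, X, g = _simulate(rng, [0.5], sigma_u=0.5, n_clusters=20)
        with pytest.raises(ValueError):
            RandomInterceptLogit(np.ones_like(y), X, g)  # constant outcome
        with pytest.raises(ValueError):
            RandomInterceptLogit(y, X, np.zeros_like(g))  # one cluster
        with pytest.raises(ValueError):
            RandomInterceptLogit(y, X, g, n_nodes=4)

    def test_deterministic(self, rng):
        y, X, g = _simulate(rng, [0.4], sigma_u=0.6, n_clusters=50)
        f1 = fit_random_intercept_logit(y, X, g)
        f2 = fit_random_intercept_logit(y, X, g)
        assert np.array_equal(f1.params, f2.params)


class TestMZR2:
    def test_null_betas_zero(self, rng):
        y, X, g = _simulate(rng, [0.0, 0.0], sigma_u=0.5, n_clusters=60)
        fit = fit_random_intercept_logit(y, X, g)
        assert fit.mz_r2() == pytest.approx(0.0, abs=0.02)

    def test_monotone_in_effect_size(self, rng):
        y, X, g = _simulate(rng, [0.5], sigma_u=0.5, n_clusters=80)
        fit = fit_random_intercept_logit(y, X, g)
        base = fit.mz_r2()
        boosted = fit.params.copy()
        boosted[1] *= 2.0
        from clipcontext.mixedlm import RandomInterceptLogitResults

        fit2 = RandomInterceptLogitResults(
            model=fit.model,
            params=boosted,
            cov_params_arr=fit.cov_params_arr,
            llf=fit.llf,
            converged=True,
            grad_norm=0.0,
            separation=False,
        )
        assert fit2.mz_r2() > base

    def test_population_plugin_value(self, rng):
        # R2 = b^2 / (b^2 + sigma_u^2 + pi^2/3) for standard-normal x
        b, sigma_u = 1.0, 1.0
        y, X, g = _simulate(rng, [b], sigma_u=sigma_u, n_clusters=500, m=10)
        fit = fit_random_intercept_logit(y, X, g)
        pop = b**2 / (b**2 + sigma_u**2 + LATENT_RESIDUAL_VAR)
        assert fit.mz_r2() == pytest.approx(pop, abs=0.03)

    def test_explicit_design_matches_results_method(self, rng):
        y, X, g = _simulate(rng, [0.7], sigma_u=0.5, n_clusters=60)
        fit = fit_random_intercept_logit(y, X, g)
        assert mz_r2_fixed(fit, X) == pytest.approx(fit.mz_r2(), abs=1e-12)


class TestHosmerLemeshow:
    def test_perfect_degenerate_fit(self):
        y = np.array([0.0, 1.0] * 60)
        assert hosmer_lemeshow_ml(y.copy(), y, None).chi2 == 0.0

    def test_null_calibration(self, rng):
        rej = 0
        reps = 120
        for _ in range(reps):
            y, X, g = _simulate(rng, [0.8, -0.5], sigma_u=0.0, n_clusters=50, m=10)
            fit = fit_random_intercept_logit(y, X, g)
            rej += fit.hosmer_lemeshow().pvalue < 0.05
        # nominal 5%; binomial 99% band for 120 reps
        assert rej / reps <= 0.11

    def test_detects_gross_misspecification(self, rng):
        # data generated with a quadratic term the model omits
        n = 3000
        g = np.repeat(np.arange(100), 30)
        x = rng.standard_normal(n)
        eta = -1.0 + 2.0 * x**2
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_random_intercept_logit(y, x[:, None], g)
        assert fit.hosmer_lemeshow().pvalue < 0.05


class TestTable3Report:
    def test_nine_models_structure(self, source_table):
        rep = table3_report(source_table)
        fitted = rep[rep["term"] != ""]
        assert set(fitted["source"]) <= {"participants", "annotators", "algorithms"}
        groups = fitted.groupby(["source", "location"])
        for _, grp in groups:
            assert list(grp["term"]) == ["brightness", "loudness", "attendance", "prior_drinks"]
            assert ((grp["ci_lo"] <= grp["OR"]) & (grp["OR"] <= grp["ci_hi"])).all()

    def test_identical_input_identical_report(self, source_table):
        a = table3_report(source_table)
        b = table3_report(source_table)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_outcome_stratum_flagged_not_fatal(self, source_table):
        st = source_table.copy()
        st.loc[st["location_coarse"] == "public", "alcohol"] = 1
        rep = table3_report(st)
        pub = rep[rep["location"] == "public"]
        assert (pub["error"] != "").all()
        other = rep[(rep["location"] != "public") & (rep["term"] != "")]
        assert len(other) > 0

    def test_sign_pattern_recovery(self, source_table):
        """Private-places fits recover the generating signs (darker/louder/more attended)."""
        rep = table3_report(source_table)
        priv = rep[(rep["location"] == "private") & (rep["term"] == "loudness")]
        assert (priv["OR"] > 1.0).all()
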