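import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from alticycle.mixed_models import (
    ConvergenceError,
    ModelFit,
    ModelSpec,
    fit_lmm_ri,
    fit_logistic_ri,
    glmm_loglik_at,
    predict_marginal,
    wald_summary,
)

GAUSS = ModelSpec("y", ("x",), "woman_id", "gaussian")
BINOM = ModelSpec("y", ("x",), "woman_id", "binomial")


def simulate_lmm(rng, G=40, npg=3, beta=(0.5, 0.8), sigma_u=0.6, sigma_e=1.0):
    g = np.repeat(np.arange(G), npg)
    x = rng.normal(size=G * npg)
    u = rng.normal(0, sigma_u, G)
    y = beta[0] + beta[1] * x + u[g] + rng.normal(0, sigma_e, G * npg)
    return pd.DataFrame({"y": y, "x": x, "woman_id": g})


def simulate_glmm(rng, G=40, npg=3, beta=(0.3, 1.0), sigma_u=1.0):
    g = np.repeat(np.arange(G), npg)
    x = rng.normal(size=G * npg)
    u = rng.normal(0, sigma_u, G)
    eta = beta[0] + beta[1] * x + u[g]
    y = rng.binomial(1, expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x": x, "woman_id": g})


def glmm_loglik_oracle(df, beta, sigma_u):
    """Direct adaptive numerical integration of each group's likelihood."""
    X = np.column_stack([np.ones(len(df)), df["x"].to_numpy()])
    y = df["y"].to_numpy()
    ll = 0.0
    for _, idx in df.groupby("woman_id").groups.items():
        Xi, yi = X[df.index.get_indexer(idx)], y[df.index.get_indexer(idx)]

        def integrand(u):
            p = expit(Xi @ np.asarray(beta) + u)
            lik = np.prod(p**yi * (1 - p) ** (1 - yi))
            return lik * np.exp(-(u**2) / (2 * sigma_u**2)) / (
                sigma_u * np.sqrt(2 * np.pi)
            )

        v, _ = quad(integrand, -10 * sigma_u, 10 * sigma_u,
                    epsabs=1e-14, epsrel=1e-12, limit=200)
        ll += np.log(v)
    return ll


class TestLMM:
    def test_balanced_oneway_matches_closed_form_ml(self):
        # ML for balanced one-way: beta0 = grand mean, sigma_e^2 = SSW/(N-a),
        # sigma_u^2 = (SSB/a - sigma_e^2)/n
        rng = np.random.default_rng(61)
        a, n = 25, 4
        g = np.repeat(np.arange(a), n)
        y = 2.0 + rng.normal(0, 0.7, a)[g] + rng.normal(0, 1.0, a * n)
        df = pd.DataFrame({"y": y, "woman_id": g})
        fit = fit_lmm_ri(ModelSpec("y", (), "woman_id", "gaussian"), df)
        gm = y.mean()
        group_means = df.groupby("woman_id")["y"].mean().to_numpy()
        ssw = float(((y - group_means[g]) ** 2).sum())
        ssb = float(n * ((group_means - gm) ** 2).sum())
        sigma_e2 = ssw / (a * n - a)
        sigma_u2 = max((ssb / a - sigma_e2) / n, 0.0)
        assert fit.beta[0] == pytest.approx(gm, abs=1e-6)
        assert fit.sigma_e**2 == pytest.approx(sigma_e2, abs=1e-6)
        assert fit.sigma_u**2 == pytest.approx(sigma_u2, abs=1e-6)

    def test_no_group_variance_collapses_to_ols(self):
        rng = np.random.default_rng(67)
        df = simulate_lmm(rng, G=60, npg=2, sigma_u=0.0)
        fit = fit_lmm_ri(GAUSS, df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert fit.sigma_u < 0.05
        assert np.allclose(fit.beta, ols, atol=1e-3)

    def test_parameter_recovery_at_scale(self):
        # 300 women, true beta = (0.5, -0.3), sigma_u = 0.6
        biases = []
        for rep in range(100):
            rng = np.random.default_rng(200 + rep)
            df = simulate_lmm(rng, G=300, npg=2, beta=(0.5, -0.3), sigma_u=0.6)
            fit = fit_lmm_ri(GAUSS, df)
            biases.append([fit.beta[0] - 0.5, fit.beta[1] + 0.3, fit.sigma_u - 0.6])
        mean_bias = np.abs(np.mean(biases, axis=0))
        assert np.all(mean_bias < 0.05)

    def test_matches_statsmodels_on_shared_fixtures(self):
        import statsmodels.formula.api as smf

        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            df = simulate_lmm(rng, G=30 + 5 * seed, npg=2 + seed % 3)
            fit = fit_lmm_ri(GAUSS, df)
            sm = smf.mixedlm("y ~ x", df, groups=df["woman_id"]).fit(reml=False)
            assert np.allclose(fit.beta, sm.params.values[:2], atol=1e-3)
            assert fit.sigma_u == pytest.approx(
                np.sqrt(sm.cov_re.values[0, 0]), abs=1e-2
            )

    def test_invariant_to_group_relabelling_and_row_order(self):
        rng = np.random.default_rng(71)
        df = simulate_lmm(rng)
        fit = fit_lmm_ri(GAUSS, df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["woman_id"] = shuffled["woman_id"].map(lambda g: f"Z{g:03d}")
        fit2 = fit_lmm_ri(GAUSS, shuffled)
        assert np.allclose(fit.beta, fit2.beta, atol=1e-8)
        assert fit.sigma_u == pytest.approx(fit2.sigma_u, abs=1e-8)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_zero_response_variance_rejected(self):
        df = pd.DataFrame({"y": np.ones(10), "x": np.arange(10.0),
                           "woman_id": np.repeat([0, 1], 5)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_lmm_ri(GAUSS, df)


class TestGLMM:
    def test_loglik_matches_integration_oracle_at_optimum(self):
        rng = np.random.default_rng(73)
        df = simulate_glmm(rng, G=5, npg=4)
        fit = fit_logistic_ri(BINOM, df)
        want = glmm_loglik_oracle(df, fit.beta, max(fit.sigma_u, 1e-8))
        assert fit.loglik == pytest.approx(want, abs=1e-8)

    def test_sigma_u_fixed_zero_collapses_to_plain_logistic(self):
        # singleton-only groups identify (beta, sigma_u) only through a flat
        # likelihood ridge, so the collapse is exercised with sigma_u pinned
        import statsmodels.api as smapi

        rng = np.random.default_rng(79)
        n = 300
        x = rng.normal(size=n)
        y = rng.binomial(1, expit(0.4 + 0.9 * x)).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "woman_id": np.arange(n)})
        fit = fit_logistic_ri(BINOM, df, sigma_u_fixed=0.0)
        glm = smapi.Logit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        assert np.allclose(fit.beta, glm.params, atol=1e-5)
        assert np.allclose(fit.se, glm.bse, atol=1e-5)
        assert fit.sigma_u == 0.0

    def test_data_without_group_variance_collapses_to_glm(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(81)
        df = simulate_glmm(rng, G=120, npg=3, beta=(0.2, 0.8), sigma_u=0.0)
        fit = fit_logistic_ri(BINOM, df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        glm = smapi.Logit(df["y"].to_numpy(), X).fit(disp=0)
        assert fit.sigma_u == pytest.approx(0.0, abs=1e-3)
        assert np.allclose(fit.beta, glm.params, atol=1e-5)

    def test_local_optimality_of_fitted_parameters(self):
        rng = np.random.default_rng(83)
        df = simulate_glmm(rng, G=30)
        fit = fit_logistic_ri(BINOM, df)
        y = df["y"].to_numpy()
        X = np.column_stack([np.ones(len(df)), df["x"]])
        gidx = df["woman_id"].to_numpy()
        opt = np.concatenate([fit.beta, [np.log(fit.sigma_u)]])
        ll0 = glmm_loglik_at(opt, y, X, gidx)
        for _ in range(20):
            pert = opt + rng.normal(0, 0.05, opt.size)
            assert glmm_loglik_at(pert, y, X, gidx) <= ll0 + 1e-9

    def test_quadrature_convergence_15_to_31(self):
        from alticycle.pipeline import _analytic_frame, derive_cycle_statistics, StudyConfig
        from alticycle.synthetic import SimConfig, simulate_study

        ds, _ = simulate_study(SimConfig(seed=89, missing_rate_trad=0.0))
        fr = _analytic_frame(derive_cycle_statistics(ds, StudyConfig()))
        spec = ModelSpec("ovulatory", ("hb_z",), "woman_id", "binomial")
        f15 = fit_logistic_ri(spec, fr, quad_points=15)
        f31 = fit_logistic_ri(spec, fr, quad_points=31)
        assert np.max(np.abs(f15.beta - f31.beta)) < 1e-4

    def test_matches_lme4_glmer_on_shared_fixtures(self):
        """Cross-check against R lme4 (adaptive GHQ, nAGQ=25) on 2 fixtures."""
        fixtures = []
        for seed in (101, 102):
            rng = np.random.default_rng(seed)
            fixtures.append(simulate_glmm(rng, G=35, npg=3))
        script_lines = ["suppressMessages(library(lme4))"]
        paths = []
        for df in fixtures:
            f = tempfile.NamedTemporaryFile(suffix=".csv", delete=False)
            df.to_csv(f.name, index=False)
            paths.append(f.name)
            script_lines.append(
                f'd <- read.csv("{f.name}"); '
                "m <- glmer(y ~ x + (1|woman_id), data=d, family=binomial, nAGQ=25); "
                'cat(fixef(m), sqrt(unlist(VarCorr(m))[1]), "\\n")'
            )
        out = subprocess.run(
            ["Rscript", "-e", "\n".join(script_lines)],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        for df, line in zip(fixtures, out.stdout.strip().splitlines()):
            b0, b1, su = map(float, line.split())
            fit = fit_logistic_ri(BINOM, df)
            assert np.allclose(fit.beta, [b0, b1], atol=1e-3)
            assert fit.sigma_u == pytest.approx(su, abs=1e-2)

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.linspace(-3, -1, 15), np.linspace(1, 3, 15)])
        y = (x > 0).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "woman_id": np.arange(30)})
        fit = fit_logistic_ri(BINOM, df)
        assert not fit.converged
        assert "separation" in fit.message
        with pytest.raises(ConvergenceError):
            wald_summary(fit)

    def test_non_binary_response_rejected(self):
        df = pd.DataFrame({"y": [0.0, 2.0, 1.0, 0.0], "x": np.arange(4.0),
                           "woman_id": [0, 0, 1, 1]})
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic_ri(BINOM, df)

    def test_too_few_quad_points_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1.0], "x": [0.0, 1.0], "woman_id": [0, 1]})
        with pytest.raises(ValueError, match="quad_points"):
            fit_logistic_ri(BINOM, df, quad_points=5)


class TestWaldSummary:
    def _fit(self, beta, se, family="binomial"):
        return ModelFit(
            spec=ModelSpec("y", ("x",), "woman_id", family),
            names=["(Intercept)", "x"], beta=np.array([0.0, beta]),
            se=np.array([1.0, se]), vcov=np.diag([1.0, se**2]),
            sigma_u=0.5, sigma_e=None, loglik=-10.0, n_obs=50, n_groups=25,
            converged=True,
        )

    def test_null_effect_gives_or_one_p_one(self):
        tab = wald_summary(self._fit(0.0, 0.5), exponentiate=True)
        assert tab.loc["x", "estimate"] == pytest.approx(1.0)
        assert tab.loc["x", "p"] == pytest.approx(1.0)

    def test_hand_computed_odds_ratio_and_ci(self):
        tab = wald_summary(self._fit(1.1849, 0.56), exponentiate=True)
        assert tab.loc["x", "estimate"] == pytest.approx(3.27, abs=0.005)
        assert tab.loc["x", "ci_low"] == pytest.approx(1.09, abs=0.005)
        assert tab.loc["x", "ci_high"] == pytest.approx(9.80, abs=0.005)

    def test_ci_contains_estimate_and_or_ci_positive(self):
        rng = np.random.default_rng(97)
        for _ in range(20):
            b, s = rng.normal(0, 2), rng.uniform(0.05, 2)
            tab = wald_summary(self._fit(b, s), exponentiate=True)
            row = tab.loc["x"]
            assert row["ci_low"] <= row["estimate"] <= row["ci_high"]
            assert row["ci_low"] > 0


class TestPredictMarginal:
    def test_intercept_only_gaussian(self):
        rng = np.random.default_rng(103)
        df = simulate_lmm(rng, beta=(1.7, 0.0))
        df = df.drop(columns=["x"])
        fit = fit_lmm_ri(ModelSpec("y", (), "woman_id", "gaussian"), df)
        pred = predict_marginal(fit, pd.DataFrame(index=range(3)))
        assert np.allclose(pred["predicted"], fit.beta[0])

    def test_binomial_probability_half_at_zero_linear_predictor(self):
        rng = np.random.default_rng(107)
        df = simulate_glmm(rng, G=60, npg=2, beta=(0.0, 1.2))
        fit = fit_logistic_ri(BINOM, df)
        x_at_zero = -fit.beta[0] / fit.beta[1]
        pred = predict_marginal(fit, pd.DataFrame({"x": [x_at_zero]}))
        assert pred["predicted"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_monotone_probability_curve(self):
        rng = np.random.default_rng(109)
        df = simulate_glmm(rng, G=80, npg=2, beta=(0.2, 1.0))
        fit = fit_logistic_ri(BINOM, df)
        grid = pd.DataFrame({"x": np.linspace(-3, 3, 25)})
        pred = predict_marginal(fit, grid)
        assert np.all(np.diff(pred["predicted"]) > 0)
        assert np.all(pred["ci_low"] <= pred["predicted"])
        assert np.all(pred["predicted"] <= pred["ci_high"])

    def test_unseen_column_rejected(self):
        rng = np.random.default_rng(113)
        fit = fit_lmm_ri(GAUSS, simulate_lmm(rng))
        with pytest.raises(KeyError, match="x"):
            predict_marginal(fit, pd.DataFrame({"z": [1.0]}))
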