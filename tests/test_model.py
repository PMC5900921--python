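"""Tests of the multivariate multilevel sampler: degenerate cases, probit
identification, missing-data handling, Empirical Bayes effects, determinism."""
import numpy as np
import pandas as pd
import pytest

from domprof import (DimensionSpec, McmcSettings, ModelSpec,
                     MultivariateMultilevelModel, SyntheticConfig,
                     default_config, fit_univariate, generate_population,
                     probit_intercept, simulate)


def _fit(df, spec, **kw):
    base = dict(iterations=800, burn_in=300, seed=2)
    base.update(kw)
    return MultivariateMultilevelModel(df, spec).fit(McmcSettings(**base))


class TestDegenerateCases:
    def test_single_provider_single_gaussian_reduces_to_sample_moments(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.5, 500)
        df = pd.DataFrame({"provider_id": 0, "y": y})
        spec = ModelSpec(dimensions=(DimensionSpec("y", "gaussian"),))
        res = _fit(df, spec, iterations=1500, burn_in=500)
        assert abs(res.alpha.mean() - y.mean()) < 3 * res.alpha.std()
        s2 = (res.sigma[:, 0] ** 2)
        assert abs(s2.mean() - y.var(ddof=1)) < 3 * s2.std()

    def test_univariate_probit_recovers_marginal_rate(self):
        # posterior of Phi(alpha/sqrt(1+tau^2)) ~ overall event rate
        from scipy.special import ndtr
        rate, tau = 0.17, 0.25
        dims = (DimensionSpec("w", "probit"),)
        cfg = SyntheticConfig(J=80, n_j=80, dimensions=dims,
                              alpha=np.array([probit_intercept(rate, tau)]),
                              beta={"w": np.array([])}, covariate_model={},
                              tau=np.array([tau]), rho_theta=np.eye(1),
                              sigma=np.ones(1), rho_eps=np.eye(1), seed=21)
        ds = generate_population(cfg)
        res = _fit(ds.patients, ModelSpec(dimensions=dims),
                   iterations=1200, burn_in=400)
        marg = ndtr(res.alpha[:, 0] / np.sqrt(1 + res.tau[:, 0] ** 2))
        obs = ds.patients["w"].mean()
        assert abs(marg.mean() - obs) < 4 * max(marg.std(), 0.003)

    def test_all_missing_dimension_rejected(self):
        df = pd.DataFrame({"provider_id": [0, 0, 1, 1],
                           "a": [1.0, 2.0, 3.0, 4.0],
                           "b": [np.nan] * 4})
        spec = ModelSpec(dimensions=(DimensionSpec("a", "gaussian"),
                                     DimensionSpec("b", "gaussian")))
        with pytest.raises(ValueError, match="b"):
            MultivariateMultilevelModel(df, spec)

    def test_invalid_binary_value_rejected(self):
        df = pd.DataFrame({"provider_id": [0, 0, 1], "y": [0.0, 2.0, 1.0]})
        spec = ModelSpec(dimensions=(DimensionSpec("y", "probit"),))
        with pytest.raises(ValueError, match="y"):
            MultivariateMultilevelModel(df, spec)


class TestGaussianOracle:
    def test_posterior_matches_closed_form_multilevel_oracle(self, gauss2_data,
                                                             gauss2_config):
        """Balanced gaussian-only case vs the independent MANOVA-style
        moment oracle: alpha = grand mean, Omega = W/(N-J),
        Sigma = (B/(J-1) - Omega)/n."""
        cfg = gauss2_config
        res = _fit(gauss2_data.patients,
                   ModelSpec(dimensions=cfg.dimensions),
                   iterations=2500, burn_in=800, seed=4)
        Y = gauss2_data.patients[["a", "b"]].to_numpy()
        jidx = gauss2_data.patients["provider_id"].to_numpy()
        J, n = cfg.J, cfg.n_j
        gm = np.stack([Y[jidx == j].mean(0) for j in range(J)])
        W = sum(((Y[jidx == j] - gm[j]).T @ (Y[jidx == j] - gm[j]))
                for j in range(J))
        B = n * ((gm - Y.mean(0)).T @ (gm - Y.mean(0)))
        Om_hat = W / (len(Y) - J)
        Sig_hat = (B / (J - 1) - Om_hat) / n
        assert np.all(np.abs(res.alpha.mean(0) - Y.mean(0)) < 3 * res.alpha.std(0))
        assert np.all(np.abs(res.Omega.mean(0) - Om_hat) < 3 * res.Omega.std(0))
        assert np.all(np.abs(res.Sigma.mean(0) - Sig_hat) < 3 * res.Sigma.std(0))


class TestIdentificationAndValidity:
    def test_probit_error_variance_exactly_one_every_draw(self, small_cohort,
                                                          short_settings):
        cfg = default_config(J=15, n_j=25)
        res = MultivariateMultilevelModel(
            small_cohort.patients, ModelSpec(dimensions=cfg.dimensions)
        ).fit(short_settings)
        diag = np.einsum("mkk->mk", res.Omega)
        assert np.allclose(diag[:, 2:], 1.0, atol=1e-12)

    def test_all_covariance_draws_psd(self, small_cohort, short_settings):
        cfg = default_config(J=15, n_j=25)
        res = MultivariateMultilevelModel(
            small_cohort.patients, ModelSpec(dimensions=cfg.dimensions)
        ).fit(short_settings)
        for mats in (res.Sigma, res.Omega):
            eig = np.linalg.eigvalsh(mats)
            assert eig.min() > -1e-10
        for p in res.provider_effects():
            assert np.linalg.eigvalsh(p.V).min() > -1e-10
            assert np.allclose(p.V, p.V.T)

    def test_seed_determinism(self, gauss2_data, gauss2_config):
        spec = ModelSpec(dimensions=gauss2_config.dimensions)
        r1 = _fit(gauss2_data.patients, spec, iterations=300, burn_in=100, seed=9)
        r2 = _fit(gauss2_data.patients, spec, iterations=300, burn_in=100, seed=9)
        assert np.array_equal(r1.alpha, r2.alpha)
        assert np.array_equal(r1.theta, r2.theta)
        assert np.array_equal(r1.Omega, r2.Omega)

    def test_correlation_matrix_is_valid(self, gauss2_data, gauss2_config):
        spec = ModelSpec(dimensions=gauss2_config.dimensions)
        res = _fit(gauss2_data.patients, spec)
        for level in ("provider", "patient"):
            C = res.correlation_matrix(level)
            assert np.allclose(np.diag(C.mean), 1.0)
            assert np.allclose(C.mean, C.mean.T)
            assert np.abs(C.mean).max() <= 1.0 + 1e-9


class TestMissingOutcomes:
    def test_fit_with_missing_close_to_complete_fit(self):
        cfg = default_config(J=30, n_j=60, seed=31, missing=False)
        complete = generate_population(cfg)
        cfg2 = default_config(J=30, n_j=60, seed=31)
        withmiss = simulate(cfg2)
        spec = ModelSpec(dimensions=cfg.dimensions)
        sett = dict(iterations=800, burn_in=300, seed=5)
        r_full = _fit(complete.patients, spec, **sett)
        r_miss = _fit(withmiss.patients, spec, **sett)
        # same generating draw; masking ~15% of one dim must not move alpha
        # by more than a few posterior SDs
        d = np.abs(r_full.alpha.mean(0) - r_miss.alpha.mean(0))
        tol = 4 * np.maximum(r_full.alpha.std(0), 1e-3)
        assert np.all(d < tol)


class TestEmpiricalBayes:
    def test_complete_shrinkage_when_no_provider_variance(self):
        cfg = default_config(J=20, n_j=40, seed=41, missing=False)
        cfg.tau = np.zeros(4)
        ds = generate_population(cfg)
        res = _fit(ds.patients, ModelSpec(dimensions=cfg.dimensions))
        for p in res.provider_effects():
            assert np.all(np.abs(p.theta_hat) < 4 * np.sqrt(np.diag(p.V)) + 0.05)

    def test_univariate_balanced_shrinkage_closed_form(self, gauss2_data,
                                                       gauss2_config):
        """EB means match lambda*(ybar_j - ybar), lambda = tau^2/(tau^2+sigma^2/n)."""
        spec = ModelSpec(dimensions=gauss2_config.dimensions)
        res = fit_univariate(gauss2_data.patients, spec, "a",
                             McmcSettings(iterations=3000, burn_in=1000, seed=6))
        t2 = (res.tau[:, 0] ** 2).mean()
        s2 = (res.sigma[:, 0] ** 2).mean()
        n = gauss2_config.n_j
        lam = t2 / (t2 + s2 / n)
        gm = gauss2_data.patients.groupby("provider_id")["a"].mean()
        closed = lam * (gm - gm.mean()).to_numpy()
        eb = np.array([p.theta_hat[0] for p in res.provider_effects()])
        sd = np.array([np.sqrt(p.V[0, 0]) for p in res.provider_effects()])
        # agreement well inside posterior spread (MCMC error scale)
        assert np.all(np.abs(eb - closed) < 0.35 * sd)

    def test_larger_provider_has_tighter_posterior(self):
        rng = np.random.default_rng(17)
        tau, sig = 0.5, 1.0
        n_small, n_big = 30, 120
        rows = []
        for j, n in enumerate([n_small, n_big] * 8):
            th = rng.normal(0, tau)
            rows.append(pd.DataFrame({
                "provider_id": j, "y": 1.0 + th + rng.normal(0, sig, n)}))
        df = pd.concat(rows, ignore_index=True)
        spec = ModelSpec(dimensions=(DimensionSpec("y", "gaussian"),))
        res = _fit(df, spec, iterations=1500, burn_in=500)
        Vs = {p.provider_id: p.V[0, 0] for p in res.provider_effects()}
        v_small = np.mean([Vs[j] for j in range(16) if j % 2 == 0])
        v_big = np.mean([Vs[j] for j in range(16) if j % 2 == 1])
        assert v_big < v_small

    def test_univariate_equals_multivariate_when_independent(self):
        cfg = default_config(J=25, n_j=60, seed=51, missing=False)
        cfg.rho_theta = np.eye(4)
        cfg.rho_eps = np.eye(4)
        ds = generate_population(cfg)
        spec = ModelSpec(dimensions=cfg.dimensions)
        mv = _fit(ds.patients, spec, iterations=1000, burn_in=400)
        uv = fit_univariate(ds.patients, spec, "ohs_post",
                            McmcSettings(iterations=1000, burn_in=400, seed=3))
        th_mv = mv.theta.mean(0)[:, 1]
        th_uv = uv.theta.mean(0)[:, 0]
        sd = mv.theta.std(0)[:, 1]
        assert np.all(np.abs(th_mv - th_uv) < 4 * sd)


class TestModelOptions:
    def test_mundlak_terms_enter_every_dimension(self, small_cohort,
                                                 short_settings):
        cfg = default_config(J=15, n_j=25)
        spec = ModelSpec(dimensions=cfg.dimensions,
                         provider_mean_covariates=("preop_score",))
        model = MultivariateMultilevelModel(small_cohort.patients, spec)
        for names in model.coef_names:
            assert "pmean_preop_score" in names
        res = model.fit(short_settings)
        assert res.coefficient_draws("pmean_preop_score").shape[1] == 4

    def test_convergence_gate_flags_short_chains(self, small_cohort):
        cfg = default_config(J=15, n_j=25)
        res = MultivariateMultilevelModel(
            small_cohort.patients, ModelSpec(dimensions=cfg.dimensions)
        ).fit(McmcSettings(iterations=60, burn_in=10, seed=1))
        d = res.diagnostics()
        assert "max_rhat" in d and np.isfinite(d["max_rhat"])

    def test_summary_contains_key_parameters(self, gauss2_data, gauss2_config):
        res = _fit(gauss2_data.patients,
                   ModelSpec(dimensions=gauss2_config.dimensions),
                   iterations=300, burn_in=100)
        s = res.summary()
        for token in ("alpha[a]", "tau[b]", "rho_provider", "rho_patient"):
            assert token in s
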