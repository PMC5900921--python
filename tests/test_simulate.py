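"""Tests of the synthetic cohort generator: moments, rates, missingness,
selection geometry and reproducibility."""
import numpy as np
import pandas as pd
import pytest

from domprof import (DimensionSpec, SelectionConfig, SyntheticConfig,
                     apply_missingness, default_config, generate_population,
                     generate_selection, probit_intercept, simulate)


def _plain_config(J, n_j, seed=0, **kw):
    dims = (DimensionSpec("c1", "gaussian"), DimensionSpec("b1", "probit"))
    base = dict(
        J=J, n_j=n_j, dimensions=dims, alpha=np.zeros(2),
        beta={"c1": np.array([]), "b1": np.array([])}, covariate_model={},
        tau=np.zeros(2), rho_theta=np.eye(2), sigma=np.ones(2),
        rho_eps=np.eye(2), seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGeneratePopulation:
    def test_all_structure_off_gives_standard_normal_and_half(self):
        # tau=0, beta=0, alpha=0, identity: continuous ~ N(0,1), probit p=0.5
        cfg = _plain_config(J=50, n_j=200, seed=1)
        pat = generate_population(cfg).patients
        c = pat["c1"].to_numpy()
        n = len(c)
        assert abs(c.mean()) < 3 / np.sqrt(n)
        assert abs(c.std(ddof=1) - 1.0) < 3 / np.sqrt(2 * n)
        p = pat["b1"].mean()
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_theta_correlation_recovered(self):
        cfg = default_config(J=2000, n_j=2, seed=1, missing=False)
        cfg.tau = np.full(4, 0.3)
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        cfg.rho_theta = R
        theta = generate_population(cfg).truth.theta
        emp = np.corrcoef(theta.T)
        off = emp[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.5, atol=0.03 + 3 * 1 / np.sqrt(2000))

    def test_probit_marginal_rate_matches_calibration(self):
        # Phi(alpha/sqrt(1+tau^2)) = 0.17 -> observed event rate ~ 0.17
        tau = 0.3
        dims = (DimensionSpec("w", "probit"),)
        cfg = SyntheticConfig(
            J=300, n_j=300, dimensions=dims,
            alpha=np.array([probit_intercept(0.17, tau)]),
            beta={"w": np.array([])}, covariate_model={},
            tau=np.array([tau]), rho_theta=np.eye(1), sigma=np.ones(1),
            rho_eps=np.eye(1), seed=4,
        )
        pat = generate_population(cfg).patients
        assert abs(pat["w"].mean() - 0.17) < 0.01

    def test_latent_variance_matches_config(self):
        # per-dimension variance of a gaussian outcome ~ tau^2 + sigma^2
        cfg = _plain_config(J=200, n_j=50, seed=5,
                            tau=np.array([0.5, 0.0]), sigma=np.array([1.2, 1.0]))
        pat = generate_population(cfg).patients
        v = pat["c1"].var(ddof=1)
        target = 0.5**2 + 1.2**2
        se = target * np.sqrt(2 / len(pat))  # crude MC error, ignores clustering
        assert abs(v - target) < max(3 * se, 0.08)

    def test_residual_correlation_recovered(self):
        cfg = _plain_config(J=10, n_j=2000, seed=6,
                            dimensions=(DimensionSpec("c1", "gaussian"),
                                        DimensionSpec("c2", "gaussian")),
                            beta={"c1": np.array([]), "c2": np.array([])},
                            rho_eps=np.array([[1, 0.4], [0.4, 1]]))
        pat = generate_population(cfg).patients
        r = np.corrcoef(pat["c1"], pat["c2"])[0, 1]
        assert abs(r - 0.4) < 3 / np.sqrt(len(pat))

    def test_reproducible_bit_identical(self):
        a = simulate(default_config(J=10, n_j=20, seed=9))
        b = simulate(default_config(J=10, n_j=20, seed=9))
        pd.testing.assert_frame_equal(a.patients, b.patients)
        assert np.array_equal(a.truth.theta, b.truth.theta)

    def test_every_row_references_existing_provider(self, small_cohort):
        assert small_cohort.patients["provider_id"].isin(range(15)).all()

    def test_binary_columns_only_01(self, small_cohort):
        for c in ("wait_over_18wk", "readmit_28d"):
            vals = small_cohort.patients[c].dropna().unique()
            assert set(vals) <= {0.0, 1.0}

    def test_invalid_correlation_rejected_with_name(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(ValueError, match="rho_theta"):
            _plain_config(J=2, n_j=2, rho_theta=bad)
        with pytest.raises(ValueError, match="rho_eps"):
            _plain_config(J=2, n_j=2, rho_eps=bad)

    def test_top_coding_caps_right_tail(self):
        cfg = default_config(J=20, n_j=100, seed=2, missing=False)
        cfg.top_code_quantile = 0.99
        pat = generate_population(cfg).patients
        q99 = pat["los"].quantile(1.0)
        assert (pat["los"] <= q99).all()
        assert (pat["los"] == pat["los"].max()).sum() >= len(pat) * 0.005


class TestMissingness:
    def test_zero_rates_identity(self, small_cohort):
        cfg = default_config(J=15, n_j=25, seed=7, missing=False)
        out = apply_missingness(small_cohort, cfg)
        pd.testing.assert_frame_equal(out.patients, small_cohort.patients)

    def test_mcar_rate_matches(self):
        # health-score-like rate 0.152 on a large cohort
        cfg = default_config(J=100, n_j=1000, seed=8)
        data = generate_population(cfg)
        out = apply_missingness(data, cfg)
        frac = out.patients["ohs_post"].isna().mean()
        assert abs(frac - 0.152) < 0.003

    def test_nonmasked_cells_and_covariates_untouched(self):
        cfg = default_config(J=20, n_j=50, seed=12)
        data = generate_population(cfg)
        out = apply_missingness(data, cfg)
        m = out.patients["ohs_post"].isna()
        orig = data.patients["ohs_post"]
        assert (out.patients.loc[~m, "ohs_post"] == orig[~m]).all()
        for c in ("preop_score", "male", "deprivation"):
            assert out.patients[c].notna().all()
            assert (out.patients[c] == data.patients[c]).all()
        # complete values retained for audit
        assert out.truth.complete["ohs_post"].notna().all()

    def test_mar_mechanism_depends_on_covariate_not_outcome(self):
        import statsmodels.api as sm
        cfg = default_config(J=50, n_j=200, seed=13)
        cfg.missing_mechanism = "MAR"
        cfg.mar_covariate = "preop_score"
        cfg.missing_rates = np.array([0.0, 0.3, 0.0, 0.0])
        data = generate_population(cfg)
        out = apply_missingness(data, cfg)
        mask = out.patients["ohs_post"].isna().astype(float)
        X = sm.add_constant(np.column_stack([
            out.patients["preop_score"],
            data.truth.complete["ohs_post"],  # the masked outcome's true value
        ]))
        fit = sm.Logit(mask, X).fit(disp=0)
        z = (fit.params / fit.bse).to_numpy()
        assert z[1] > 4           # driver covariate clearly detected
        assert abs(z[2]) < 3      # no conditional dependence on the outcome

    def test_rate_outside_unit_interval_rejected(self, small_cohort):
        cfg = default_config(J=15, n_j=25, seed=7)
        cfg.missing_rates = cfg.missing_rates.copy()
        cfg.missing_rates[0] = 1.5
        with pytest.raises(ValueError):
            apply_missingness(small_cohort, cfg)


class TestSelection:
    def test_requires_at_least_two_providers(self):
        cfg = _plain_config(J=1, n_j=10, selection=SelectionConfig())
        data = generate_population(cfg)
        with pytest.raises(ValueError):
            generate_selection(data, cfg)

    def test_lambda_zero_choice_depends_only_on_distance(self):
        cfg = default_config(J=10, n_j=100, seed=14, missing=False,
                             selection=SelectionConfig(lam=0.0))
        ds = simulate(cfg)
        conf = ds.truth.latent_confounder
        jmean = pd.DataFrame({"j": ds.patients["provider_id"], "c": conf}
                             ).groupby("j")["c"].mean()
        # no confounding: provider-mean confounder is ~0 everywhere
        n_per = ds.patients["provider_id"].value_counts()
        se = 1 / np.sqrt(n_per.reindex(jmean.index))
        assert (jmean.abs() < 4 * se).all()

    def test_lambda_positive_links_residual_and_confounder(self):
        from domprof import (build_choice_set, choice_data_from_wide,
                             first_stage_residuals, fit_conditional_logit)
        cfg = default_config(J=20, n_j=80, seed=10, missing=False,
                             selection=SelectionConfig(lam=0.8))
        ds = simulate(cfg)
        choice = build_choice_set(choice_data_from_wide(ds.patients), 0)
        resid = first_stage_residuals(fit_conditional_logit(choice), choice)
        merged = pd.DataFrame({
            "patient_id": ds.patients["patient_id"],
            "conf": ds.truth.latent_confounder}).merge(resid, on="patient_id")
        r = np.corrcoef(merged["conf"], merged["choice_residual"])[0, 1]
        assert r > 0.2

    def test_strong_distance_preference_means_closest_chosen(self):
        cfg = default_config(J=10, n_j=100, seed=15, missing=False,
                             selection=SelectionConfig(gamma_d=-25.0,
                                                       delta_closest=2.0))
        ds = simulate(cfg)
        dist_cols = [f"dist_to_{j}" for j in range(10)]
        d = ds.patients[dist_cols].to_numpy()
        chosen = ds.patients["provider_id"].to_numpy()
        frac = (d.argmin(axis=1) == chosen).mean()
        assert frac > 0.5

    def test_distance_columns_present_and_nonnegative(self):
        cfg = default_config(J=5, n_j=40, seed=16, missing=False,
                             selection=SelectionConfig())
        ds = simulate(cfg)
        cols = [c for c in ds.patients.columns if c.startswith("dist_to_")]
        assert len(cols) == 5
        assert (ds.patients[cols] >= 0).all().all()
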