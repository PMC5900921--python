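"""Multivariate multilevel model of provider performance.

``MultivariateMultilevelModel`` holds a patient table and a ``ModelSpec``
and its ``fit()`` runs the Gibbs sampler, returning ``MVMLMResults`` with
posterior draws, summaries, convergence diagnostics, Empirical Bayes
provider-effect posteriors and level-specific correlation matrices.

The model is, for patient i in provider j and dimension k,

    Y*_ijk = alpha_k + X'_ijk beta_k + theta_jk + eps_ijk,

with theta_j ~ MVN(0, Sigma) across providers and eps_i ~ MVN(0, Omega)
across patients; probit dimensions observe I(Y* > 0) and have their error
variance fixed at 1. Missing outcome cells are augmented from their
conditional normal given the observed dimensions (MAR given covariates and
observed performance).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dimensions import DimensionSpec, ModelSpec
from .gibbs import McmcSettings, run_gibbs

__all__ = [
    "MultivariateMultilevelModel",
    "MVMLMResults",
    "ProviderEffectPosterior",
    "McmcSettings",
    "fit_univariate",
]


@dataclass
class ProviderEffectPosterior:
    """Posterior of one provider's K-vector effect theta_j.

    ``theta_hat`` is the posterior (Empirical Bayes) mean, ``V`` the
    posterior covariance of theta_j, ``draws`` the retained MCMC samples.
    """

    provider_id: object
    theta_hat: np.ndarray      # (K,)
    V: np.ndarray              # (K, K)
    draws: np.ndarray          # (M, K)
    n_j: int
    dimension_names: tuple[str, ...] = ()


@dataclass
class CorrelationSummary:
    """Posterior summary of a level-specific correlation matrix."""

    level: str
    mean: np.ndarray
    sd: np.ndarray
    excludes_zero: np.ndarray  # True where the central 95% interval misses 0
    names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=self.names, columns=self.names)


class MultivariateMultilevelModel:
    """Random-intercept model over K mixed gaussian/probit outcomes.

    Parameters
    ----------
    data : DataFrame
        One row per patient; must contain ``provider_col``, every outcome
        named in ``spec`` and every referenced covariate. Missing outcomes
        are allowed (NaN); covariates must be complete.
    spec : ModelSpec
    provider_col : str
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 provider_col: str = "provider_id"):
        if len(data) == 0:
            raise ValueError("data is empty")
        if provider_col not in data.columns:
            raise ValueError(f"column {provider_col!r} not found")
        spec.validate_against(data)
        self.spec = spec
        self.provider_col = provider_col
        self.data = data.reset_index(drop=True)

        codes, uniques = pd.factorize(self.data[provider_col], sort=True)
        self.provider_ids = list(uniques)
        self.j_idx = codes.astype(np.intp)
        self.J = len(uniques)
        self.N = len(self.data)
        self.K = spec.K

        self._build_arrays()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec,
                       provider_col: str = "provider_id"):
        return cls(data, spec, provider_col=provider_col)

    def _build_arrays(self) -> None:
        spec, data = self.spec, self.data
        N, K = self.N, self.K

        Z0 = np.zeros((N, K))
        obs = np.zeros((N, K), dtype=bool)
        ybin = np.zeros((N, K))
        self.is_probit = np.array([d.is_probit for d in spec.dimensions])

        for k, d in enumerate(spec.dimensions):
            y = data[d.name].to_numpy(dtype=float)
            observed = ~np.isnan(y)
            if not observed.any():
                raise ValueError(f"dimension {d.name!r} has no observed values")
            obs[:, k] = observed
            if d.is_probit:
                vals = np.unique(y[observed])
                bad = np.setdiff1d(vals, [0.0, 1.0])
                if bad.size:
                    rows = np.where(np.isin(y, bad))[0]
                    raise ValueError(
                        f"binary outcome {d.name!r} contains {bad.tolist()} "
                        f"(first offending row {rows[0]})"
                    )
                ybin[:, k] = np.where(observed, y, 0.0)
                Z0[:, k] = np.where(observed, np.where(y > 0.5, 0.5, -0.5), 0.0)
            else:
                z = d.to_latent(y)
                fill = np.nanmean(z)
                Z0[:, k] = np.where(observed, z, fill)

        # Mundlak contextual terms: provider means on the estimation sample
        mundlak: dict[str, np.ndarray] = {}
        for c in spec.provider_mean_covariates:
            means = data.groupby(self.j_idx)[c].transform("mean").to_numpy()
            mundlak[f"pmean_{c}"] = means

        self.X_list: list[np.ndarray] = []
        self.coef_names: list[list[str]] = []
        for d in spec.dimensions:
            cols = [np.ones(N)]
            names = ["const"]
            for c in d.covariates:
                cols.append(data[c].to_numpy(dtype=float))
                names.append(c)
            for nm, v in mundlak.items():
                cols.append(v)
                names.append(nm)
            if spec.residual_column is not None:
                r = data[spec.residual_column].to_numpy(dtype=float)
                if np.ptp(r) == 0:
                    raise ValueError(
                        f"residual column {spec.residual_column!r} is constant"
                    )
                cols.append(r)
                names.append(spec.residual_column)
            X = np.column_stack(cols)
            if np.isnan(X).any():
                raise ValueError(f"covariates for dimension {d.name!r} contain NaN")
            self.X_list.append(X)
            self.coef_names.append(names)

        self.Z0, self.obs_mask, self.ybin = Z0, obs, ybin

    def fit(self, settings: Optional[McmcSettings] = None) -> "MVMLMResults":
        settings = settings or McmcSettings()
        draws = run_gibbs(
            Z0=self.Z0, obs_mask=self.obs_mask, is_probit=self.is_probit,
            ybin=self.ybin, X_list=self.X_list, j_idx=self.j_idx, J=self.J,
            settings=settings,
        )
        return MVMLMResults(self, settings, draws)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a single chain (split into two halves)."""
    m = len(x) // 2
    if m < 2:
        return np.nan
    halves = np.stack([x[:m], x[m : 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((w * (m - 1) / m + b / m) / w))


class MVMLMResults:
    """Posterior draws and summaries of a fitted multivariate multilevel model."""

    def __init__(self, model: MultivariateMultilevelModel,
                 settings: McmcSettings, draws: dict):
        self.model = model
        self.settings = settings
        self.draws = draws
        self.dimension_names = tuple(model.spec.names)
        self.provider_ids = list(model.provider_ids)
        self._diagnostics: Optional[dict] = None
        self.fingerprint = hashlib.sha256(
            f"{model.N}|{model.J}|{model.spec.names}|{settings.seed}|"
            f"{settings.iterations}".encode()
        ).hexdigest()[:16]

    # ---- basic posterior quantities -------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        return self.draws["alpha"]

    @property
    def Sigma(self) -> np.ndarray:
        return self.draws["Sigma"]

    @property
    def Omega(self) -> np.ndarray:
        return self.draws["Omega"]

    @property
    def theta(self) -> np.ndarray:
        return self.draws["theta"]

    @property
    def tau(self) -> np.ndarray:
        """Draws of the provider-level SDs (sqrt diag Sigma)."""
        return np.sqrt(np.einsum("mkk->mk", self.Sigma))

    @property
    def sigma(self) -> np.ndarray:
        """Draws of the patient-level residual SDs (1 on probit dims)."""
        return np.sqrt(np.einsum("mkk->mk", self.Omega))

    def _corr_draws(self, level: str) -> np.ndarray:
        mats = self.Sigma if level == "provider" else self.Omega
        sd = np.sqrt(np.einsum("mkk->mk", mats))
        denom = np.einsum("mi,mj->mij", sd, sd)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = mats / denom
        # degenerate (zero-variance) draws: define the correlation as 0
        corr = np.where(np.isfinite(corr), corr, 0.0)
        idx = np.arange(mats.shape[1])
        corr[:, idx, idx] = 1.0
        return corr

    def correlation_matrix(self, level: str = "provider"):
        """Posterior mean correlation matrix at ``level`` ('provider' or
        'patient'), with posterior SDs and a flag for entries whose central
        95% interval excludes zero."""
        if level not in ("provider", "patient"):
            raise ValueError("level must be 'provider' or 'patient'")
        draws = self._corr_draws(level)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return CorrelationSummary(
            level=level, mean=draws.mean(axis=0), sd=draws.std(axis=0, ddof=1),
            excludes_zero=(lo > 0) | (hi < 0), names=self.dimension_names,
        )

    # ---- provider-effect posteriors -------------------------------------
    def provider_effects(self) -> list[ProviderEffectPosterior]:
        """Empirical Bayes posterior mean and covariance of each provider's
        effect vector, from the retained draws."""
        th = self.theta  # M x J x K
        mean = th.mean(axis=0)
        out = []
        n_per = np.bincount(self.model.j_idx, minlength=self.model.J)
        for j, pid in enumerate(self.provider_ids):
            d = th[:, j, :]
            out.append(ProviderEffectPosterior(
                provider_id=pid, theta_hat=mean[j],
                V=np.cov(d, rowvar=False).reshape(self.model.K, self.model.K),
                draws=d, n_j=int(n_per[j]),
                dimension_names=self.dimension_names,
            ))
        return out

    def coefficient_draws(self, name: str) -> np.ndarray:
        """Draws (M x K) of the coefficient on covariate ``name`` in every
        dimension that includes it; NaN where a dimension lacks it."""
        M = self.alpha.shape[0]
        out = np.full((M, self.model.K), np.nan)
        for k in range(self.model.K):
            names = self.model.coef_names[k]
            if name in names:
                out[:, k] = self.draws["beta"][k][:, names.index(name)]
        return out

    # ---- diagnostics ------------------------------------------------------
    def diagnostics(self) -> dict:
        """Split-R-hat and crude effective sample sizes for the scalar
        parameters (intercepts, SDs, correlations)."""
        if self._diagnostics is not None:
            return self._diagnostics
        scalars: dict[str, np.ndarray] = {}
        K = self.model.K
        for k, nm in enumerate(self.dimension_names):
            scalars[f"alpha[{nm}]"] = self.alpha[:, k]
            scalars[f"tau[{nm}]"] = self.tau[:, k]
            if not self.model.is_probit[k]:
                scalars[f"sigma[{nm}]"] = self.sigma[:, k]
        for lvl in ("provider", "patient"):
            corr = self._corr_draws(lvl)
            for a in range(K):
                for b_ in range(a + 1, K):
                    scalars[f"rho_{lvl}[{a},{b_}]"] = corr[:, a, b_]
        rhat = {nm: _split_rhat(x) for nm, x in scalars.items()}
        try:
            import arviz as az
            ess = {nm: float(az.ess(x[None, :])) for nm, x in scalars.items()}
        except Exception:
            ess = {nm: float(len(x)) for nm, x in scalars.items()}
        finite = [v for v in rhat.values() if np.isfinite(v)]
        self._diagnostics = {
            "rhat": rhat,
            "ess": ess,
            "max_rhat": max(finite) if finite else np.nan,
            "converged": bool(finite) and max(finite) < self.settings.rhat_threshold,
        }
        return self._diagnostics

    @property
    def converged(self) -> bool:
        return self.diagnostics()["converged"]

    # ---- presentation -----------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        rows = []

        def add(name, x):
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append({"parameter": name, "mean": x.mean(),
                         "sd": x.std(ddof=1), "q2.5": lo, "q97.5": hi})

        K = self.model.K
        for k, nm in enumerate(self.dimension_names):
            add(f"alpha[{nm}]", self.alpha[:, k])
            for i, cn in enumerate(self.model.coef_names[k]):
                if cn != "const":
                    add(f"beta[{nm}][{cn}]", self.draws["beta"][k][:, i])
            add(f"tau[{nm}]", self.tau[:, k])
            if not self.model.is_probit[k]:
                add(f"sigma[{nm}]", self.sigma[:, k])
        for lvl in ("provider", "patient"):
            corr = self._corr_draws(lvl)
            for a in range(K):
                for b_ in range(a + 1, K):
                    add(f"rho_{lvl}[{self.dimension_names[a]},"
                        f"{self.dimension_names[b_]}]", corr[:, a, b_])
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        diag = self.diagnostics()
        head = (
            "Multivariate multilevel model of provider performance\n"
            f"  patients: {self.model.N}   providers: {self.model.J}   "
            f"dimensions: {self.model.K}\n"
            f"  draws: {self.settings.n_draws} (burn-in {self.settings.burn_in}, "
            f"thinning {self.settings.thinning}, seed {self.settings.seed})\n"
            f"  max split-R-hat: {diag['max_rhat']:.3f}  "
            f"converged: {diag['converged']}\n"
        )
        with pd.option_context("display.float_format", "{:10.4f}".format):
            return head + df.to_string(index=False)

    # ---- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        """Persist the fit as a directory of CSV draw files plus JSON
        metadata/diagnostics. Layout (version 1): alpha.csv (M x K),
        beta_<dim>.csv, sigma_draws.csv / omega_draws.csv (flattened rows),
        theta_<dim>.csv (M x J), meta.json, diagnostics.json."""
        p = Path(directory)
        p.mkdir(parents=True, exist_ok=True)
        K, J = self.model.K, self.model.J
        names = list(self.dimension_names)
        pd.DataFrame(self.alpha, columns=names).to_csv(p / "alpha.csv", index=False)
        for k, nm in enumerate(names):
            pd.DataFrame(self.draws["beta"][k],
                         columns=self.model.coef_names[k]
                         ).to_csv(p / f"beta_{nm}.csv", index=False)
            pd.DataFrame(self.theta[:, :, k],
                         columns=[str(x) for x in self.provider_ids]
                         ).to_csv(p / f"theta_{nm}.csv", index=False)
        M = self.alpha.shape[0]
        pd.DataFrame(self.Sigma.reshape(M, K * K)).to_csv(
            p / "sigma_draws.csv", index=False)
        pd.DataFrame(self.Omega.reshape(M, K * K)).to_csv(
            p / "omega_draws.csv", index=False)
        meta = {
            "layout_version": 1,
            "dimension_names": names,
            "provider_ids": [str(x) for x in self.provider_ids],
            "K": K, "J": J, "M": M,
            "settings": {
                "iterations": self.settings.iterations,
                "burn_in": self.settings.burn_in,
                "thinning": self.settings.thinning,
                "seed": self.settings.seed,
            },
            "fingerprint": self.fingerprint,
        }
        (p / "meta.json").write_text(json.dumps(meta, indent=1))
        diag = self.diagnostics()
        (p / "diagnostics.json").write_text(json.dumps(
            {k: (v if not isinstance(v, dict) else v) for k, v in diag.items()},
            indent=1, default=float))


def load_provider_effects(directory) -> list[ProviderEffectPosterior]:
    """Rebuild provider-effect posteriors from a persisted fit directory."""
    p = Path(directory)
    meta = json.loads((p / "meta.json").read_text())
    names = meta["dimension_names"]
    theta = np.stack(
        [pd.read_csv(p / f"theta_{nm}.csv").to_numpy() for nm in names], axis=2
    )  # M x J x K
    out = []
    for j, pid in enumerate(meta["provider_ids"]):
        d = theta[:, j, :]
        out.append(ProviderEffectPosterior(
            provider_id=pid, theta_hat=d.mean(axis=0),
            V=np.cov(d, rowvar=False).reshape(len(names), len(names)),
            draws=d, n_j=-1, dimension_names=tuple(names)))
    return out


def fit_univariate(data: pd.DataFrame, spec: ModelSpec, dimension: str,
                   settings: Optional[McmcSettings] = None,
                   provider_col: str = "provider_id") -> MVMLMResults:
    """Fit the K=1 model for one named dimension with the same engine."""
    model = MultivariateMultilevelModel(data, spec.subset(dimension),
                                        provider_col=provider_col)
    return model.fit(settings)
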