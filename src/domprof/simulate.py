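"""Synthetic patient-level data with the correlated-random-terms structure.

Generates cohorts that mimic elective-surgery profiling data: J providers,
n_j patients each, K correlated outcomes (continuous and binary), per-
dimension risk-adjustment covariates, missing outcomes (MCAR or MAR on a
covariate), and — optionally — endogenous provider choice driven by
distance plus an unobserved patient severity confounder.

The generating model is exactly the estimation model: for patient i in
provider j and dimension k,

    Y*_ijk = alpha_k + X'_ijk beta_k + theta_jk + eps_ijk,

with theta_j ~ MVN(0, Sigma), Sigma = diag(tau) rho_theta diag(tau), and
eps_i ~ MVN(0, Omega), Omega built from rho_eps and the residual SDs
(fixed at 1 on probit dimensions). Gaussian dimensions report the inverse
transform of Y*; probit dimensions report I(Y* > 0).

Default parameter values emulate the hip-replacement application: two
skewed continuous outcomes (length of stay on a log1p scale, a 0-48
patient-reported health score), a >18-week waiting indicator with marginal
rate 0.17, a 28-day readmission indicator with rate 0.05, provider- and
patient-level correlation matrices patterned on the published estimates,
and missingness rates of 15.2% (health score), 4% (waiting) and 0.1%
(length of stay).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .dimensions import DimensionSpec

# sub-stream keys so each generation stage is reproducible in isolation
_STREAM_POPULATION = 0
_STREAM_SELECTION = 1
_STREAM_MISSING = 2


def _check_correlation(name: str, R: np.ndarray, K: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (K, K):
        raise ValueError(f"{name} must be {K}x{K}, got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} does not have a unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError(f"{name} is not positive semi-definite")
    return R


@dataclass
class SelectionConfig:
    """Distance-driven provider choice with an unobserved confounder.

    Choice utility for patient i and provider j is

        u_ij = g1*exp(-lam*c_i)*d_ij + g2*d_ij^2 + g3*d_ij^3
               + delta*closest_ij + Gumbel noise,

    where c_i ~ N(0,1) is unobserved patient severity: with lam > 0,
    severe patients are less distance-sensitive and travel further, so
    their choices deviate systematically from what distance alone
    predicts. The same c_i is added to every outcome error with
    per-dimension loadings, so naive estimation of the provider effects
    is biased (providers drawing distant, severe patients look worse).
    """

    gamma_d: float = -8.0
    gamma_d2: float = 0.0
    gamma_d3: float = 0.0
    delta_closest: float = 0.75
    lam: float = 0.0
    # per-dimension loading of the severity confounder on the outcome errors;
    # None -> -orientation * 0.5 * residual SD (severity hurts every dimension)
    confounder_loadings: Optional[np.ndarray] = None


@dataclass
class SyntheticConfig:
    """All knobs of the generator. ``default_config()`` gives study-like values."""

    J: int
    n_j: int | tuple[int, int]
    dimensions: tuple[DimensionSpec, ...]
    alpha: np.ndarray
    beta: dict  # dim name -> coefficient array aligned with dim.covariates
    covariate_model: dict  # name -> (dist, params); dist in {normal, bernoulli, uniform}
    tau: np.ndarray
    rho_theta: np.ndarray
    sigma: np.ndarray  # residual SD per dim; ignored (forced 1) on probit dims
    rho_eps: np.ndarray
    missing_rates: np.ndarray = None
    missing_mechanism: str = "MCAR"  # or "MAR"
    mar_covariate: str | None = None  # missingness driver under MAR
    mar_slope: float = 1.0
    selection: Optional[SelectionConfig] = None
    top_code_quantile: Optional[float] = None  # e.g. 0.99; applied to gaussian dims
    # pin selected providers' true effects (classification power experiments):
    # J x K array, NaN entries are drawn from MVN(0, Sigma) as usual
    theta_override: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        K = len(self.dimensions)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.missing_rates is None:
            self.missing_rates = np.zeros(K)
        self.missing_rates = np.asarray(self.missing_rates, dtype=float)
        for nm, vec in (("alpha", self.alpha), ("tau", self.tau),
                        ("sigma", self.sigma), ("missing_rates", self.missing_rates)):
            if vec.shape != (K,):
                raise ValueError(f"{nm} must have length K={K}")
        if (self.tau < 0).any():
            raise ValueError("tau must be non-negative")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        if ((self.missing_rates < 0) | (self.missing_rates > 1)).any():
            raise ValueError("missing_rates must lie in [0, 1]")
        self.rho_theta = _check_correlation("rho_theta", self.rho_theta, K)
        self.rho_eps = _check_correlation("rho_eps", self.rho_eps, K)
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")

    @property
    def K(self) -> int:
        return len(self.dimensions)

    @property
    def residual_sd(self) -> np.ndarray:
        """Residual SD actually used: 1 on probit dims (identification)."""
        s = self.sigma.copy()
        for k, d in enumerate(self.dimensions):
            if d.is_probit:
                s[k] = 1.0
        return s

    @property
    def Sigma(self) -> np.ndarray:
        return np.diag(self.tau) @ self.rho_theta @ np.diag(self.tau)

    @property
    def Omega(self) -> np.ndarray:
        s = self.residual_sd
        return np.diag(s) @ self.rho_eps @ np.diag(s)


@dataclass
class SyntheticTruth:
    """Generating parameters and the true provider effects, kept for audit."""

    theta: np.ndarray  # J x K
    config: SyntheticConfig
    complete: Optional[pd.DataFrame] = None  # outcome columns before masking
    latent_confounder: Optional[np.ndarray] = None  # per patient, selection only
    provider_sites: Optional[np.ndarray] = None
    eps: Optional[np.ndarray] = None  # base residual draws, reused by selection

    def to_json(self, path) -> None:
        cfg = self.config
        payload = {
            "theta": self.theta.tolist(),
            "alpha": cfg.alpha.tolist(),
            "tau": cfg.tau.tolist(),
            "sigma": cfg.residual_sd.tolist(),
            "rho_theta": cfg.rho_theta.tolist(),
            "rho_eps": cfg.rho_eps.tolist(),
            "beta": {k: list(map(float, v)) for k, v in cfg.beta.items()},
            "seed": cfg.seed,
            "dimensions": [
                {"name": d.name, "family": d.family, "orientation": d.orientation}
                for d in cfg.dimensions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticDataset:
    patients: pd.DataFrame
    truth: SyntheticTruth

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = self.patients.drop(columns=[c for c in ("_confounder",)
                                          if c in self.patients.columns])
        out.to_csv(directory / "patients.csv", index=False, na_rep="")
        self.truth.to_json(directory / "truth.json")


def _stage_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _draw_covariates(rng, config: SyntheticConfig, n: int) -> pd.DataFrame:
    cols = {}
    for name, (dist, params) in config.covariate_model.items():
        if dist == "normal":
            x = rng.normal(params.get("mean", 0.0), params.get("sd", 1.0), n)
            x = x - x.mean()  # continuous covariates are mean-centred
        elif dist == "bernoulli":
            x = rng.binomial(1, params.get("p", 0.5), n).astype(float)
        elif dist == "uniform":
            x = rng.uniform(params.get("low", 0.0), params.get("high", 1.0), n)
            x = x - x.mean()
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
        cols[name] = x
    return pd.DataFrame(cols, index=pd.RangeIndex(n))


def _linear_predictor(config: SyntheticConfig, X: pd.DataFrame) -> np.ndarray:
    """alpha_k + X'beta_k for every patient and dimension (no random terms)."""
    n = len(X)
    mu = np.tile(config.alpha, (n, 1))
    for k, d in enumerate(config.dimensions):
        beta = np.asarray(config.beta.get(d.name, np.zeros(len(d.covariates))), float)
        if len(d.covariates) != len(beta):
            raise ValueError(f"beta for {d.name!r} has wrong length")
        if len(d.covariates):
            mu[:, k] += X[list(d.covariates)].to_numpy() @ beta
    return mu


def _observe(config: SyntheticConfig, ystar: np.ndarray) -> pd.DataFrame:
    """Map latent draws to the observed scale, dimension by dimension."""
    out = {}
    for k, d in enumerate(config.dimensions):
        if d.is_probit:
            out[d.name] = (ystar[:, k] > 0).astype(float)
        else:
            y = d.to_observed(ystar[:, k])
            if config.top_code_quantile is not None:
                y = np.minimum(y, np.quantile(y, config.top_code_quantile))
            out[d.name] = y
    return pd.DataFrame(out)


def generate_population(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete cohort (no missingness, no selection) from the model."""
    rng = _stage_rng(config.seed, _STREAM_POPULATION)
    J, K = config.J, config.K

    if isinstance(config.n_j, tuple):
        lo, hi = config.n_j
        n_per = rng.integers(lo, hi + 1, size=J)
    else:
        n_per = np.full(J, int(config.n_j))
    N = int(n_per.sum())
    j_idx = np.repeat(np.arange(J), n_per)

    theta = rng.multivariate_normal(np.zeros(K), config.Sigma, size=J, method="svd")
    if config.theta_override is not None:
        override = np.asarray(config.theta_override, dtype=float)
        if override.shape != (J, K):
            raise ValueError("theta_override must be J x K")
        pin = ~np.isnan(override)
        theta[pin] = override[pin]
    eps = rng.multivariate_normal(np.zeros(K), config.Omega, size=N, method="svd")

    X = _draw_covariates(rng, config, N)
    ystar = _linear_predictor(config, X) + theta[j_idx] + eps
    ydf = _observe(config, ystar)

    patients = pd.concat(
        [pd.DataFrame({"patient_id": np.arange(N), "provider_id": j_idx}), ydf, X],
        axis=1,
    )
    truth = SyntheticTruth(theta=theta, config=config,
                           complete=ydf.copy(), eps=eps)
    return SyntheticDataset(patients=patients, truth=truth)


def generate_selection(data: SyntheticDataset, config: SyntheticConfig) -> SyntheticDataset:
    """Endogenise provider choice: distance-driven conditional-logit assignment
    with an unobserved severity confounder entering both choice and outcomes.

    Outcomes are regenerated under the chosen provider, reusing the base
    residual draws and adding the scaled confounder, so naive estimation is
    biased when ``lam > 0``. Per-provider straight-line distances are stored
    as ``dist_to_<j>`` columns.
    """
    sel = config.selection
    if sel is None:
        raise ValueError("config.selection block is required")
    if config.J < 2:
        raise ValueError("selection requires at least 2 providers")
    rng = _stage_rng(config.seed, _STREAM_SELECTION)

    J, K = config.J, config.K
    pat = data.patients.copy()
    N = len(pat)

    sites = rng.uniform(0, 1, size=(J, 2))
    coords = rng.uniform(0, 1, size=(N, 2))
    dist = np.linalg.norm(coords[:, None, :] - sites[None, :, :], axis=2)  # N x J
    closest = (dist == dist.min(axis=1, keepdims=True)).astype(float)

    conf = rng.normal(size=N)

    sens = np.exp(-sel.lam * conf)  # severity damps distance sensitivity
    util = (sel.gamma_d * sens[:, None] * dist
            + sel.gamma_d2 * dist**2 + sel.gamma_d3 * dist**3
            + sel.delta_closest * closest)
    gumbel = rng.gumbel(size=(N, J))
    chosen = np.argmax(util + gumbel, axis=1)

    loadings = sel.confounder_loadings
    if loadings is None:
        orient = np.array([d.orientation for d in config.dimensions], float)
        loadings = -orient * 0.5 * config.residual_sd
    loadings = np.asarray(loadings, dtype=float)

    cov_names = list(config.covariate_model.keys())
    X = pat[cov_names]
    eps = data.truth.eps + conf[:, None] * loadings[None, :]
    ystar = _linear_predictor(config, X) + data.truth.theta[chosen] + eps
    ydf = _observe(config, ystar)

    pat["provider_id"] = chosen
    for k, d in enumerate(config.dimensions):
        pat[d.name] = ydf[d.name].to_numpy()
    for j in range(J):
        pat[f"dist_to_{j}"] = dist[:, j]

    truth = replace(data.truth, complete=ydf.copy(), latent_confounder=conf,
                    provider_sites=sites)
    return SyntheticDataset(patients=pat, truth=truth)


def apply_missingness(data: SyntheticDataset, config: SyntheticConfig) -> SyntheticDataset:
    """Mask outcome cells. MCAR masks uniformly at the per-dimension rate;
    MAR makes the masking probability logistic in ``mar_covariate``, with the
    intercept calibrated so the marginal rate still matches. Covariates are
    never masked; the complete outcomes stay in ``truth.complete``.
    """
    rates = config.missing_rates
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("missing rates must lie in [0, 1]")
    rng = _stage_rng(config.seed, _STREAM_MISSING)
    pat = data.patients.copy()
    n = len(pat)

    if config.missing_mechanism == "MAR":
        xname = config.mar_covariate or next(
            nm for nm, (dist, _) in config.covariate_model.items() if dist != "bernoulli"
        )
        x = pat[xname].to_numpy(dtype=float)

    for k, d in enumerate(config.dimensions):
        rate = rates[k]
        if rate == 0:
            continue
        if rate == 1:
            mask = np.ones(n, bool)
        elif config.missing_mechanism == "MCAR":
            mask = rng.uniform(size=n) < rate
        else:  # MAR: p_i = expit(a + b x_i), a solved so mean(p) = rate
            b = config.mar_slope
            a = brentq(lambda a_: expit(a_ + b * x).mean() - rate, -40, 40)
            mask = rng.uniform(size=n) < expit(a + b * x)
        col = pat[d.name].to_numpy(dtype=float)
        col[mask] = np.nan
        pat[d.name] = col

    truth = replace(data.truth, complete=data.truth.complete)
    return SyntheticDataset(patients=pat, truth=truth)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Population draw, then selection (if configured), then missingness."""
    data = generate_population(config)
    if config.selection is not None:
        data = generate_selection(data, config)
    if (config.missing_rates > 0).any():
        data = apply_missingness(data, config)
    return data


def probit_intercept(rate: float, tau: float) -> float:
    """Latent intercept giving marginal event probability ``rate`` when the
    provider effect has SD ``tau``:  Phi(alpha / sqrt(1 + tau^2)) = rate."""
    return float(ndtri(rate) * np.sqrt(1.0 + tau**2))


def default_dimensions() -> tuple[DimensionSpec, ...]:
    """The four study-like dimensions: length of stay (log1p, lower better),
    post-operative health score (identity, higher better), waiting beyond
    18 weeks and 28-day readmission (probits, event = bad). Waiting time is
    deliberately not risk-adjusted."""
    core = ("preop_score", "male", "deprivation")
    return (
        DimensionSpec("los", "gaussian", transform="log1p", orientation=-1,
                      covariates=core),
        DimensionSpec("ohs_post", "gaussian", transform="identity", orientation=+1,
                      covariates=core),
        DimensionSpec("wait_over_18wk", "probit", orientation=-1, covariates=()),
        DimensionSpec("readmit_28d", "probit", orientation=-1, covariates=core),
    )


# Provider-level (oriented-to-raw) correlations patterned on the published
# profiling estimates: LOS-OHS -0.34, LOS-wait 0.26, OHS-wait -0.31,
# LOS-readm 0.03, OHS-readm -0.49, wait-readm 0.16. On the oriented
# (utility) scale all pairs are positive.
_RHO_THETA = np.array([
    [1.00, -0.34, 0.26, 0.03],
    [-0.34, 1.00, -0.31, -0.49],
    [0.26, -0.31, 1.00, 0.16],
    [0.03, -0.49, 0.16, 1.00],
])
_RHO_EPS = np.array([
    [1.00, -0.13, 0.02, 0.02],
    [-0.13, 1.00, -0.02, -0.07],
    [0.02, -0.02, 1.00, 0.00],
    [0.02, -0.07, 0.00, 1.00],
])


def default_config(J: int = 100, n_j: int | tuple[int, int] = 100, seed: int = 0,
                   selection: Optional[SelectionConfig] = None,
                   missing: bool = True) -> SyntheticConfig:
    """Study-conditioned defaults.

    Marginal event rates 0.17 (waiting > 18 weeks) and 0.05 (28-day
    readmission); mean length of stay ~5.4 days with right skew on the raw
    scale; health score centred near 38.5 with SD ~9; missingness 15.2% /
    4% / 0.1% / 0% (health score / waiting / LOS / readmission).
    """
    dims = default_dimensions()
    tau = np.array([0.12, 1.2, 0.25, 0.20])
    sigma = np.array([0.45, 8.8, 1.0, 1.0])
    alpha = np.array([
        1.80,                              # log1p(LOS) scale
        38.5,                              # health score
        probit_intercept(0.17, tau[2]),
        probit_intercept(0.05, tau[3]),
    ])
    beta = {
        # sicker (higher preop score = worse here): longer stay, lower score,
        # higher readmission risk; males slightly shorter stay.
        "los": np.array([0.10, -0.03, 0.08]),
        "ohs_post": np.array([-2.5, 0.6, -1.5]),
        "wait_over_18wk": np.array([]),
        "readmit_28d": np.array([0.12, 0.05, 0.10]),
    }
    covariate_model = {
        "preop_score": ("normal", {}),
        "male": ("bernoulli", {"p": 0.41}),
        "deprivation": ("uniform", {}),
    }
    rates = np.array([0.001, 0.152, 0.04, 0.0]) if missing else np.zeros(4)
    return SyntheticConfig(
        J=J, n_j=n_j, dimensions=dims, alpha=alpha, beta=beta,
        covariate_model=covariate_model, tau=tau, rho_theta=_RHO_THETA.copy(),
        sigma=sigma, rho_eps=_RHO_EPS.copy(), missing_rates=rates,
        selection=selection, seed=seed,
    )
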