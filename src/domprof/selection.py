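"""Two-stage residual inclusion for endogenous provider choice.

Patients choose their provider, and unobserved factors (severity, health
literacy) can drive both the choice and the outcomes, biasing the provider
effects. Straight-line distance from the patient's residence to each
provider is the instrument: a conditional-logit choice model over distance,
distance^2, distance^3 and a closest-provider indicator gives per-patient
predicted choice probabilities. The generalised first-stage residual
r_i = 1 - p_hat(chosen alternative) is then entered as a regressor into
every outcome dimension; a joint Wald test of its K coefficients detects
selection bias, and the refitted model gives corrected provider posteriors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from .dimensions import ModelSpec
from .gibbs import McmcSettings
from .model import MultivariateMultilevelModel, MVMLMResults

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("distance", "distance^2", "distance^3", "closest")


@dataclass
class ChoiceData:
    """Per-patient choice sets with alternative-specific distance features."""

    patient_ids: np.ndarray        # (N,)
    provider_ids: list             # choice-set providers, length Jc
    distances: np.ndarray          # (N, Jc)
    chosen: np.ndarray             # (N,) index into provider_ids
    closest: np.ndarray            # (N, Jc) 0/1, exactly one per row
    n_dropped: int = 0             # patients dropped by the volume floor

    def __post_init__(self):
        if (self.distances < 0).any():
            raise ValueError("distances must be non-negative")
        if not (self.closest.sum(axis=1) == 1).all():
            raise ValueError("each patient must have exactly one closest provider")

    @property
    def n_alternatives(self) -> int:
        return len(self.provider_ids)


def choice_data_from_wide(data: pd.DataFrame, prefix: str = "dist_to_",
                          provider_col: str = "provider_id",
                          patient_col: str = "patient_id") -> ChoiceData:
    """Build choice sets from wide ``dist_to_<provider>`` columns."""
    dist_cols = [c for c in data.columns if c.startswith(prefix)]
    if not dist_cols:
        raise ValueError(f"no {prefix}* columns found")
    provider_ids = [c[len(prefix):] for c in dist_cols]
    # match the dtype of the provider column where possible
    sample = data[provider_col].iloc[0]
    if isinstance(sample, (int, np.integer)):
        provider_ids = [int(x) for x in provider_ids]
    dist = data[dist_cols].to_numpy(dtype=float)
    chosen_raw = data[provider_col].to_numpy()
    lookup = {pid: i for i, pid in enumerate(provider_ids)}
    try:
        chosen = np.array([lookup[c] for c in chosen_raw])
    except KeyError as e:
        raise ValueError(f"chosen provider {e} has no distance column") from e
    closest = np.zeros_like(dist)
    closest[np.arange(len(dist)), dist.argmin(axis=1)] = 1.0
    return ChoiceData(patient_ids=data[patient_col].to_numpy(),
                      provider_ids=provider_ids, distances=dist,
                      chosen=chosen, closest=closest)


def build_choice_set(choice: ChoiceData, min_patients: int = 30) -> ChoiceData:
    """Apply the volume floor: providers with fewer than ``min_patients``
    chosen patients leave every choice set; their patients are dropped with
    a logged count."""
    counts = np.bincount(choice.chosen, minlength=choice.n_alternatives)
    keep = counts >= min_patients
    if keep.all():
        return choice
    if not keep.any():
        raise ValueError("volume floor removes every provider")
    drop_pat = ~keep[choice.chosen]
    n_dropped = int(drop_pat.sum())
    logger.info("volume floor %d: removed %d providers, dropped %d patients",
                min_patients, int((~keep).sum()), n_dropped)
    rows = ~drop_pat
    dist = choice.distances[np.ix_(rows, keep)]
    if dist.shape[1] == 0 or dist.shape[0] == 0:
        raise ValueError("empty choice set after applying the volume floor")
    old_to_new = np.cumsum(keep) - 1
    closest = np.zeros_like(dist)
    closest[np.arange(len(dist)), dist.argmin(axis=1)] = 1.0
    return ChoiceData(
        patient_ids=choice.patient_ids[rows],
        provider_ids=[p for p, k in zip(choice.provider_ids, keep) if k],
        distances=dist, chosen=old_to_new[choice.chosen[rows]],
        closest=closest, n_dropped=choice.n_dropped + n_dropped,
    )


@dataclass
class ChoiceFit:
    """Fitted conditional logit over distance features."""

    coefficients: np.ndarray       # raw-scale (distance, ^2, ^3, closest)
    loglik: float
    loglik_null: float
    probabilities: np.ndarray      # (N, Jc), rows sum to 1
    converged: bool
    se: Optional[np.ndarray] = None


def _features(choice: ChoiceData, centre: float) -> np.ndarray:
    """(N, Jc, 4) centred polynomial + closest-indicator features."""
    dc = choice.distances - centre
    return np.stack([dc, dc**2, dc**3, choice.closest], axis=2)


def _raw_coefficients(b: np.ndarray, c: float) -> np.ndarray:
    """Map coefficients on the centred basis (d-c)^p back to the raw basis
    d^p (the alternative-invariant constant term drops from the logit)."""
    return np.array([
        b[0] - 2 * b[1] * c + 3 * b[2] * c**2,
        b[1] - 3 * b[2] * c,
        b[2],
        b[3],
    ])


def fit_conditional_logit(choice: ChoiceData) -> ChoiceFit:
    """Maximum-likelihood conditional logit; deterministic given the data.

    The distance polynomial is computed on the mean-centred distance for
    numerical stability and the coefficients are reported on the raw scale.
    """
    if choice.n_alternatives < 2:
        raise ValueError("need at least 2 alternatives per patient")
    centre = float(choice.distances.mean())
    F = _features(choice, centre)  # N x J x 4
    N = F.shape[0]
    rows = np.arange(N)

    def negll_grad(b):
        u = F @ b                              # N x J
        lse = logsumexp(u, axis=1)
        ll = u[rows, choice.chosen].sum() - lse.sum()
        p = np.exp(u - lse[:, None])
        gr = F[rows, choice.chosen].sum(axis=0) - np.einsum("nj,njf->f", p, F)
        return -ll, -gr

    res = minimize(negll_grad, np.zeros(4), jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1.0, N):
        raise RuntimeError(f"conditional logit did not converge: {res.message}")
    u = F @ res.x
    p = np.exp(u - logsumexp(u, axis=1)[:, None])
    ll0 = -N * np.log(choice.n_alternatives)
    # delta-method SEs on the raw scale via the centred-basis Hessian
    se = None
    try:
        Hinv = res.hess_inv
        Jac = np.array([[1, 0, 0, 0],
                        [-2 * centre, 1, 0, 0],
                        [3 * centre**2, -3 * centre, 1, 0],
                        [0, 0, 0, 1]]).T
        cov_raw = Jac.T @ Hinv @ Jac
        se = np.sqrt(np.clip(np.diag(cov_raw), 0, None))
    except Exception:
        pass
    return ChoiceFit(coefficients=_raw_coefficients(res.x, centre),
                     loglik=float(-res.fun), loglik_null=float(ll0),
                     probabilities=p, converged=bool(res.success), se=se)


def first_stage_residuals(fit: ChoiceFit, choice: ChoiceData) -> pd.DataFrame:
    """Generalised residual r_i = 1 - p_hat(chosen alternative), one scalar
    per patient, returned keyed by patient id."""
    p_chosen = fit.probabilities[np.arange(len(choice.chosen)), choice.chosen]
    return pd.DataFrame({"patient_id": choice.patient_ids,
                         "choice_residual": 1.0 - p_chosen})


@dataclass
class SelectionTestReport:
    coefficients: np.ndarray   # posterior means of the K residual coefficients
    covariance: np.ndarray     # posterior covariance of those coefficients
    statistic: float           # Wald chi-square analogue
    df: int
    p_value: float
    corrected: MVMLMResults
    dimension_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"coefficients": self.coefficients.tolist(),
                "covariance": self.covariance.tolist(),
                "statistic": self.statistic, "df": self.df,
                "p_value": self.p_value,
                "dimensions": list(self.dimension_names)}


def second_stage_test(data: pd.DataFrame, spec: ModelSpec,
                      settings: Optional[McmcSettings] = None,
                      residual_col: str = "choice_residual",
                      provider_col: str = "provider_id") -> SelectionTestReport:
    """Refit the model with the first-stage residual in every dimension and
    test the K residual coefficients jointly (posterior Wald analogue on K
    degrees of freedom). Returns the corrected fit alongside the test."""
    settings = settings or McmcSettings()
    if residual_col not in data.columns:
        raise ValueError(f"residual column {residual_col!r} not in data")
    r = data[residual_col].to_numpy(dtype=float)
    if np.ptp(r) == 0:
        raise ValueError("residual column is constant; test is degenerate")
    spec2 = ModelSpec(dimensions=spec.dimensions,
                      provider_mean_covariates=spec.provider_mean_covariates,
                      residual_column=residual_col)
    fit = MultivariateMultilevelModel(data, spec2, provider_col=provider_col
                                      ).fit(settings)
    cd = fit.coefficient_draws(residual_col)   # M x K
    c = cd.mean(axis=0)
    V = np.cov(cd, rowvar=False).reshape(spec.K, spec.K)
    stat = float(c @ np.linalg.solve(V, c))
    return SelectionTestReport(
        coefficients=c, covariance=V, statistic=stat, df=spec.K,
        p_value=float(chi2.sf(stat, spec.K)), corrected=fit,
        dimension_names=tuple(spec.names),
    )


def attach_residuals(data: pd.DataFrame, min_patients: int = 30,
                     provider_col: str = "provider_id",
                     patient_col: str = "patient_id") -> pd.DataFrame:
    """Convenience: build choice sets from wide distance columns, fit the
    conditional logit, and merge the residual onto the patient table
    (patients dropped by the volume floor are dropped here too)."""
    choice = choice_data_from_wide(data, provider_col=provider_col,
                                   patient_col=patient_col)
    choice = build_choice_set(choice, min_patients=min_patients)
    clfit = fit_conditional_logit(choice)
    resid = first_stage_residuals(clfit, choice)
    resid = resid.rename(columns={"patient_id": patient_col})
    return data.merge(resid, on=patient_col, how="inner")
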