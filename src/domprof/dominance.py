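"""Dominance classification of providers against a benchmark.

A provider *dominates* the benchmark when its true effect is better on
every dimension, *is dominated* when worse on every dimension, and is
*non-comparable* otherwise (better on some, worse on others — no ranking
without weights). With the provider-effect posterior approximately
multivariate normal, these are orthant probabilities of the posterior:

    Pr(dominant)   = (1/S) sum_s prod_k I(z_ks > 0)
    Pr(dominated)  = (1/S) sum_s prod_k I(z_ks < 0)
    Pr(non-comp.)  = 1 - Pr(dominant) - Pr(dominated)

where z_ks is the oriented, benchmark-centred effect in simulation draw s.
The default benchmark is the conditional mean — the performance of a
hypothetical provider of average performance alpha_k, i.e. theta* = 0.

Also implemented: a deterministic orthant-probability oracle, the
"confidence box" approach (per-dimension one-sided probabilities with an
optional Bonferroni correction) and the three-way comparison of
univariate / intermediate / full multivariate classification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from .dimensions import ModelSpec
from .gibbs import McmcSettings
from .model import (MultivariateMultilevelModel, MVMLMResults,
                    ProviderEffectPosterior, fit_univariate)

LABELS = ("dominant", "dominated", "unclassified")


@dataclass(frozen=True)
class Benchmark:
    """Performance standard providers are compared to.

    ``conditional_mean`` mode compares to a hypothetical average provider
    (theta* = 0); ``absolute`` mode uses an externally supplied theta*
    on the latent scale. ``orientation`` holds +1/-1 per dimension so every
    comparison is on a "higher is better" scale.
    """

    orientation: np.ndarray
    mode: str = "conditional_mean"
    theta_star: Optional[np.ndarray] = None

    def __post_init__(self):
        orient = np.asarray(self.orientation, dtype=float)
        if not np.isin(orient, (1.0, -1.0)).all():
            raise ValueError("orientation entries must be +1 or -1")
        object.__setattr__(self, "orientation", orient)
        if self.mode not in ("conditional_mean", "absolute"):
            raise ValueError("mode must be 'conditional_mean' or 'absolute'")
        if self.mode == "absolute":
            ts = np.asarray(self.theta_star, dtype=float)
            if ts.shape != orient.shape or not np.isfinite(ts).all():
                raise ValueError("theta_star must be a finite K-vector")
            object.__setattr__(self, "theta_star", ts)
        else:
            object.__setattr__(self, "theta_star", np.zeros_like(orient))

    @classmethod
    def from_spec(cls, spec: ModelSpec, mode: str = "conditional_mean",
                  theta_star=None) -> "Benchmark":
        return cls(orientation=spec.orientations, mode=mode, theta_star=theta_star)


@dataclass
class DominanceResult:
    """Dominance probabilities and threshold labels for one provider."""

    provider_id: object
    p_dominant: float
    p_dominated: float
    p_noncomparable: float
    S: int
    p_k: np.ndarray          # per-dimension one-sided Pr(better than benchmark)
    labels: dict             # threshold -> label
    approach: str = "full"
    mc_se: float = 0.0       # binomial Monte-Carlo SE at S for p ~ 0.5

    def __post_init__(self):
        for p in (self.p_dominant, self.p_dominated, self.p_noncomparable):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        total = self.p_dominant + self.p_dominated + self.p_noncomparable
        if abs(total - 1.0) > 1e-12:
            raise ValueError("dominance probabilities must sum to 1")


def _clip_psd(V: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clip a posterior covariance to PSD; warn if clipping bites."""
    V = 0.5 * (V + V.T)
    w, Q = np.linalg.eigh(V)
    if w.min() < -tol * max(1.0, w.max()):
        warnings.warn("posterior covariance not PSD; clipping negative "
                      f"eigenvalues (min {w.min():.3g})")
    w = np.clip(w, tol * max(w.max(), tol), None)
    return Q @ np.diag(w) @ Q.T


def orthant_probability(mean, cov, signs) -> float:
    """Deterministic Pr(sign_k * X_k > 0 for all k), X ~ MVN(mean, cov).

    Genz-style numerical integration via the multivariate normal CDF,
    accurate to ~1e-5 for K <= 6. The deterministic counterpart of the
    simulation estimator, used as its oracle.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    signs = np.atleast_1d(np.asarray(signs, dtype=float))
    K = mean.size
    if K > 6:
        raise ValueError("orthant_probability supports K <= 6")
    if not np.isin(signs, (1.0, -1.0)).all():
        raise ValueError("signs must be +1/-1")
    m = signs * mean
    C = cov * np.outer(signs, signs)
    sd = np.sqrt(np.diag(C))
    if K == 1:
        return float(ndtr(m[0] / sd[0]))
    # P(Y > 0 componentwise) = CDF of N(-m, C) at the origin
    mvn = multivariate_normal(mean=-m, cov=C, allow_singular=True,
                              seed=np.random.default_rng(0))
    return float(np.clip(mvn.cdf(np.zeros(K)), 0.0, 1.0))


def dominance_probabilities(post: ProviderEffectPosterior, bench: Benchmark,
                            S: int = 10_000, seed: int = 0,
                            mode: str = "mvn",
                            thresholds: Sequence[float] = (0.9,)
                            ) -> DominanceResult:
    """Simulate the posterior classification probabilities for one provider.

    ``mode='mvn'`` draws S samples from MVN(theta_hat, V) (the default);
    ``mode='draws'`` resamples the retained MCMC draws of theta_j with
    replacement. Ties at exactly zero count against the strict inequality.
    """
    if S < 1000:
        raise ValueError("S must be at least 1000")
    if mode not in ("mvn", "draws"):
        raise ValueError("mode must be 'mvn' or 'draws'")
    rng = np.random.default_rng(seed)
    orient, ts = bench.orientation, bench.theta_star
    K = orient.size

    if mode == "mvn":
        V = _clip_psd(np.atleast_2d(post.V))
        L = np.linalg.cholesky(V)
        sims = post.theta_hat[None, :] + rng.standard_normal((S, K)) @ L.T
    else:
        idx = rng.integers(0, len(post.draws), size=S)
        sims = post.draws[idx]

    z = (sims - ts[None, :]) * orient[None, :]
    n_dom = int((z > 0).all(axis=1).sum())
    n_ded = int((z < 0).all(axis=1).sum())
    # integer counts keep p_dom + p_ded + p_nc = 1 exact
    p_dom = n_dom / S
    p_ded = n_ded / S
    p_nc = (S - n_dom - n_ded) / S

    zhat = orient * (post.theta_hat - ts)
    sd = np.sqrt(np.clip(np.diag(np.atleast_2d(post.V)), 1e-300, None))
    p_k = ndtr(zhat / sd)

    res = DominanceResult(
        provider_id=post.provider_id, p_dominant=p_dom, p_dominated=p_ded,
        p_noncomparable=p_nc, S=S, p_k=p_k, labels={}, approach="full",
        mc_se=float(0.5 / np.sqrt(S)),
    )
    res.labels = {t: classify(res, t) for t in thresholds}
    return res


def classify(result: DominanceResult, threshold: float) -> str:
    """Label a provider at a probability threshold in [0.5, 1].

    Above 0.5 at most one of the two conditions can fire; at exactly 0.5
    (the bottom of the customary threshold grid) a tie would need
    p_dominant = p_dominated = 0.5 exactly, and the dominant condition is
    checked first. Neither condition firing gives 'unclassified'.
    """
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0.5, 1]")
    if result.p_dominant >= threshold:
        return "dominant"
    if result.p_dominated >= threshold:
        return "dominated"
    return "unclassified"


def confidence_box_classify(p_k: np.ndarray, threshold: float,
                            correction: str = "bonferroni") -> str:
    """Classify from per-dimension one-sided probabilities alone.

    ``p_k`` holds Pr(better than benchmark on dimension k). A provider is
    dominant when every p_k reaches the (possibly Bonferroni-corrected)
    cut 1 - (1 - threshold)/K, dominated when every 1 - p_k does; the
    comparison is >= (boundary passes).
    """
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0.5, 1]")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    p_k = np.asarray(p_k, dtype=float)
    K = p_k.size
    cut = 1.0 - (1.0 - threshold) / K if correction == "bonferroni" else threshold
    if (p_k >= cut).all():
        return "dominant"
    if (1.0 - p_k >= cut).all():
        return "dominated"
    return "unclassified"


def assess_providers(results: MVMLMResults, bench: Optional[Benchmark] = None,
                     S: int = 10_000, seed: int = 0,
                     thresholds: Sequence[float] = (0.5, 0.8, 0.9, 0.99),
                     mode: str = "mvn",
                     require_convergence: bool = False) -> pd.DataFrame:
    """Dominance probabilities and labels for every provider of a fit.

    With ``require_convergence=True`` the call refuses to classify from a
    chain whose split-R-hat exceeds the gate.
    """
    if require_convergence and not results.converged:
        raise RuntimeError(
            "fit failed the convergence gate (split-R-hat "
            f"{results.diagnostics()['max_rhat']:.3f}); pass "
            "require_convergence=False to override")
    bench = bench or Benchmark.from_spec(results.model.spec)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(results.provider_ids))
    for i, post in enumerate(results.provider_effects()):
        r = dominance_probabilities(post, bench, S=S, seed=int(child_seeds[i]),
                                    mode=mode, thresholds=thresholds)
        row = {"provider_id": r.provider_id, "n_j": post.n_j,
               "p_dominant": r.p_dominant, "p_dominated": r.p_dominated,
               "p_noncomparable": r.p_noncomparable, "mc_se": r.mc_se}
        for k, nm in enumerate(post.dimension_names):
            row[f"p_better[{nm}]"] = r.p_k[k]
            row[f"theta_hat[{nm}]"] = post.theta_hat[k]
        for t in thresholds:
            row[f"label@{t}"] = r.labels[t]
        rows.append(row)
    return pd.DataFrame(rows)


def _count_labels(labels: Iterable[str]) -> dict:
    labels = list(labels)
    return {"dominant": labels.count("dominant"),
            "dominated": labels.count("dominated")}


def compare_approaches(data: pd.DataFrame, spec: ModelSpec,
                       settings: Optional[McmcSettings] = None,
                       thresholds: Sequence[float] = (0.5, 0.8, 0.9, 0.99),
                       S: int = 10_000, seed: int = 0,
                       bench: Optional[Benchmark] = None,
                       provider_col: str = "provider_id") -> dict:
    """Counts of dominant/dominated providers under three approaches:

    (1) univariate  — separate K=1 fits, confidence-box rule (Bonferroni);
    (2) intermediate — multivariate fit, box rule on its marginals;
    (3) full        — multivariate fit, joint orthant simulation.

    Returns ``{"counts": {threshold: {approach: {...}}}, "labels": ...,
    "table": DataFrame}``.
    """
    settings = settings or McmcSettings()
    bench = bench or Benchmark.from_spec(spec)
    orient, ts = bench.orientation, bench.theta_star

    mv = MultivariateMultilevelModel(data, spec, provider_col=provider_col).fit(settings)
    posts = mv.provider_effects()
    pids = [p.provider_id for p in posts]

    # univariate per-dimension posteriors
    uni_pk = np.zeros((len(pids), spec.K))
    for k, dim in enumerate(spec.dimensions):
        from dataclasses import replace as _dc_replace
        uset = _dc_replace(settings, seed=settings.seed + 101 + k)
        ur = fit_univariate(data, spec, dim.name, uset, provider_col=provider_col)
        for p in ur.provider_effects():
            j = pids.index(p.provider_id)
            zhat = orient[k] * (p.theta_hat[0] - ts[k])
            uni_pk[j, k] = ndtr(zhat / max(np.sqrt(p.V[0, 0]), 1e-150))

    inter_pk = np.zeros((len(pids), spec.K))
    full_res = []
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(len(pids))
    for j, p in enumerate(posts):
        zhat = orient * (p.theta_hat - ts)
        inter_pk[j] = ndtr(zhat / np.sqrt(np.clip(np.diag(p.V), 1e-300, None)))
        full_res.append(dominance_probabilities(
            p, bench, S=S, seed=int(child[j]), thresholds=thresholds))

    counts: dict = {}
    labels: dict = {}
    rows = []
    for t in thresholds:
        lab_uni = [confidence_box_classify(uni_pk[j], t) for j in range(len(pids))]
        lab_int = [confidence_box_classify(inter_pk[j], t) for j in range(len(pids))]
        lab_full = [classify(r, t) for r in full_res]
        labels[t] = {"univariate": lab_uni, "intermediate": lab_int,
                     "full": lab_full, "provider_ids": pids}
        counts[t] = {"univariate": _count_labels(lab_uni),
                     "intermediate": _count_labels(lab_int),
                     "full": _count_labels(lab_full)}
        for appr in ("univariate", "intermediate", "full"):
            rows.append({"threshold": t, "approach": appr, **counts[t][appr]})
    return {"counts": counts, "labels": labels, "table": pd.DataFrame(rows),
            "fit": mv}


def ellipse_box_coordinates(post: ProviderEffectPosterior, bench: Benchmark,
                            dims: tuple[int, int] = (0, 1), level: float = 0.95,
                            n_points: int = 200) -> dict:
    """Plain coordinates of the joint confidence ellipse and the
    Bonferroni-corrected confidence box for two dimensions, for plotting
    the box-vs-ellipse contrast externally."""
    from scipy.stats import chi2, norm
    i, j = dims
    orient = bench.orientation[[i, j]]
    m = orient * (post.theta_hat[[i, j]] - bench.theta_star[[i, j]])
    V = post.V[np.ix_([i, j], [i, j])] * np.outer(orient, orient)
    w, Q = np.linalg.eigh(_clip_psd(V))
    r = np.sqrt(chi2.ppf(level, df=2))
    t = np.linspace(0, 2 * np.pi, n_points)
    circ = np.stack([np.cos(t), np.sin(t)])
    ell = (Q @ (np.sqrt(w)[:, None] * circ)) * r + m[:, None]
    zcut = norm.ppf(1.0 - (1.0 - level) / 2 / 2)  # Bonferroni over 2 dims
    sd = np.sqrt(np.diag(V))
    box = {"x": [m[0] - zcut * sd[0], m[0] + zcut * sd[0]],
           "y": [m[1] - zcut * sd[1], m[1] + zcut * sd[1]]}
    return {"centre": m.tolist(), "ellipse_x": ell[0].tolist(),
            "ellipse_y": ell[1].tolist(), "box": box}
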