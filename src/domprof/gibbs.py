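"""Gibbs sampler for the multivariate multilevel model.

The sampler augments the data with (a) latent Gaussian variables behind the
probit dimensions (truncated-normal draws) and (b) draws of missing outcome
cells from their conditional multivariate normal given the observed
dimensions — which operationalises missing-at-random conditional on the
modelled covariates and the observed performance dimensions. Conditional on
the complete latent matrix the updates are conjugate: normal draws for the
regression coefficients, per-provider multivariate-normal draws for the
random effects, and inverse-Wishart draws for both covariance matrices.

Identification of the probit scales (unit error variance) is maintained by
parameter expansion: the patient-level covariance is drawn unconstrained
and the draw, the latent data, the coefficients, the provider effects and
the provider-level covariance are rescaled back to the identified scale
before storage.

A translation move (an ancillarity-sufficiency interweaving step) swaps
mass between the intercepts and the mean of the provider effects each
iteration; it leaves the likelihood untouched and removes the slow random
walk between alpha_k and mean_j(theta_jk).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri

_PTAIL = 1e-14  # probability clip for truncated-normal inversion
_DISABLE_TRANSLATION = False  # debugging switch for the interweaving move


@dataclass
class McmcSettings:
    """Chain length, seed and priors.

    Coefficients have independent N(0, coef_prior_var) priors; Sigma
    (provider level) and Omega (patient level) have inverse-Wishart priors
    with ``K + wishart_extra_df`` degrees of freedom. ``wishart_scale``
    is either a float c (scale matrix c * I at both levels) or "auto"
    (default): the scale is a diagonal method-of-moments estimate of the
    level's variances, so the prior carries the weight of roughly one
    pseudo-observation at the data's own scale instead of pulling the
    variances toward an arbitrary constant — which matters when J is small.
    """

    iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0
    coef_prior_var: float = 1e4
    wishart_extra_df: float = 2.0
    wishart_scale: float | str = "auto"
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


def _rinvwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (deterministic
    given ``rng``)."""
    K = scale.shape[0]
    # W ~ Wishart(df, inv(scale)); return inv(W)
    L_inv_scale = cholesky(np.linalg.inv(scale), lower=True)
    A = np.zeros((K, K))
    for i in range(K):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.normal()
    LA = L_inv_scale @ A
    W = LA @ LA.T
    return np.linalg.inv(W)


def _truncnorm_draw(rng, mean, sd, positive: np.ndarray) -> np.ndarray:
    """Vectorised one-sided truncated normal at 0 via inverse CDF."""
    a = ndtr(-mean / sd)  # P(X <= 0)
    u = rng.uniform(size=mean.shape)
    p = np.where(positive, a + u * (1.0 - a), u * a)
    p = np.clip(p, _PTAIL, 1.0 - _PTAIL)
    return mean + sd * ndtri(p)


def _auto_scales(Z0: np.ndarray, j_idx: np.ndarray, J: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments diagonal scale matrices for the inverse-Wishart
    priors: within-provider variances for Omega, the excess variance of
    provider means (floored at a small fraction of the sampling noise) for
    Sigma. Computed from the initialised latent matrix, so probit
    dimensions contribute on their +-0.5 coding — the right order of
    magnitude for a unit-variance latent scale."""
    N, K = Z0.shape
    n_per = np.bincount(j_idx, minlength=J).astype(float)
    n_per_safe = np.maximum(n_per, 1.0)
    means = np.zeros((J, K))
    for k in range(K):
        means[:, k] = np.bincount(j_idx, weights=Z0[:, k], minlength=J) / n_per_safe
    resid = Z0 - means[j_idx]
    within = np.maximum(resid.var(axis=0) * N / max(N - J, 1), 1e-8)
    nbar = N / J
    if J > 1:
        between = np.maximum(means.var(axis=0, ddof=1) - within / nbar,
                             1e-3 * within)
    else:
        between = 1e-3 * within
    return np.diag(between), np.diag(within)


def run_gibbs(
    *,
    Z0: np.ndarray,            # N x K initial latent matrix (no NaNs)
    obs_mask: np.ndarray,      # N x K, True where the outcome cell is observed
    is_probit: np.ndarray,     # K bools
    ybin: np.ndarray,          # N x K, binary outcome (only read on probit cells)
    X_list: list[np.ndarray],  # per-dim design matrices, intercept first
    j_idx: np.ndarray,         # N provider codes in 0..J-1
    J: int,
    settings: McmcSettings,
) -> dict:
    """Run the chain and return stacked post-burn-in draws."""
    rng = np.random.default_rng(settings.seed)
    N, K = Z0.shape
    v0 = settings.coef_prior_var
    nu0 = K + settings.wishart_extra_df
    if settings.wishart_scale == "auto":
        S0_sigma, S0_omega = _auto_scales(Z0, j_idx, J)
    else:
        S0_sigma = S0_omega = float(settings.wishart_scale) * np.eye(K)

    Z = Z0.copy()
    gamma = []
    XtX = []
    for k in range(K):
        X = X_list[k]
        XtX.append(X.T @ X)
        g, *_ = np.linalg.lstsq(X + 0.0, Z[:, k], rcond=None)
        gamma.append(g)
    theta = np.zeros((J, K))
    Sigma = 0.01 * np.eye(K)
    Omega = np.eye(K)
    n_per = np.bincount(j_idx, minlength=J)

    Xg = np.column_stack([X_list[k] @ gamma[k] for k in range(K)])
    mu = Xg + theta[j_idx]

    probit_any = is_probit.any()
    update_cell = (~obs_mask) | (is_probit[None, :] & obs_mask)  # cells to redraw
    pos = ybin > 0.5

    M = settings.n_draws
    out = {
        "alpha": np.empty((M, K)),
        "beta": [np.empty((M, len(gamma[k]))) for k in range(K)],
        "Sigma": np.empty((M, K, K)),
        "Omega": np.empty((M, K, K)),
        "theta": np.empty((M, J, K)),
    }
    m = 0

    others = [np.array([i for i in range(K) if i != k]) for k in range(K)]

    for it in range(settings.iterations):
        # --- conditional regression pieces of Omega, recomputed once per sweep
        g_cond = []
        v_cond = []
        for k in range(K):
            o = others[k]
            if K == 1:
                g_cond.append(np.zeros(0))
                v_cond.append(Omega[0, 0])
            else:
                gk = np.linalg.solve(Omega[np.ix_(o, o)], Omega[o, k])
                g_cond.append(gk)
                v_cond.append(float(Omega[k, k] - Omega[k, o] @ gk))

        # --- 1. latent data: truncate probit cells, impute missing cells
        if probit_any or (~obs_mask).any():
            for k in range(K):
                sel = update_cell[:, k]
                if not sel.any():
                    continue
                o = others[k]
                E = Z - mu
                cmean = mu[:, k] + (E[:, o] @ g_cond[k] if K > 1 else 0.0)
                sd = np.sqrt(v_cond[k])
                trunc = sel & obs_mask[:, k]  # observed probit cells
                free = sel & ~obs_mask[:, k]  # missing cells, any family
                if trunc.any():
                    Z[trunc, k] = _truncnorm_draw(rng, cmean[trunc], sd, pos[trunc, k])
                if free.any():
                    Z[free, k] = cmean[free] + sd * rng.standard_normal(free.sum())

        # --- 2. regression coefficients, dimension by dimension
        for k in range(K):
            o = others[k]
            E = Z - mu
            adj = E[:, o] @ g_cond[k] if K > 1 else 0.0
            t = Z[:, k] - theta[j_idx, k] - adj
            prec = XtX[k] / v_cond[k] + np.eye(len(gamma[k])) / v0
            c, low = cho_factor(prec)
            mean = cho_solve((c, low), X_list[k].T @ t / v_cond[k])
            L = cholesky(prec, lower=True)
            gamma[k] = mean + solve_triangular(
                L.T, rng.standard_normal(len(mean)), lower=False
            )
            Xg[:, k] = X_list[k] @ gamma[k]
            mu[:, k] = Xg[:, k] + theta[j_idx, k]

        # --- 3. provider effects
        R = Z - Xg  # theta_{j(i)} + eps_i
        rsum = np.empty((J, K))
        for k in range(K):
            rsum[:, k] = np.bincount(j_idx, weights=R[:, k], minlength=J)
        Oinv = np.linalg.inv(Omega)
        Sinv = np.linalg.inv(Sigma)
        b = rsum @ Oinv.T
        for n in np.unique(n_per):
            grp = np.where(n_per == n)[0]
            if n == 0:
                cov = Sigma
                means = np.zeros((len(grp), K))
            else:
                A = Sinv + n * Oinv
                cov = np.linalg.inv(A)
                means = b[grp] @ cov.T
            Lc = cholesky(cov + 1e-12 * np.eye(K), lower=True)
            theta[grp] = means + rng.standard_normal((len(grp), K)) @ Lc.T
        mu = Xg + theta[j_idx]

        # --- 3b. redundant-multiplier (scale interweaving) move: draw one
        # expansion factor per dimension by GLS regression of the residuals
        # on the current provider effects, then rescale theta and Sigma.
        # Moves the random-effect scales with likelihood information and
        # breaks the slow theta-Sigma random walk that otherwise cripples
        # weakly identified variances (e.g. rare binary outcomes).
        Mth = (theta.T * n_per) @ theta            # sum_i theta_ik theta_il
        Cth = theta.T @ rsum                       # sum_i theta_ik R_il
        P_a = Oinv * Mth + np.eye(K) / 100.0       # mild N(0,10^2) prior on a
        rhs_a = (Oinv * Cth).sum(axis=1)
        cov_a = np.linalg.inv(P_a)
        La = cholesky(0.5 * (cov_a + cov_a.T) + 1e-14 * np.eye(K), lower=True)
        a = cov_a @ rhs_a + La @ rng.standard_normal(K)
        theta *= a[None, :]
        Sigma = Sigma * np.outer(a, a)
        Sinv = np.linalg.inv(Sigma)
        mu = Xg + theta[j_idx]

        # --- 4. translation (interweaving) move between alpha and mean(theta)
        alpha = np.array([gamma[k][0] for k in range(K)])
        prec_d = J * Sinv + np.eye(K) / v0
        mean_d = np.linalg.solve(prec_d, Sinv @ (J * theta.mean(axis=0)) - alpha / v0)
        Ld = cholesky(np.linalg.inv(prec_d) + 1e-14 * np.eye(K), lower=True)
        delta = (mean_d + Ld @ rng.standard_normal(K)
                 if not _DISABLE_TRANSLATION else np.zeros(K))
        theta -= delta[None, :]
        for k in range(K):
            gamma[k][0] += delta[k]
            Xg[:, k] += delta[k]
        # mu unchanged: alpha + theta shift cancels

        # --- 5. provider-level covariance
        Sigma = _rinvwishart(rng, nu0 + J, S0_sigma + theta.T @ theta)

        # --- 6. patient-level covariance with parameter-expansion rescale
        E = Z - mu
        Omega_u = _rinvwishart(rng, nu0 + N, S0_omega + E.T @ E)
        d = np.where(is_probit, np.sqrt(np.diag(Omega_u)), 1.0)
        Omega = Omega_u / np.outer(d, d)
        if probit_any:
            Z /= d[None, :]
            Xg /= d[None, :]
            theta /= d[None, :]
            for k in range(K):
                gamma[k] = gamma[k] / d[k]
            Sigma = Sigma / np.outer(d, d)
            mu = Xg + theta[j_idx]

        # --- store
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            out["alpha"][m] = [gamma[k][0] for k in range(K)]
            for k in range(K):
                out["beta"][k][m] = gamma[k]
            out["Sigma"][m] = Sigma
            out["Omega"][m] = Omega
            out["theta"][m] = theta
            m += 1

    assert m == M
    return out
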