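# Methods

## The problem

Public-sector providers (the running example is hospitals performing
elective hip replacement) are judged on several outcomes at once —
inpatient length of stay, waiting time beyond a target, short-term
readmission, patient-reported health gain. Stakeholders rarely agree on
weights for these dimensions, so a composite score is not defensible. The
approach implemented here makes only a sign assumption (each dimension can
be oriented so that more is better) and classifies each provider against a
benchmark as **dominant** (better on every dimension), **dominated** (worse
on every dimension) or **non-comparable** (better on some, worse on
others), with posterior probabilities attached to each classification.

## Model

For patient `i = 1..n_j` in provider `j = 1..J` and dimension `k = 1..K`:

    Y*_ijk = alpha_k + X'_ijk beta_k + theta_jk + eps_ijk

* Continuous dimensions observe `Y = f^{-1}(Y*)` for a monotone transform
  `f` chosen so a Gaussian error is defensible (default `log1p` for the
  skewed length-of-stay dimension, identity for the health score).
* Binary dimensions observe `I(Y* > 0)` (probit); their error variance is
  fixed at 1 for identification.
* `theta_j ~ MVN(0, Sigma)` across providers, `eps_i ~ MVN(0, Omega)`
  across patients; both matrices are dense, so performance dimensions may
  be correlated at either level. `Sigma = diag(tau) R_theta diag(tau)`;
  `Omega` carries the residual SDs `sigma_k` (1 on probit dimensions) and
  the patient-level correlations.
* Covariate sets may differ by dimension (risk adjustment); the waiting
  dimension deliberately carries none, since waiting-list management is
  part of what is being judged.

## Estimation

The sampler is a Gibbs scheme with data augmentation:

1. **Latent probit values** are drawn from one-sided truncated normals
   with the conditional mean/variance given the other dimensions' current
   residuals.
2. **Missing outcome cells** (any family) are drawn from the conditional
   normal given the observed dimensions — the missing-at-random assumption
   conditions on modelled covariates *and* observed performance.
3. **Coefficients** `(alpha_k, beta_k)` update dimension-by-dimension via
   seemingly-unrelated-regression conditionals.
4. **Provider effects** `theta_j` have conjugate MVN conditionals with
   precision `Sigma^-1 + n_j Omega^-1`.
5. **Sigma** and **Omega** update by inverse-Wishart; `Omega` is drawn
   unconstrained and rescaled to unit probit variances (parameter
   expansion), with the latent data, coefficients, provider effects and
   `Sigma` rescaled in the same move.

Two interweaving (ancillarity–sufficiency) moves are essential for mixing
and are always on:

* a **translation move** exchanging mass between `alpha` and the mean of
  `theta` (otherwise their sum is well identified but the split mixes at a
  crawl), and
* a **redundant-multiplier scale move**: one expansion factor per
  dimension is drawn by GLS regression of the residuals on the current
  provider effects, then `theta` and `Sigma` are rescaled. Without it the
  provider variance of a rare binary dimension (readmission at a 5% event
  rate has ~5 events per provider at `n_j = 100`) shows split-R-hat above
  1.6 at any feasible chain length; with it, chains of ~1500 iterations
  behave. During development the univariate probit fit was cross-checked
  against `lme4::glmer` (probit, adaptive quadrature) on identical data;
  the posterior covers the MLE.

Priors: coefficients `N(0, 10^4)`; `Sigma`, `Omega` inverse-Wishart with
`K + 2` degrees of freedom. The default scale matrix is **data-scaled**
("auto"): a diagonal method-of-moments estimate of each level's variances,
i.e. roughly one pseudo-observation at the data's own scale. A fixed
near-zero scale is *not* weakly informative for variance parameters — it
concentrates prior mass near zero and visibly crushes `Sigma` when `J` is
small — which is why the constant-scale option exists but is not the
default.

Convergence is summarised by split-R-hat over the scalar parameters
(intercepts, SDs, correlations), gated at 1.05; the pipeline can be told
to refuse classification on an unconverged fit.

`theta_hat_j` (posterior mean of the retained `theta_j` draws) and `V_j`
(their covariance) are the Empirical Bayes provider summaries consumed by
the classification stage.

## Classification

The benchmark is the conditional mean — a hypothetical provider of average
performance (`theta* = 0`) — or an absolute `theta*`. Each dimension is
oriented by its `orientation` (+1 higher-better, −1 lower-better). For
provider `j`, `S` draws are taken from `MVN(theta_hat_j, V_j)` (or
resampled from the MCMC draws) and

    Pr(dominant)  = fraction of draws better than the benchmark on all K,
    Pr(dominated) = fraction worse on all K,
    Pr(non-comparable) = the remainder (exact by construction).

Ties at exactly zero count against the strict inequalities (a
measure-zero convention). Labels are assigned at thresholds in
`[0.5, 1]`; the bottom of the customary grid is 0.50 and the dominant
condition is checked first there. A deterministic orthant-probability
oracle (Genz-type MVN CDF, `K <= 6`, ~1e-5 accuracy) backs the simulation
in tests; the bivariate zero-mean case has the closed form
`1/4 + arcsin(rho)/(2*pi)`.

Two reduced approaches are provided for comparison, both "confidence box"
rules on per-dimension one-sided probabilities
`p_k = Phi(orient_k (theta_hat_k - theta*_k)/sqrt(V_kk))`, with a
Bonferroni cut `1 - (1 - Pr*)/K` (the correction's exact arithmetic is a
package choice): the **univariate** approach computes `p_k` from separate
K=1 fits; the **intermediate** approach computes them from the joint fit
but ignores the posterior correlation. By the Bonferroni inequality a
box-dominant provider is always joint-dominant, so the full approach's
dominant/dominated sets contain the intermediate ones by construction;
containment of the univariate sets in the intermediate sets is an
efficiency phenomenon (univariate fits have larger `V_kk` when dimensions
are correlated) and holds on the default, positively correlated cohort.

## Selection correction (2SRI)

Patients choose providers; unobserved severity can drive both the choice
and the outcomes. The instrument is the distance from the patient to each
provider: a conditional logit over distance, distance², distance³ and a
closest-provider indicator (providers under a volume floor — default 30
patients — leave every choice set, and their patients are dropped with a
logged count). The polynomial is computed on centred distance for
conditioning and mapped back to raw-scale coefficients. The generalised
first-stage residual `r_i = 1 - p_hat(chosen)` — one scalar per patient,
a documented convention since the first stage admits several residual
definitions — enters every dimension of a refit; the K residual
coefficients get a posterior Wald test on K degrees of freedom. The Wald
analogue is built from posterior means and covariances, so its null
behaviour is approximate; in the packaged size experiment it is
conservative (rejections at or below the nominal 5%).

## Synthetic cohorts

The generator draws from exactly the estimation model, so every
downstream stage is testable without restricted data. Defaults emulate
the hip-replacement setting:

| dimension | family | transform | orientation | alpha | tau | sigma |
|---|---|---|---|---|---|---|
| los | gaussian | log1p | −1 | 1.80 | 0.12 | 0.45 |
| ohs_post | gaussian | identity | +1 | 38.5 | 1.2 | 8.8 |
| wait_over_18wk | probit | — | −1 | calibrated to rate 0.17 | 0.25 | 1 |
| readmit_28d | probit | — | −1 | calibrated to rate 0.05 | 0.20 | 1 |

Probit intercepts solve `Phi(alpha/sqrt(1 + tau^2)) = rate`. Provider- and
patient-level correlation matrices follow the published profiling
estimates (e.g. −0.34 between length of stay and health score at provider
level); on the oriented scale all pairs are positive. Covariates: a
standard-normal pre-operative severity score, male ~ Bernoulli(0.41), a
uniform deprivation index; continuous covariates are mean-centred.
Missingness defaults: 15.2% (health score), 4% (waiting), 0.1% (length of
stay), 0 (readmission); MCAR by default, or MAR with a logistic link to a
named covariate whose intercept is calibrated to hold the marginal rate.
Optional top-coding at the 99th percentile reproduces the right-tail
truncation of recorded length of stay.

For selection experiments, providers sit at fixed uniform sites on the
unit square and patients at uniform points; choice follows the
conditional logit with utility
`g1*exp(-lam*c_i)*d + g2*d^2 + g3*d^3 + delta*closest`, where
`c_i ~ N(0,1)` is the unobserved severity: with `lam > 0` severe patients
are less distance-sensitive, so their choices deviate from what distance
predicts and the generalised residual tracks `c_i` (correlation ≈ 0.4 at
`lam = 0.8`). The same `c_i` loads on every outcome error
(default −orientation·0.5·sigma_k: severity hurts every dimension). This
mechanism was chosen over a per-provider "attractiveness" loading
because the latter leaves the scalar residual nearly orthogonal to the
confounder — a correction method cannot be demonstrated on data whose
confounding its residual cannot see.

What the generator does **not** emulate: record linkage, coding systems,
survey non-response that depends on the outcome (missingness is MCAR/MAR
by construction), patient covariate distributions beyond the three
defaults, and cream-skimming by providers. Passing tests therefore say
the method works under its own assumptions at realistic parameter values,
not that those assumptions hold in any particular administrative dataset.

## Numerical choices

* Truncated-normal draws by inverse CDF with probabilities clipped at
  1e-14.
* Posterior covariances are eigenvalue-clipped (warning if materially
  non-PSD) before Cholesky.
* `S = 10,000` dominance simulations by default; the Monte-Carlo SE
  (~0.005 at p = 0.5) is reported alongside.
* Sub-seeding: every pipeline stage derives its seed from the master seed
  via `SeedSequence(master, spawn_key=(stage,))`; runs are byte-identical
  given the master seed.
* Degenerate inputs: all-missing dimensions, constant residual columns,
  non-PSD correlation inputs and empty choice sets are rejected with
  named diagnostics rather than propagated.

## Test problem sizes

The packaged studies are sized for a single CPU: parameter recovery uses
10 replicates of the J=100, n_j=100 benchmark with 1200-iteration chains
(pooled 95% credible-interval coverage across all generating parameters
is the calibration check); the classification power study pins 10% of a
J=40 cohort at +2·tau with n_j=400; selection experiments use J=25,
n_j=100 (bias reduction) and J=15, n_j=60 (null size). Larger sizes
sharpen all of these but change no conclusion.

## Known limitations

* The conditional-mean benchmark is itself estimated from the cohort: if
  many providers are genuinely excellent, the standard moves with them
  and individual margins shrink. This is a property of relative
  benchmarking, visible in the power experiments when a large fraction of
  providers is pinned above the mean.
* Provider variances of rare binary dimensions are weakly identified at
  realistic event counts; posteriors are honest about this (wide, mildly
  skewed toward zero) but short chains can under-disperse them.
* Uncertainty in correlation significance is summarised by posterior SDs
  and credible intervals, not by sandwich standard errors; with
  frequentist fits the flagged entries could differ at the margin.
* The 2SRI residual is one convention among several; the joint test's
  chi-square reference is asymptotic and the posterior-Wald version runs
  conservative.
* Dominance with bounds on marginal rates of substitution (cone-restricted
  rather than orthant-restricted) is out of scope, as are survival/count
  outcome families and multiple imputation for covariate missingness.
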