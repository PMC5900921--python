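# domprof

Multidimensional performance assessment of providers (hospitals, schools,
police forces …) using **dominance criteria**: estimate a multivariate
multilevel model over correlated performance dimensions, obtain Empirical
Bayes posteriors of each provider's effect vector, and classify every
provider against a benchmark as **dominant**, **dominated** or
**non-comparable** with posterior probabilities attached.

## Who this is for

Analysts profiling institutions on several outcomes at once — e.g. length
of stay, waiting time beyond a target, 28-day readmission, and
patient-reported health gain after elective surgery — when stakeholders
cannot agree on weights to collapse those outcomes into one score. The
only preference assumption used is the *sign* of each dimension (more is
better, or less is better).

## The model

For patient `i` in provider `j` and dimension `k = 1..K`:

```
Y*_ijk = α_k + X'_ijk β_k + θ_jk + ε_ijk
θ_j  ~ MVN(0, Σ)      (provider level,  Σ = diag(τ) R_θ diag(τ))
ε_i  ~ MVN(0, Ω)      (patient level; var fixed at 1 on probit dims)
```

Continuous dimensions observe a monotone transform of `Y*`; binary
dimensions observe `I(Y* > 0)` (probit). Both covariance matrices are
dense, so dimensions can be correlated at both levels; covariate sets may
differ per dimension; missing outcome cells are handled by augmentation
(MAR given covariates and observed dimensions). Estimation is a Gibbs
sampler with truncated-normal probit augmentation and parameter-expansion
identification — see `docs/methods.md`.

For provider `j`, the posterior mean `θ̂_j` and covariance `V_j` feed the
classification: with `S` draws from `MVN(θ̂_j, V_j)`, oriented so every
coordinate is higher-is-better and centred at the benchmark `θ*`,

```
Pr(dominant | j)   = (1/S) Σ_s Π_k 1(θ_jks > 0)
Pr(dominated | j)  = (1/S) Σ_s Π_k 1(θ_jks < 0)
Pr(non-comp. | j)  = 1 − Pr(dominant|j) − Pr(dominated|j)
```

These are orthant probabilities of the joint posterior — unlike a
"confidence box" of K separate intervals, they respect the posterior
correlation between dimensions. A two-stage residual-inclusion (2SRI)
correction for endogenous provider choice, instrumented by patient–provider
distance through a conditional logit, is included, as is a synthetic-cohort
generator that reproduces the whole data structure (mixed outcome
families, both correlation levels, missingness, distance-driven choice
with an unobserved severity confounder).

## Worked example

```python
import numpy as np
from domprof import (ModelSpec, McmcSettings, MultivariateMultilevelModel,
                     assess_providers, default_config, simulate)

cfg = default_config(J=60, n_j=100, seed=4)    # study-like synthetic cohort
ds = simulate(cfg)
model = MultivariateMultilevelModel.from_dataframe(
    ds.patients, ModelSpec(dimensions=cfg.dimensions))
res = model.fit(McmcSettings(iterations=1500, burn_in=600, seed=5))
print(res.correlation_matrix("provider").to_frame().round(2))

tab = assess_providers(res, S=10_000, seed=6, thresholds=(0.8, 0.9))
print(tab[["provider_id", "p_dominant", "p_dominated",
           "p_noncomparable", "label@0.9"]].head(6).round(3))
```

Output (as printed by this example):

```
                 los  ohs_post  wait_over_18wk  readmit_28d
los             1.00     -0.03            0.40         0.13
ohs_post       -0.03      1.00           -0.58        -0.80
wait_over_18wk  0.40     -0.58            1.00         0.76
readmit_28d     0.13     -0.80            0.76         1.00
   provider_id  p_dominant  p_dominated  p_noncomparable     label@0.9
0            0       0.301        0.008            0.691  unclassified
1            1       0.090        0.019            0.890  unclassified
2            2       0.070        0.157            0.773  unclassified
3            3       0.081        0.051            0.868  unclassified
4            4       0.000        0.995            0.005     dominated
5            5       0.030        0.014            0.956  unclassified
```

The correlation matrix is the posterior mean of the provider-level
correlations between dimensions (`los` = length of stay on a log1p scale,
lower better; `ohs_post` = post-operative health score, higher better;
the two probit dimensions are waiting beyond 18 weeks and 28-day
readmission, event = worse). The per-provider table gives the posterior
probability that the provider is better than an average provider on *all*
dimensions simultaneously (`p_dominant`), worse on all (`p_dominated`),
or mixed (`p_noncomparable`); `label@0.9` applies the 90% threshold.

The same pipeline runs from the shell:

```bash
domprof run --out results_run --seed 4 -J 30 -n 80 --iterations 1000 --burn-in 400
domprof simulate --out cohort -J 50 -n 100 --seed 1
```

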