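# flexjm

Flexible joint models for a continuous longitudinal outcome and a
discrete time-to-event outcome, with **individual-level penalized
splines** (truncated linear basis) shared between the two processes.

The follow-up window is partitioned into `M` intervals whose boundaries
double as spline knots. Each subject's longitudinal trajectory is a
continuous piecewise-linear curve, `m_i(t) = sum_l (beta_l + b_il) B_l(t)`,
with population coefficients `beta` and random coefficients `b_i`. The
discrete hazard of the event in interval `r` is a probit model whose
linear predictor includes the trajectory's intercept and slope at the
start of the interval, so the same random coefficients drive both
processes. Key properties:

* **Exact likelihood.** Each subject's marginal likelihood is available
  in closed form: Gaussian conjugacy for the longitudinal part plus a
  single K-dimensional multivariate-normal CDF for the survival part —
  no quadrature over the random effects.
* **Data-driven smoothness.** The population spline is shrunk by a
  quadratic penalty with smoothing parameter `lambda` chosen by AIC
  using effective degrees of freedom `df(lambda)`; the individual-level
  smoothness is governed by the variance `sigma2^2`, estimated by
  maximum likelihood.
* **MCMC-free dynamic prediction.** Conditioning the random coefficients
  on a subject's history and survival status yields a multivariate
  skew-normal posterior that is sampled exactly via a truncated latent
  Gaussian; conditional survival probabilities at later intervals are
  then plugged in.
* **Comparator methods** (shared plumbing, for simulation studies):
  a probit survival model with last-observation-carried-forward as a
  time-varying covariate, a two-stage approach (longitudinal-only fit +
  empirical Bayes plug-in), a random intercept + slope joint model, and
  a gold-standard predictor from the simulated truth.
* **Generative simulator** that emulates a long HIV-cohort design
  (12 intervals, one scheduled visit per interval, event and dropout
  censoring), an 8-interval scaled version of it for method-comparison
  studies, and a compact 5-interval scenario for fast runs.

## Command-line usage

```bash
# simulate a dataset (writes long.csv, surv.csv, truth.csv, config.yaml)
flexjm simulate --scenario demo -n 300 --seed 1 -o data/

# fit the joint model at a fixed smoothing value
flexjm fit -c data/config.yaml --long data/long.csv --surv data/surv.csv \
    --lam 0.4 -o fit.json

# AIC grid search over the configured lambda grid
flexjm select-lambda -c data/config.yaml --long data/long.csv \
    --surv data/surv.csv -o lambda_table.csv

# dynamic predictions for subjects at risk at interval r
flexjm predict -c data/config.yaml --fit fit.json --long data/long.csv \
    --surv data/surv.csv -r 3 --horizons 1,2,3 --seed 1 -o preds.csv

# simulation study: all methods vs the gold standard
flexjm compare --scenario demo --replicates 5 --seed 1 -o compare.csv
```

### File formats

Longitudinal CSV: `id,time,y,<covariates...>` (time in original units).
Survival CSV: `id,s_star,delta,<baseline covariates...>`, where `s_star`
is the observed interval (1-based) and `delta` is 1 for an event, 0 for
censoring. A censored subject with `s_star = s` is assumed to have
survived through interval `s`. The YAML config names the partition
boundaries (original units), the time scale, the survival design terms
(`1`, `rstart`, `rstart^2`, baseline column names, optional
standardization) and the association structure.

## Package layout

| module | contents |
| --- | --- |
| `flexjm.timegrid` | time partition, truncated linear basis, intercept/slope maps |
| `flexjm.data` | dataset containers, CSV/YAML I/O, parameter transforms |
| `flexjm.likelihood` | closed-form subject likelihood, batched whole-dataset core |
| `flexjm.estimation` | penalized ML, observed-information SEs, `df(lambda)`, AIC |
| `flexjm.prediction` | skew-normal posterior, exact sampler, survival predictions |
| `flexjm.simulate` | generative simulator and ready-made scenarios |
| `flexjm.comparators` | benchmark methods and the prediction-error evaluator |
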