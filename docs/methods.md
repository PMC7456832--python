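# Methods

## Structural model and estimands

Data are generated from a linear structural model for a randomized binary
treatment `X`, two measured confounders `C1, C2`, an unmeasured standard
normal confounder `U`, a continuous mediator `M` and continuous outcome `Y`:

```
C1 = g·X + k·U + e3        C2 = h·X + n·U + e4
M  = a·X + d·C1 + f·C2 + e1
Y  = c′·X + b·M + t·U + e2
```

`U` and `e1..e4` are independent standard normal. `C1` and `C2` confound the
`M → Y` relation (they predict `M` directly and `Y` through `U`); when
`g, h ≠ 0` they are post-treatment confounders, the hard case: adjusting for
them (or for `M`) conditions on a collider on the path `X → C → U → Y` and
biases the direct-effect estimate. The latent paths default to
`k = n = t = 1`.

Estimands, by path tracing: controlled direct effect `CDE = c′` (no `X·M`
interaction anywhere in the model), total effect `c = c′ + b(a + dg + fh)`,
and the indirect effect as their difference, `b(a + dg + fh)`, which reduces
to the familiar product `a·b` when `g = h = 0`. All estimators report the
indirect effect as `ĉ − ĉ′` with a shared unadjusted `ĉ` (the OLS slope of
`Y` on `X`, valid under randomization), so methods differ only through `ĉ′`.

Assumptions the estimators rely on: randomized `X`, linear
homoscedastic-normal models, no `X·M` interaction, and — for consistency —
that the measured confounders entering a given model close all back-door
paths for `M → Y`. The simulation's purpose is precisely to measure what
happens when the last assumption fails.

## Estimators

* **Regression with adjustment**: OLS `Y ~ 1 + X + M + C`; `ĉ′` is the `X`
  coefficient.
* **IPW**: stabilized weights `w_i = φ(M_i | X_i) / φ(M_i | X_i, C_i)`; each
  conditional density is normal with mean the OLS fitted value and SD the
  residual standard error `sqrt(RSS/(n−p))` of that mediator regression.
  The weighted outcome model contains `X` and `M` only — confounder
  adjustment happens entirely through the weights. The treatment-only
  numerator stabilizes the weights (mean → 1 under correct specification)
  without changing the estimand. A binary-mediator analogue uses logistic
  fitted probabilities (`P[M=1|X]/P[M=1|X,C]` for `M = 1`, complement ratio
  for `M = 0`); the simulation study itself uses the continuous form.
* **IPW-truncated**: identical, with weights winsorized at the 1st and 99th
  empirical percentiles of the current weight vector.
* **Sequential g-estimation**: Q-model OLS `Y ~ 1 + X + M + C` gives `β_M`;
  the residualized outcome `Y − β_M·M` is regressed on `X` alone, and its
  slope `ψ` estimates the CDE. Step 2 includes no covariates because `X` is
  randomized; baseline covariates would be admissible there, post-treatment
  ones would not.
* **Doubly robust sequential g-estimation**: the Q-model is fitted by WLS
  with untruncated mediator-propensity weights, then step 2 as above,
  unweighted. Misspecification variants omit one confounder from the
  propensity model only, the Q-model only, or both. Whether the final stage
  should also be weighted is ambiguous in the method's verbal descriptions;
  the unweighted reading is implemented because the weights' job — making
  `M` ignorable inside the outcome regression — is done in the Q-model, and
  step 2 is a regression on randomized `X` only. The choice is isolated in
  `sequential_g_direct(weights=...)`.

Unit-weight reductions hold exactly and are tested: IPW with unit weights is
the unadjusted OLS of `Y` on `X, M`; DR with unit weights is sequential g.
With no confounders modeled anywhere, product-of-coefficients,
difference-in-coefficients and sequential g coincide to machine precision
(an OLS identity), which anchors the implementations algebraically.

## Inference

Percentile bootstrap: `B` with-replacement resamples of whole records; the
full pipeline (propensity fits, truncation caps, `β_M`, total effect) is
refitted per resample, so the interval reflects nuisance-estimation
uncertainty — the reason analytic standard errors for `ψ` are biased.
Interval endpoints use the symmetric nearest-rank rule: with
`k = ⌈(1−level)/2 · B⌉`, the `k`-th and `(B+1−k)`-th smallest resampled
estimates (ranks 25 and 976 at `B = 1000`, level 0.95). Resamples containing
a single treatment arm are redrawn, up to 100 times. Defaults: `B = 1000`,
level 0.95.

## Monte Carlo study

The reference factorial design crosses `a ∈ {0.14, 0.39, 0.59}`,
`b, c′ ∈ {0, 0.14, 0.59}`, `d = f ∈ {0.14, 0.39, 0.59}` and
`g = h ∈ {0, 0.14, 0.59}` — 243 conditions at n = 500 — plus 12
opposite-sign conditions (six `(d, f)` sign pairs × `b ∈ {0, 0.59}`, with
`a = 0.59`, `c′ = 0`, `g = h = d`) and a zero-confounding calibration
condition on which every method must be unbiased. Each condition is
replicated (R = 1000 by default; the packaged checks use R = 500 and the
mini-study example R = 200) and summarized per estimation model.

Metrics: `bias = mean(θ̂) − θ`; `MSE = mean((θ̂ − θ)²)`, i.e. about the
truth, equal to variance-about-mean (1/R normalization) plus squared bias —
the verbal definition of MSE, which conflicts with a variance-only reading
of the same quantity; both are emitted (`mse`, `var_estimates`) so either
can be inspected. Relative bias is `100·bias/θ`, undefined (NaN) at `θ = 0`;
10% absolute relative bias is used as the acceptability bound. CI coverage
is reported when the bootstrap is enabled (off by default in bias/MSE runs,
which do not need it).

Reproducibility: every replication's generator seed derives from
`SeedSequence([master_seed, condition_index, replication_index])`, so
summaries are independent of execution order and identical runs are
byte-identical.

## Numerical and design choices

* Treatment allocation is `P(X=1) = 0.5` and all intercepts are 0; error
  and latent-confounder variances are 1. These are assumptions — the
  generating model's description leaves them open.
* All regression stages use dense least squares (`numpy.linalg.lstsq`) on
  explicit design matrices; rank deficiency raises a degenerate-design
  error rather than silently pseudo-inverting. Tests cross-check every fit
  against statsmodels OLS/WLS.
* Weight truncation uses nearest-rank percentiles (value at rank
  `⌈p/100·n⌉`) computed from the current weight vector, never pooled across
  replications or bootstrap resamples; truncation is idempotent and order
  preserving. A mediator-model residual SD at rounding-error scale raises a
  degenerate-model error (the density ratio would be 0/0); non-finite or
  non-positive weights are refused with the offending record named.
* Failed replications (degenerate weights, single-arm datasets) are logged
  with their seed, excluded, and counted in `n_failed` instead of aborting a
  long factorial run.
* The demo scenario uses `a = b = d = f = g = h = 0.59, c′ = 0`, the
  coefficient set whose path-traced indirect effect equals the tabled true
  value 0.759; the coefficients are user-overridable.

## What the generator does and does not emulate

It emulates randomized assignment, linear confounded mediation with normal
errors, and both baseline and treatment-dependent confounding — the
conditions under which the estimators' consistency claims can be verified
exactly. It does not emulate non-normal or heteroscedastic errors, binary
or skewed mediators, `X·M` interactions, nonlinear links, missing data, or
more than two measured confounders. Passing tests therefore certify the
estimators' behavior under the linear-normal model, not robustness to those
departures on real data.

## Known limitations

* Only the CDE-based indirect effect (total minus direct) is estimated;
  natural direct/indirect effects are out of scope (they coincide with the
  CDE decomposition here only because the model has no `X·M` interaction).
* IPW assumes a correctly specified normal mediator density; heavy-tailed
  true weights make the stabilized-weight sample mean converge slowly, and
  truncation trades that variance for bias.
* A doubly robust estimator with exactly one component model misspecified
  remains consistent; empirical claims that *every* misspecified model is
  badly biased cannot and do not reproduce for those variants (the
  both-misspecified variant is the one that fails, and does).
* Figure-level findings are reproduced as orderings and threshold checks,
  not point values.
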