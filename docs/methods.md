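# Methods

## The estimation problem

Repeated biomarker measurements `Y_ij` (subject `i`, visit `j` at time
`t_ij` years) are modelled together with a right-censored event time
`T*_i = min(T_i, C_i)`, `δ_i = 1{T_i ≤ C_i}`. Two latent per-subject
quantities drive the analysis: the *usual level* `b0_i` (the subject's
underlying average) and the *visit-to-visit variability* `σ_i`, a
subject-specific residual SD. The scientific question is the association
of each with the hazard of the event, expressed as log hazard ratios
`α0` (per unit of usual level) and `ασ` (per unit of residual SD). No
distinction is made between true within-subject fluctuation and
measurement error; both contribute to `σ_i`.

## Models

**Location-scale mixed model.** `Y_ij = β'X_i (+β_t t_ij) + b0_i
(+b1_i t_ij) + ε_ij` with `ε_ij ~ N(0, σ_i²)` and `log σ_i` normal —
a log-normal law for `σ_i`, guaranteeing positivity and giving a natural
way to correlate level and variability through a joint multivariate
normal for `(b0_i[, b1_i], log σ_i)`. The four standard specifications
toggle the random slope and the level–variability correlation(s):
`lmm1` (intercept, uncorrelated), `lmm2` (intercept, correlated `ρ`),
`lmm3` (slope, only intercept–slope correlation), `lmm4` (slope, fully
unstructured). A time-constant covariate vector `X_i` may enter the mean;
covariates in the *scale* model (a linear predictor for `μσ,i`) are a
documented extension point, not implemented.

**Two-stage Cox.** Stage one estimates `U_i = (BP̂_i, BPSD̂_i)` either
naively (per-subject mean and SD) or as posterior means from the mixed
model; stage two maximises the Cox partial likelihood for
`h_i(t) = h0(t) exp(α'U_i + γ'W_i)`. Stage-one uncertainty is *not*
propagated — `U_i` is treated as fixed, mirroring field practice; the
simulation harness quantifies the consequences. When measurement
follow-up precedes survival follow-up, `separate_followup` splits the
data at `t_sep`: measurements in `[0, t_sep)` feed stage one, subjects
still at risk at `t_sep` enter stage two with the survival clock reset to
`t_sep` (a conditional-on-survival analysis with no left truncation).
Censored subjects whose follow-up ends before `t_sep` contribute nothing
after separation and are dropped.

**Joint model.** The same longitudinal submodel is linked to
`h_i(t) = h0(t) exp(α0 b0_i + ασ σ_i (+ α1 b1_i) + γ'W_i)` through the
latent quantities themselves. The residual SD enters on its natural
scale (mmHg), so `ασ` is directly comparable across all methods. The
baseline hazard is piecewise constant on `K` intervals whose interior
cutpoints sit at the `j/K` empirical quantiles (type-7 linear
interpolation) of the observed event times, with the final boundary at
the largest follow-up time and the last level extending beyond it, so the
cumulative hazard is an exact finite sum and the survival likelihood
needs no numerical integration. `K` counts *intervals* (default 15, i.e.
14 interior cutpoints) and requires at least `K` events.

## Posterior computation

Sampling is Metropolis-within-Gibbs over a *hierarchically centred*
parameterisation (the subject state carries the usual level itself, with
population mean `β'X_i`), which decorrelates fixed effects from random
effects and is the main reason short chains suffice:

* usual level (and slope): exact Gaussian full-conditional draws in the
  mixed model; in the joint model the same Gaussian is used as an
  independence proposal accepted with the survival-likelihood ratio
  (acceptance is near 1 because one subject's contribution to the hazard
  term is small);
* `log σ_i`: per-subject adaptive random-walk Metropolis, survival term
  included in the joint model;
* population means `(β, β_t, μσ)`: one conjugate Gaussian block;
* SDs and correlations `(τ0, τ1, τσ, ρ, …)`: per-coordinate adaptive
  random-walk Metropolis on the bivariate/trivariate normal likelihood,
  rejecting non-positive-definite proposals;
* baseline hazard levels `h0_k`: conditionally independent given the
  linear predictors; an independence proposal from the likelihood-shaped
  Gamma(d_k, R_k) (interval event count, exposure-weighted risk) is
  accepted with the diffuse-prior ratio, which is essentially 1;
* association coefficients `α`, `γ`: per-coordinate adaptive random
  walks. Internally the shared covariates are centred (constants fixed at
  data-driven values) to decorrelate `α` from the baseline levels; the
  reported `h0_k` are transformed back to the uncentred scale.

Priors (defaults, configurable): U[0, 100] on every SD, U[−1, 1] on every
correlation, N(0, 100²) on all location parameters including `log h0_k`.
Defaults for chains: burn-in 1000 (mixed) / 2000 (joint), 1000 retained
draws, thinning 1 / 4 — the joint association parameters are the
slowest-mixing quantities. Adaptation (Robbins–Monro tuning toward ~0.35
acceptance) runs during burn-in only. Two chains by default, with the
Brooks–Gelman corrected potential scale reduction factor
`R̂ = sqrt(((n−1)/n·W + (m+1)/(mn)·B)/W)` (floored at 1 so identical
chains give exactly 1) checked against a configurable threshold of 1.05;
exceedances produce a warning with per-parameter values, not an error.
Per-chain seeds derive deterministically from one master seed.

Degenerate inputs: subjects with a single measurement are legitimate in
the mixed/joint models (their `σ_i` is prior-driven); `τσ → 0` collapses
`log σ_i` to `μσ` and is handled with a small numerical floor (1e−6) on
SD proposals; proposals for `log σ_i` are clipped to ±40 to avoid
overflow in `exp`.

**Cox fitting** is Newton–Raphson with step-halving on the standardised
covariate scale, tolerance 1e−9 on the score norm, at most 50 iterations,
Efron's correction when event times are tied (tie-free data take a
vectorised cumulative-sum path; simulated event times are continuous so
ties have probability zero). Standard errors come from the inverse
observed information; 95% intervals are `estimate ± 1.96·SE`. A
standardised coefficient exceeding 10 triggers a monotone-likelihood
(perfect separation) error; a singular information matrix a collinearity
error. Agreement with an independent reference implementation is part of
the test suite (≤1e−6 in coefficients on tie-free data).

## The synthetic cohort generator

The generator emulates the structure of a large blood-pressure cohort:
`(b0_i, log σ_i)` bivariate normal with means (120, 2), SDs (15, 0.5) and
correlation ρ = 0.5 (positive level–variability correlation, as seen in
real cohorts); `Y_ij = b0_i + ε_ij`; event times Weibull proportional
hazards, `S(t) = exp(−λ t^k)` with `λ = exp(γ0 + α0 b0_i + ασ σ_i)`,
`γ0 = −10.26`, `k = 2`, `α0 = 0.02`, `ασ = 0.05`; administrative
censoring at 20 years. With this calibration the *median* subject
(`b0 = 120`, `σ = e²`) has exactly a 20% event probability by 20 years;
the marginal event fraction is ≈22% because the hazard is convex in the
latent quantities. Visits are scheduled equidistantly on [0, 18] years
including both endpoints. Scenario 1 keeps every scheduled measurement
(measurement follow-up effectively precedes survival follow-up);
Scenario 2 discards measurements at `t ≥ T_i` for subjects with events
(reading "following the event" as inclusive of the boundary), while
censored subjects keep all visits since censoring falls after the last
visit. Fixed seeds make generation bit-reproducible.

What the generator does *not* emulate: real visit-time irregularity and
missed visits, covariate effects on the mean trajectory, time trends
(slopes are zero in the generated truth), non-normal measurement error,
competing risks, and dependence of the visit process on health status
beyond termination by the event. Passing simulation benchmarks therefore
demonstrates correctness of the estimators under the stated data-generating
law, not robustness to these real-data features.

## Simulation harness and metrics

Each replicate simulates a fresh cohort (default 1500 subjects) and runs
the requested methods; per method the harness records the two estimated
log hazard ratios with 95% intervals (Wald intervals for Cox-based
methods, central posterior intervals for joint models). Aggregates are
the replicate mean, SD (n−1 divisor), RMSE (square root of the plain mean
squared error about the truth) and coverage. Replicates where a fit fails
are excluded for that method and counted. Replicates are independent with
seeds spawned deterministically from one master seed, so results do not
depend on execution order. The naive method in the harness uses the
sample SD (n−1 denominator), the convention of the stock statistical
software that produced the benchmark tables this package reproduces;
`naive_estimates` itself defaults to the population form (denominator
`n_i`) and exposes both. Subjects reduced to a single measurement by
Scenario-2 truncation are excluded from the naive stage (and hence that
replicate's naive Cox fit) with the count logged; the mixed and joint
models use all subjects. Scenario-2 two-stage fits use the truncated
streams directly — that is precisely the practice whose bias the harness
measures — while the `t_sep` separation is available for data where
measurement and survival follow-up can be divided.

Problem sizes: the Cox-only benchmarks (true-covariate and naive methods)
run at the study's full scale, 1000 replicates. The MCMC benchmarks
(two-stage `lmm2`, joint `jm2`) run at 50 replicates with one chain per
fit in the automated checks; their tolerances are three Monte-Carlo
standard errors combining both replicate counts, so the reduced scale is
reflected honestly in the assertion width.

## Known limitations

* Stage-two standard errors ignore stage-one uncertainty (by design, to
  match the practice being studied).
* No interval censoring, competing risks, stratified baselines,
  time-varying survival covariates, or informative-visit-process
  submodels.
* The half-Cauchy alternative for the residual-SD law and covariates in
  the log-SD mean are not implemented.
* Model selection over the number of hazard intervals (e.g. by DIC) is
  out of scope; `K` is a user choice.
* The marginal event fraction of the default generator is ≈22%, not the
  20% of its median-subject calibration; analyses sensitive to the
  absolute event rate should recalibrate `γ0`.
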