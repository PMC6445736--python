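# bpvar — visit-to-visit biomarker variability and time-to-event outcomes

Visit-to-visit variability of a longitudinal biomarker — classically
systolic blood pressure (SBP) across clinic visits — is itself a risk
factor for cardiovascular events. The standard epidemiological practice is
to summarise each subject's repeated measurements by their mean and SD and
enter both into a Cox regression. Because a per-subject SD computed from a
handful of visits is a very noisy estimate of the subject's true
variability, the resulting hazard ratio is badly attenuated (regression
dilution); and when the measurement stream is cut short by the event
itself (informative truncation), the attenuation can swallow the
association entirely.

`bpvar` implements the full model stack for doing this properly, for
biostatisticians working with cohort data of the form *(subject, visit
time, biomarker value)* plus *(follow-up time, event indicator)*:

* **Naive per-subject estimators** — mean, SD (denominator `n` or `n−1`),
  coefficient of variation, average real variability (ARV).
* **Bayesian location-scale mixed models** (`lmm1`–`lmm4`) — random
  intercept (optionally slope) with a *subject-specific residual SD*
  `σ_i`, log-normally distributed and optionally correlated with the
  usual level:

  ```
  Y_ij = β'X_i (+ β_t t_ij) + b0_i (+ b1_i t_ij) + ε_ij,   ε_ij ~ N(0, σ_i²)
  (b0_i[, b1_i], log σ_i) ~ multivariate normal
  ```

* **Two-stage Cox regression** — posterior-mean usual level `BP̂_i` and
  residual SD `BPSD̂_i` (or the naive summaries) as covariates in
  `h_i(t) = h0(t)·exp(α'U_i + γ'W_i)`, fitted by an own
  Newton–Raphson partial-likelihood maximiser with Efron tie handling.
* **Shared-random-effects joint models** (`jm1`–`jm4`) — the location-scale
  longitudinal submodel and a survival submodel
  `h_i(t) = h0(t)·exp(α0 b0_i + ασ σ_i + γ'W_i)` with a piecewise-constant
  baseline hazard on event-time-quantile intervals, estimated
  simultaneously by MCMC. This removes both regression dilution and
  informative-truncation bias.
* **A replicated simulation harness** quantifying bias, RMSE and coverage
  of every method under two designs: Scenario 1 (complete visit
  schedules) and Scenario 2 (visits truncated by events).

MCMC is a Metropolis-within-Gibbs sampler written for this model family
(hierarchically centred, conjugate where possible, adaptive random-walk
steps elsewhere), with the Brooks–Gelman potential scale reduction factor
as the convergence diagnostic.

## Worked example

Simulate a default cohort (1500 subjects, 4 visits, usual level
N(120, 15²) mmHg, log residual SD N(2, 0.5²) with correlation 0.5, Weibull
proportional hazards with log-hazard slopes 0.02 per mmHg of usual level
and 0.05 per mmHg of variability, 20-year censoring) and compare the Cox
fit on the *true* latent covariates with the naive two-stage method over
200 replicates:

```sh
$ bpvar simstudy --reps 200 --methods true,naive --seed 7 --out table.csv
              Usual Level logHR                             Variability logHR
Method        True    Mean (SD)           RMSE    Coverage  True    Mean (SD)           RMSE    Coverage
True values   0.02    0.0200 (0.0042)     0.0042  0.9400    0.05    0.0512 (0.0107)     0.0107  0.9600
Naive         0.02    0.0208 (0.0035)     0.0036  0.9400    0.05    0.0293 (0.0085)     0.0224  0.3250
```

Reading the table: with the latent truth as covariates the variability log
hazard ratio is estimated without bias (0.0512 vs a true 0.05) and the
nominal 95% interval covers at about its nominal rate. The naive method
attenuates the same coefficient by ~40% (0.0293) and its coverage
collapses to 0.33 — regression dilution from estimating a subject's SD
with four visits. A `lmm2` or `jm2` fit (add them to `--methods`) restores
the estimate to near 0.05.

The same machinery is available from Python:

```python
from bpvar import SimConfig, simulate_dataset, fit_locscale, subject_effects, fit_cox

dataset, truth = simulate_dataset(SimConfig(scenario=2, seed=1))
draws = fit_locscale(dataset, "lmm2")            # location-scale mixed model
effects = subject_effects(draws)                 # posterior-mean level & SD
fit = fit_cox(effects.df.rename(columns={"bp_hat": "level", "sd_hat": "sbp_sd"})
              [["id", "level", "sbp_sd"]], dataset.survival)
print(fit.summary())
```

Individual commands (`bpvar simulate`, `bpvar fit naive|lmm|cox|joint`)
read and write plain CSV; see `bpvar --help`.

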