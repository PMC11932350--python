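# radconfound

Monte-Carlo quantification of smoking confounding in occupational
radiation-cohort studies.

Cohort studies of radiation workers estimate the excess relative risk
(ERR) of cancer mortality per Gy, but most cannot adjust for smoking.
Because smoking is both a strong cause of cancer death and — in some
cohorts — positively associated with radiation dose, the unadjusted
dose coefficient absorbs part of the smoking effect. `radconfound`
simulates this situation end to end so that epidemiologists and
biostatisticians can ask: *if the smoking–dose association has
odds ratio X, how badly biased is the unadjusted dose estimate, and
does adjusting fix it?*

## The model

A closed cohort of male workers enters follow-up at age 20 (clock
t = 0) and is followed 60 years. Per subject *i*:

- dose `dᵢ` ~ log-normal (GM 0.2623 Gy, GSD 2.223), clamped at 1 Gy;
- smoking `sᵢ` ~ Bernoulli with `logit p(d) = logit(0.3) + ln(OR₁ᴳʸ)·d`,
  so the odds ratio of smoking at 1 Gy vs 0 Gy equals `OR₁ᴳʸ` exactly;
- frailty `uᵢ` ~ N(0, 1), independent of dose and smoking;
- cancer death hazard `λᵢ(t) = λ₀(t)·exp(β_r dᵢ + β_s sᵢ + β_u uᵢ)` with
  Weibull baseline (shape 6.086609, scale 75.992411 years), sampled
  directly as Weibull(a, b/λ^{1/a});
- non-cancer death hazard `exp(0.001022·(t+0.05311)² − 7.221)`, sampled
  by the inversion method (solve `H(t) = −ln(1−u)` on a precomputed
  monotone grid);
- observed time = min(cancer time, non-cancer time, 60 y); only cancer
  death counts as the event.

Each replicate cohort is analysed four ways: Cox proportional hazards
on the individual records and grouped Poisson regression on a
person-years table (1-year age bands, equal-width dose categories,
person-year-weighted cell covariates, log person-years offset and a
quadratic-in-age baseline), each with and without the smoking
covariate. Scenarios are summarised by the mean relative bias of the
dose coefficient `mean(β̂_r − β_r)/ERR` with `ERR = exp(β_r) − 1`, the
mean standard error, and the 95% Wald coverage, over replications.

## Worked example

One scenario at the default mechanism (ERR 0.3/Gy, smoking HR 1.6,
smoking odds ratio 32 at 1 Gy), scaled down to 20,000 workers and 50
replications:

```bash
$ radconfound simulate --reps 50 --cohort-size 20000 --seed 7 --out example.csv
cox      adjusted    bias=+0.028 se=0.056 coverage=0.960 (n_converged=50)
cox      unadjusted  bias=+0.992 se=0.053 coverage=0.000 (n_converged=50)
poisson  adjusted    bias=+0.026 se=0.056 coverage=0.960 (n_converged=50)
poisson  unadjusted  bias=+1.000 se=0.053 coverage=0.000 (n_converged=50)
wrote example.csv
```

Reading: with smoking in the model (adjusted) the dose coefficient is
essentially unbiased (+3% of the true ERR, within Monte-Carlo noise)
and the interval attains its nominal level. Without it, the estimate
overshoots by ≈ 99% of the true ERR — the radiation effect roughly
doubles — and the 95% interval virtually never covers the truth. Cox
and grouped Poisson agree closely. Sweeps over parameter grids
(`radconfound sweep --config cfg.yaml`, `radconfound tables`) write
one CSV row per scenario with the 12 per-arm metric columns.

The library surface mirrors the pipeline: `generate_cohort`,
`cox_fit`/`poisson_fit`, `build_py_table`, `run_scenario`/`run_grid`,
and `extrapolate_or_per_gray` for converting smoking proportions in
two dose groups into a per-Gy odds ratio.

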