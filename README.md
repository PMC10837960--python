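# alsmbma

Model-based meta-analysis (MBMA) of the placebo-group disease course in
amyotrophic lateral sclerosis (ALS) trials, for trial statisticians and
pharmacometricians who need a quantitative historical control: simulating
expected placebo outcomes for trial design, benchmarking single-arm studies,
and borrowing historical information into small concurrent placebo groups.

ALS trials report two canonical endpoints at the arm level: overall survival
(OS; time to death, tracheostomy or continuous ventilatory support, read off
digitized Kaplan–Meier curves) and the mean change from baseline of the
revised ALS Functional Rating Scale (ALSFRS-R, 0–48 points). This package
fits both to aggregate per-arm data pooled across published trials, with
study-level random effects and size-weighted residual noise.

## Models

**Survival.** A log-normal base distribution with proportional-hazards
covariates:

```
S0(t) = 1 − Φ((ln t − MU) / SIGM)
h(t)  = h0(t) · exp(θ_dur · (DURATION − 17.8) + θ_ril · RILUZOLE)
S(t)  = S0(t)^HR
```

DURATION is the arm's median time from symptom onset to enrollment (months,
centered at the corpus median 17.8) and RILUZOLE the fraction of patients on
riluzole. Between-study effects act log-normally on MU and SIGM; the
published estimates (MU = 3.04, SIGM = 0.916, θ_dur = 0.0317,
θ_ril = −0.228) ship in `alsmbma.reference`.

**Function.** A sigmoid-Emax time course of the mean ALSFRS-R change:

```
ΔALSFRS-R(t) = −Emax · t^γ / (ET50^γ + t^γ)
```

with Emax = 26.2 points, ET50 = 17.5 months and γ = 1.2 at the published
estimates — i.e. half of the maximal functional decline is reached around
17.5 months, with a plateau near 40 months.

Estimation is marginal maximum likelihood (Laplace approximation with a
Gauss–Newton conditional Hessian, the FOCE-style convention), with stepwise
covariate search, empirical-Bayes per-study estimates, a nonparametric
study-level bootstrap, goodness-of-fit/CWRES diagnostics, visual predictive
checks, Monte Carlo typical-course simulation, DerSimonian–Laird subgroup
pooling, and normal–normal Bayesian borrowing. A synthetic-data generator
reproduces the statistical structure of the published corpus (≈30 OS and
29 ALSFRS-R arms, arm sizes 11–468) so the whole pipeline is testable
offline.

## Worked example

```python
from alsmbma import (GeneratorConfig, generate, fit, simulate_typical,
                     CovariateProfile, PLACEBO_OS_PARAMS, median_os)

corpus = generate(GeneratorConfig(seed=1))        # synthetic corpus
result = fit(corpus, "ALSFRS", n_starts=2)        # refit the Emax model
print(f"converged: {result.converged}, OFV: {result.ofv:.1f}")
for name in ("emax", "et50", "gamma"):
    print(f"  {name:6s} {result.estimates[name]:7.2f}"
          f"  (RSE {result.rse_pct[name]:.1f}%)")

course = simulate_typical(result, n_mc=1000, seed=1)
mid, lo, hi = course.summary["change_at_12m"]
print(f"typical 12-month ALSFRS-R change: {mid:.2f} (95% CI {lo:.2f}, {hi:.2f})")

cov = CovariateProfile(duration_months=17.8, riluzole_frac=0.9)
print(f"plug-in median OS at the reference profile: "
      f"{median_os(cov, PLACEBO_OS_PARAMS):.1f} months")
```

prints

```
converged: True, OFV: 1634.5
  emax     22.67  (RSE 12.2%)
  et50     14.81  (RSE 17.3%)
  gamma     1.43  (RSE 12.9%)
typical 12-month ALSFRS-R change: -9.55 (95% CI -13.16, -6.54)
plug-in median OS at the reference profile: 24.7 months
```

The refitted Emax/ET50/γ recover the generating values (26.2 / 17.5 / 1.2)
within their sampling uncertainty for this single synthetic corpus; the
simulated 12-month decline of ≈ −9.6 points carries the parameter
uncertainty of the fit; and the plug-in median OS at the reference profile
(median disease duration, 90% riluzole) is 24.7 months.

A command-line interface wraps the same stages:

```
alsmbma simulate-data --seed 1 --out data/
alsmbma fit --endpoint ALSFRS --in data/corpus.csv --out fit/
alsmbma borrow --prior=-8.07,-9.57,-6.72 --observed=-10.1,-12.75,-7.45 \
               --drug=-7.1,-9.04,-5.16
```

The last command performs the conjugate update of the historical placebo
prior with a small concurrent placebo arm and prints the posterior
(−8.53, 95% CI −9.78 to −7.27) together with the drug arm's relative
efficacy (≈17% less decline than placebo).

## Layout

- `alsmbma.trial_data` — arm-level containers, long-CSV I/O, corpus summary
- `alsmbma.os_model`, `alsmbma.alsfrs_model` — structural models
- `alsmbma.reference` — published historical-placebo estimates
- `alsmbma.nlme_fit` — Laplace NLME fitting, covariate search, bootstrap
- `alsmbma.diagnostics` — GOF/CWRES, visual predictive check
- `alsmbma.simulation` — Monte Carlo typical courses, scenario tables
- `alsmbma.subgroup_meta` — DerSimonian–Laird subgroup pooling
- `alsmbma.application` — external control bands, Bayesian borrowing
- `alsmbma.synthetic_data` — corpus generator
- `alsmbma.cli` — `alsmbma` console script

See `docs/methods.md` for modeling assumptions, numerical choices and
limitations.
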