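# Methods

## Data model

The unit of analysis is a placebo **arm** from a published ALS randomized
trial, carrying study-level covariates (disease duration at enrollment in
months, riluzole-treated fraction, and optionally age at onset, sex and
bulbar-onset fractions, baseline ALSFRS-R, a basic-treatment flag and
publication year), the arm sample size n, and one or two observation
series: survival proportions S(t) at a grid of months (as digitized from
Kaplan–Meier curves) and/or mean ALSFRS-R changes from baseline. Survival
proportions of exactly 0 are rejected at ingestion (the fitting scale is
logit by default) and times must be strictly increasing with non-increasing
survival within an arm. Arms require n ≥ 11; arms missing a covariate are
dropped only from analyses that request that covariate, with a logged
count. All times are months throughout the library; any unit conversion is
a presentation concern.

## Structural models

**OS.** Log-normal time-to-event base distribution,
S0(t) = 1 − Φ((ln t − MU)/SIGM), with covariates acting proportionally on
the hazard: h(t) = h0(t)·exp(θ_dur (d − 17.8) + θ_ril r). Survival then
transforms as S = S0^HR. The reference parameterization reads MU as the
log-time location and SIGM as the log-time scale: MU = 3.04 implies a
baseline median of e^3.04 ≈ 20.9 months, the only physically coherent
reading of the published table (whose footnote swaps the labels). The
riluzole covariate enters as a fraction in [0, 1]; this reproduces the
published ≈0.4-month median-OS gain per 10-percentage-point increase.
Weibull, log-logistic and exponential base hazards exist solely as
candidates for base-model selection by AIC.

**ALSFRS-R.** Sigmoid-Emax time course, Δ(t) = −Emax·t^γ/(ET50^γ + t^γ),
with decline stored as negative change and Emax a positive magnitude
(≤ 48). The final published model carries no covariates; the covariate
machinery (linear effects on log-parameters) remains available but defaults
off.

**Variability.** Between-study effects are multiplicative log-normal,
param_i = param·exp(η), with η SDs interpreted as the published %CV values
(e.g. 25.2% → ω = 0.252). The residual SD of an arm of size n is
ε·sqrt(75/n): 75 is the published all-arm median size, fixed as a constant
so that ε keeps one meaning across corpora and bootstrap resamples. OS
residuals live on the logit of the survival proportion by default
(configurable: logit / cloglog / identity); an additive SD of 0.693 is not
plausible on the probability scale, and the logit scale also keeps
simulated observations inside (0, 1). Score residuals are additive points.
When an arm reports standard errors they can be used instead of the size
weighting.

## Estimation

The marginal likelihood integrates the per-arm random effects (two per
endpoint: SIGM/MU for OS, Emax/γ for scores). The integral is approximated
by Laplace's method at the per-arm posterior mode of η, with the
Gauss–Newton (first-order) information GᵀΣ⁻¹G + Ω⁻¹ as the curvature —
the same convention as FOCE-style estimators; exact reproduction of any
specific software's objective value is not attempted, and correctness is
established by parameter recovery on synthetic corpora and by agreement
with 5-node adaptive Gauss–Hermite quadrature (within 0.5 OFV units on
small corpora, checked in the test suite). The inner mode search is a
damped Gauss–Newton iteration vectorized across arms; the outer problem
(L-BFGS-B on transformed parameters: log scale for positive quantities,
raw for MU and covariate coefficients) uses 5 jittered starts by default
(fewer in bootstrap refits, which warm-start at the point estimates).
Between-study SDs are floored at 10⁻³ and the residual SD at 10⁻⁴ to keep
the objective smooth at variance boundaries; as a consequence a zero-noise
corpus has a shallow ridge (tiny structural shifts can be absorbed by η at
negligible penalty), and structural parameters are then recovered to ~1%
(scores) / ~5% (OS location) rather than machine precision, with covariate
coefficients essentially exact.

Standard errors come from the central-difference Hessian of the objective
at the optimum (delta method back to the natural scale); a Hessian that is
finite but not invertible yields NA standard errors while the fit still
counts as converged — mirroring the successful-minimization /
failed-covariance distinction that bootstrap success rates conventionally
use.

Covariate model building is forward inclusion (ΔOFV > 3.84, df 1, p<0.05)
then backward elimination (ΔOFV > 6.63, p<0.01), with continuous covariates
centered at the corpus median (the canonical OS model centers duration at
17.8 months and leaves the riluzole fraction uncentered). Empirical-Bayes
study estimates are the posterior modes param·exp(η̂) with conditional SDs
from the inner curvature. The bootstrap resamples arms with replacement at
the study level and refits; >50% failures abort.

## Diagnostics

CWRES uses the first-order linearization around the empirical-Bayes mode:
V = GΩGᵀ + Σ, CWRES = V^(−1/2)(y − f(η̂) + Gη̂). The VPC simulates replicate
corpora under the observed design drawing η and ε only (parameter
uncertainty is deliberately excluded, as is conventional), bins times —
exactly per grid time when the design shares a grid, quantile bins
otherwise (default 8) — and reports 2.5/50/97.5 percentile bands plus the
fraction of observations inside the 95% band. Simulated OS observations are
back-transformed from the fitting scale and truncated to (0, 1]. All band
data are emitted as TSV; plotting is left to the caller.

## Simulation and applications

Typical-course simulation draws parameters independently from
N(estimate, SE²) on the estimation scale (log-normal for positive
parameters, so draws are always admissible; invalid draws would be redrawn
and counted). Independence is a stated approximation — published tables
give RSEs but no correlation matrix; when bootstrap replicates are
available they are the better uncertainty source. `include_eta` switches
from "typical study" (η = 0, the default) to "new study" bands;
`include_eps` additionally adds residual noise for an arm of a given size,
giving a predictive band for observed points. Percentiles are type-7.
The published typical median OS of 29.0 months (95% CI 24.5–34.5) and the
1/2/5-year rates are *not* reproduced by the plug-in calculation at the
same covariates (24.8 months, inside the published interval); the Monte
Carlo recipe behind the published value is underdetermined by the available
description (the η = 0 vs new-study distinction is the leading suspect), so
the package exposes the switch and validates directions and solver accuracy
instead of that single number.

External-control comparison simulates the matched placebo band at the
trial's covariate profile — by default the predictive band (η and ε drawn,
residual scaled to the trial arm size), since observed arm points carry
both sources of noise — and classifies each point as below/inside/above.
The overall verdict requires at least two excursions, all on the same side,
sustained at the end of follow-up; early OS points sit near S = 1 where all
bands overlap, so a majority-of-all-points rule would never trigger.
"Above" is beneficial for both endpoints (higher survival; less negative
score change).

Bayesian borrowing is the conjugate normal–normal update; printed
(possibly asymmetric) 95% CIs are converted to SEs by full width/(2·1.96),
which reproduces the published posterior to two decimals. The reported
borrow weight is the prior's share of posterior precision. Subgroup
analysis splits arms at the corpus median (continuous), 2009 (publication
year) or the flag (basic treatment), pools the log-scale empirical-Bayes
parameters per level with DerSimonian–Laird (the estimator is not named in
the source; DL is the standard default), and propagates the pooled normal
to the course summary (median OS at the reference profile duration 17.8 /
riluzole 0.9, or the 12-month score change) by Monte Carlo.

## Synthetic corpus

The generator emulates the published corpus: 30 OS + 29 score arms; arm
sizes log-uniform on [11, 468] (median ≈ 72 vs published 75); disease
duration log-uniform on [9, 36] months (median 18 vs published 17.6) —
log-uniform rather than uniform because the published median sits well
below the range midpoint; riluzole fraction a mixture 0.8·U[0.7, 1] +
0.2·U[0, 0.7] (median ≈ 0.88 vs published ≈ 0.88); age, sex, bulbar,
baseline-score and publication-year ranges per the published
characteristics table. OS arms are observed every 3 months to 60; score
arms every 3 months to an arm-specific follow-up drawn from {3, …, 48}.
Observations are structural curves plus η and size-weighted ε on the
fitting scale. Noisy OS series are projected onto the non-increasing cone
by isotonic regression (PAVA): digitized KM curves are monotone, and PAVA
is the mean-preserving projection, whereas a running minimum would bias
the series downward and measurably attenuate covariate effects at the
generating noise level. A raw mode without projection exists for
likelihood unit tests (usable when the noise is small enough to keep
monotonicity, which arm validation enforces).

What the generator does **not** emulate: digitization error correlated
along a curve, censoring-driven KM step patterns, covariate correlations
across studies (covariates are drawn independently), reporting selection,
and true non-placebo heterogeneity (e.g. calendar-time trends). Passing
recovery tests therefore shows the estimator is consistent under the
assumed data-generating process, not that the published corpus satisfies
those assumptions.

## Problem sizes in the checks

The test suite and acceptance script size their simulations as follows:
parameter recovery uses 20 OS corpora and 5 score corpora at the published
generating values; the bootstrap check uses 200 replicates (the published
analysis used 1000); VPCs use 500 simulated replicates; the null-covariate
likelihood-ratio calibration uses 30 seeded corpora of 12 arms; the
acceptance script's refit experiment uses 5 corpora. These sizes give
stable medians while keeping the default runs fast on one CPU.

## Known limitations

- Laplace/Gauss–Newton marginalization carries small-sample bias relative
  to exact integration; at the corpus sizes here the residual median bias
  is a few percent on structural parameters (ET50 ~ −10% under truncated
  follow-up designs, still inside the stated recovery tolerance).
- Digitized KM points within an arm are treated as independent on the
  fitting scale given η; real digitized curves have autocorrelated errors,
  and the isotonic projection in the generator reduces the effective
  residual variance the fit sees (fitted ε ≈ 0.4 against a generating 0.693
  on the logit scale).
- Parameter-uncertainty simulation ignores estimate correlations unless
  bootstrap replicates are supplied.
- The external-control verdict is a screening heuristic for exploratory
  single-arm comparisons, not a confirmatory decision rule.
- Aggregate-level covariate effects are ecological: arm-level duration and
  riluzole fractions need not reflect patient-level hazard ratios, and
  patient-level survival prediction is out of scope.
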