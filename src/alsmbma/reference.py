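"""Published historical-placebo model estimates for ALS trials.

These are the final-model estimates from a model-based meta-analysis of
placebo arms in ALS randomized trials (30 OS arms / 29 ALSFRS-R arms,
~6100 participants): a log-normal proportional-hazards survival model with
disease duration and riluzole-treated fraction as hazard covariates, and a
covariate-free sigmoid-Emax model for mean ALSFRS-R change from baseline.
They serve as defaults for the synthetic-data generator, as plug-in
parameters for typical-course simulation, and as the historical prior for
external-control and Bayesian-borrowing applications.
"""

from __future__ import annotations

from .os_model import OSParams
from .alsfrs_model import EmaxParams

__all__ = ["PLACEBO_OS_PARAMS", "PLACEBO_OS_RSE",
           "PLACEBO_EMAX_PARAMS", "PLACEBO_EMAX_RSE"]

#: Final OS model: log-normal hazard, duration centered at the corpus median
#: 17.8 months, riluzole as treated fraction; eta SDs as CV fractions.
PLACEBO_OS_PARAMS = OSParams(
    mu=3.04,
    sigm=0.916,
    theta_duration=0.0317,
    theta_riluzole=-0.228,
    duration_center=17.8,
    eta_sd_sigm=0.252,
    eta_sd_mu=0.0720,
    eps_sd=0.693,
    obs_scale="logit",
)

#: Relative standard errors (%) of the OS estimates.
PLACEBO_OS_RSE = {
    "mu": 2.80, "sigm": 5.80,
    "theta_duration": 28.3, "theta_riluzole": 57.5,
    "eta_sd_sigm": 15.6, "eta_sd_mu": 19.4, "eps_sd": 17.2,
}

#: Final ALSFRS-R model: covariate-free sigmoid Emax.
PLACEBO_EMAX_PARAMS = EmaxParams(
    emax=26.2,
    et50=17.5,
    gamma=1.2,
    eta_sd_emax=0.258,
    eta_sd_gamma=0.122,
    eps_sd=4.00,
)

#: Relative standard errors (%) of the ALSFRS-R estimates.
PLACEBO_EMAX_RSE = {
    "emax": 7.0, "et50": 4.4, "gamma": 5.8,
    "eta_sd_emax": 18.0, "eta_sd_gamma": 20.0, "eps_sd": 14.9,
}
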