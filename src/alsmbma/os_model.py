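"""Log-normal base hazard with proportional-hazards covariates for overall
survival (OS) of ALS placebo arms.

The base distribution is log-normal in time: S0(t) = 1 - Phi((ln t - MU)/SIGM),
with MU the log-time location and SIGM the log-time scale. Study covariates act
proportionally on the hazard,

    h(t) = h0(t) * exp(theta_dur * (duration - c) + theta_ril * riluzole),

so survival transforms as S(t) = S0(t)**HR with HR the hazard ratio. The
duration covariate is centered at the corpus median (c = 17.8 months by
default); riluzole enters as the arm-level treated fraction in [0, 1].

Between-study heterogeneity is multiplicative log-normal on MU and SIGM:
MU_i = mu * exp(eta_mu), SIGM_i = sigm * exp(eta_sigm), with eta standard
deviations interpreted as coefficients of variation (the pharmacometric
%CV convention for log-normal random effects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .trial_data import CovariateProfile, StudyArm

__all__ = ["OSParams", "log_hazard_multiplier", "survival", "hazard",
           "median_os", "predict_surv_series", "to_obs_scale",
           "from_obs_scale"]

#: Root-finding horizon for the median survival time, months.
HORIZON_MONTHS = 600.0

_SURV_CLIP_HI = 1.0 - 1e-9
_SURV_CLIP_LO = 1e-12


@dataclass(frozen=True)
class OSParams:
    """Parameters of the log-normal proportional-hazards survival model.

    eta_sd_* are between-study SDs (CV fractions, e.g. 0.252 for 25.2%CV) of
    the multiplicative study effects on SIGM and MU. eps_sd is the additive
    residual SD on the configured observation scale (default: logit of the
    survival proportion) for an arm of the reference size.
    """

    mu: float
    sigm: float
    theta_duration: float = 0.0
    theta_riluzole: float = 0.0
    duration_center: float = 17.8
    eta_sd_sigm: float = 0.0
    eta_sd_mu: float = 0.0
    eps_sd: float = 0.0
    obs_scale: str = "logit"

    def __post_init__(self) -> None:
        if self.sigm <= 0:
            raise ValueError("sigm must be positive")
        if min(self.eta_sd_sigm, self.eta_sd_mu, self.eps_sd) < 0:
            raise ValueError("eta/eps SDs must be nonnegative")
        if self.obs_scale not in ("logit", "cloglog", "identity"):
            raise ValueError(f"unknown obs_scale {self.obs_scale!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OSParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def log_hazard_multiplier(cov: CovariateProfile, params: OSParams) -> float:
    """Linear predictor on the log-hazard for an arm's covariate profile.

    theta_duration * (duration - duration_center) + theta_riluzole * riluzole.
    """
    if cov.duration_months is None or cov.riluzole_frac is None:
        raise ValueError("covariate profile must provide duration and riluzole")
    return (params.theta_duration * (cov.duration_months - params.duration_center)
            + params.theta_riluzole * cov.riluzole_frac)


def _study_params(params: OSParams, eta: Sequence[float]):
    eta_sigm, eta_mu = float(eta[0]), float(eta[1])
    return params.sigm * np.exp(eta_sigm), params.mu * np.exp(eta_mu)


def base_survival(t, mu: float, sigm: float):
    """S0(t) of the log-normal time distribution; S0(0) = 1."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    out[pos] = stats.norm.sf((np.log(t[pos]) - mu) / sigm)
    return out


def survival(t, cov: CovariateProfile, params: OSParams,
             eta: Sequence[float] = (0.0, 0.0)):
    """S(t) = S0(t)**exp(log_hazard_multiplier) at a covariate profile.

    ``eta`` is the pair of study effects (eta_sigm, eta_mu); the default 0
    gives the population-typical study. Accepts scalar or array t >= 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    sigm_i, mu_i = _study_params(params, eta)
    hr = np.exp(log_hazard_multiplier(cov, params))
    s = base_survival(t_arr, mu_i, sigm_i) ** hr
    return s if np.ndim(t) else float(s)


def hazard(t, cov: CovariateProfile, params: OSParams,
           eta: Sequence[float] = (0.0, 0.0)):
    """Instantaneous hazard h(t) = h0(t) * HR, t > 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("hazard defined for t > 0")
    sigm_i, mu_i = _study_params(params, eta)
    z = (np.log(t_arr) - mu_i) / sigm_i
    h0 = stats.norm.pdf(z) / (sigm_i * t_arr * stats.norm.sf(z))
    h = h0 * np.exp(log_hazard_multiplier(cov, params))
    return h if np.ndim(t) else float(h)


def median_os(cov: CovariateProfile, params: OSParams,
              eta: Sequence[float] = (0.0, 0.0)) -> float:
    """Median overall survival: the root of S(t) = 0.5, in months.

    Solved by Brent's method on (1e-6, 600] months to 1e-6 months.
    """
    def f(t):
        return survival(t, cov, params, eta) - 0.5

    if f(HORIZON_MONTHS) > 0:
        raise ValueError("median beyond horizon (S(600 months) > 0.5)")
    return float(optimize.brentq(f, 1e-6, HORIZON_MONTHS, xtol=1e-6))


def to_obs_scale(s, scale: str = "logit"):
    """Map survival probabilities to the observation scale used for fitting.

    Probabilities at the boundary are clipped to (0, 1-1e-9) first so that
    logit/cloglog stay finite (S=1 occurs in digitized curves at early times).
    """
    s = np.clip(np.asarray(s, dtype=float), _SURV_CLIP_LO, _SURV_CLIP_HI)
    if scale == "identity":
        return s
    if scale == "logit":
        return np.log(s / (1.0 - s))
    if scale == "cloglog":
        return np.log(-np.log(s))
    raise ValueError(f"unknown scale {scale!r}")


def from_obs_scale(y, scale: str = "logit"):
    """Inverse of :func:`to_obs_scale`."""
    y = np.asarray(y, dtype=float)
    if scale == "identity":
        return np.clip(y, _SURV_CLIP_LO, 1.0)
    if scale == "logit":
        return 1.0 / (1.0 + np.exp(-y))
    if scale == "cloglog":
        return np.exp(-np.exp(y))
    raise ValueError(f"unknown scale {scale!r}")


def predict_surv_series(arm: StudyArm, params: OSParams,
                        eta: Sequence[float] = (0.0, 0.0),
                        scale: str | None = None) -> np.ndarray:
    """Model predictions on the observation scale at the arm's OS times."""
    if not arm.has_os:
        raise ValueError(f"arm {arm.study_id} has no OS series")
    if scale is None:
        scale = params.obs_scale
    t = np.array([p.time_months for p in arm.os_series])
    s = survival(t, arm.covariates, params, eta)
    return to_obs_scale(s, scale)
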