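"""Sigmoid-Emax time course of mean ALSFRS-R change from baseline.

The mean functional decline of a placebo arm is modeled as a saturating
curve in treatment time t (months):

    change(t) = -Emax * t**gamma / (ET50**gamma + t**gamma)

with Emax the maximum decline (points, stored as a positive magnitude; the
predicted change is negative), ET50 the time to half-maximal decline and
gamma the sigmoidicity. Between-study heterogeneity is multiplicative
log-normal on Emax and gamma (SDs as CV fractions); the residual SD of an
arm of size n is eps_sd * sqrt(75 / n), i.e. eps_sd is the SD at the
corpus-median arm size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .trial_data import StudyArm

__all__ = ["EmaxParams", "typical_change", "fraction_of_max",
           "predict_score_series", "REFERENCE_ARM_SIZE"]

#: Arm size at which eps_sd is the residual SD (corpus median).
REFERENCE_ARM_SIZE = 75.0


@dataclass(frozen=True)
class EmaxParams:
    """Sigmoid-Emax parameters with between-study and residual variability."""

    emax: float
    et50: float
    gamma: float
    eta_sd_emax: float = 0.0
    eta_sd_gamma: float = 0.0
    eps_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.emax <= 48):
            raise ValueError("emax must be in (0, 48]")
        if self.et50 <= 0 or self.gamma <= 0:
            raise ValueError("et50 and gamma must be positive")
        if min(self.eta_sd_emax, self.eta_sd_gamma, self.eps_sd) < 0:
            raise ValueError("eta/eps SDs must be nonnegative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EmaxParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def typical_change(t, params: EmaxParams,
                   eta: Sequence[float] = (0.0, 0.0)):
    """Mean ALSFRS-R change from baseline at time t (months), <= 0.

    ``eta`` = (eta_emax, eta_gamma) are the study's multiplicative effects;
    zero gives the population-typical curve.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    e_i = params.emax * np.exp(float(eta[0]))
    g_i = params.gamma * np.exp(float(eta[1]))
    with np.errstate(divide="ignore"):
        tg = np.where(t_arr > 0, np.power(t_arr, g_i), 0.0)
    out = -e_i * tg / (params.et50 ** g_i + tg)
    return out if np.ndim(t) else float(out)


def fraction_of_max(t, params: EmaxParams):
    """Fraction of the maximal decline reached by time t: t^g/(ET50^g + t^g)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    tg = np.where(t_arr > 0, np.power(t_arr, params.gamma), 0.0)
    out = tg / (params.et50 ** params.gamma + tg)
    return out if np.ndim(t) else float(out)


def residual_sd(eps_sd: float, n: float) -> float:
    """Residual SD of an arm of size n: eps_sd * sqrt(75 / n)."""
    return eps_sd * np.sqrt(REFERENCE_ARM_SIZE / n)


def predict_score_series(arm: StudyArm, params: EmaxParams,
                         eta: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """Predicted mean changes at the arm's score observation times."""
    if not arm.has_score:
        raise ValueError(f"arm {arm.study_id} has no score series")
    t = np.array([p.time_months for p in arm.score_series])
    return typical_change(t, params, eta)
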