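"""Monte Carlo simulation of typical disease courses with uncertainty.

Parameter uncertainty is propagated by drawing parameter vectors from
independent normals on the estimation scale (log-normal for positive
parameters, so draws stay admissible), evaluating the deterministic course
per draw, and summarizing pointwise percentiles. Optionally the draws also
include a study-level random effect (a "new study" rather than the typical
study) and residual noise (a predictive band for arm-level observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trial_data import CovariateProfile
from . import os_model, alsfrs_model
from .os_model import OSParams
from .alsfrs_model import EmaxParams, REFERENCE_ARM_SIZE
from .nlme_fit import FitResult

__all__ = ["TypicalCourse", "simulate_typical", "scenario_table"]

_POSITIVE = {"sigm", "emax", "et50", "gamma", "eta_sd_sigm", "eta_sd_mu",
             "eta_sd_emax", "eta_sd_gamma", "eps_sd", "wb_scale", "wb_shape",
             "ll_scale", "ll_shape", "exp_scale"}

#: Landmark months summarized for the ALSFRS course (1, 2 and 4 years).
SCORE_LANDMARKS = (12.0, 24.0, 48.0)


@dataclass
class TypicalCourse:
    """Simulated typical trajectory with pointwise 95% interval."""

    endpoint: str
    covariates: Optional[CovariateProfile]
    grid: np.ndarray
    point: np.ndarray          # pointwise median across draws
    lo95: np.ndarray
    hi95: np.ndarray
    n_mc: int
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.grid, "point": self.point,
                             "lo95": self.lo95, "hi95": self.hi95})


def _se_dict(fit: Union[FitResult, OSParams, EmaxParams],
             se: Optional[dict]):
    """Resolve (estimates dict, se dict, params object, endpoint)."""
    if isinstance(fit, FitResult):
        if not fit.converged:
            raise ValueError("simulate_typical requires a converged fit")
        params = fit.params
        if params is None:
            raise ValueError("fit configuration has no typed parameter form")
        return fit.estimates, dict(fit.se), params, fit.endpoint
    params = fit
    endpoint = "OS" if isinstance(params, OSParams) else "ALSFRS"
    est = {k: v for k, v in params.__dict__.items() if isinstance(v, float)}
    return est, dict(se or {}), params, endpoint


def _draw_params(rng, est: dict, se: dict, names, n_mc: int):
    """Independent draws per parameter; log-domain for positive parameters."""
    draws = {}
    for name in names:
        v = est[name]
        s = se.get(name, 0.0)
        s = 0.0 if s is None or not np.isfinite(s) else float(s)
        if s == 0.0 or v == 0.0:
            draws[name] = np.full(n_mc, v)
        elif name in _POSITIVE:
            cv = s / abs(v)
            draws[name] = v * np.exp(rng.normal(0.0, cv, n_mc))
        else:
            draws[name] = rng.normal(v, s, n_mc)
    return draws


def simulate_typical(fit: Union[FitResult, OSParams, EmaxParams],
                     cov: Optional[CovariateProfile] = None,
                     n_mc: int = 1000, seed: int = 0,
                     include_eta: bool = False,
                     include_eps: bool = False,
                     arm_n: float = REFERENCE_ARM_SIZE,
                     se: Optional[dict] = None,
                     grid: Optional[np.ndarray] = None) -> TypicalCourse:
    """Typical disease course at a covariate profile, with 95% interval.

    ``fit`` is a converged FitResult (SEs taken from it) or a bare parameter
    object (``se`` maps parameter names to standard errors; RSE% tables can
    be converted via se = rse/100*estimate). With all SEs zero the band
    collapses onto the deterministic typical curve and the result does not
    depend on the seed.

    include_eta draws a study-level random effect per replicate (band for a
    new study rather than the typical one); include_eps additionally adds
    residual noise for an arm of ``arm_n`` patients (predictive band for
    observed arm-level points). The summary holds the median OS (OS) or the
    changes at 12/24/48 months (ALSFRS).
    """
    est, se_map, params, endpoint = _se_dict(fit, se)
    rng = np.random.default_rng(seed)
    if endpoint == "OS":
        if cov is None:
            raise ValueError("OS simulation needs a covariate profile")
        if grid is None:
            grid = np.arange(1.0, 61.0, 1.0)
        names = ["mu", "sigm", "theta_duration", "theta_riluzole", "eps_sd"]
    else:
        if grid is None:
            grid = np.arange(1.0, 49.0, 1.0)
        names = ["emax", "et50", "gamma", "eps_sd"]
    grid = np.asarray(grid, dtype=float)
    names = [n for n in names if n in est]
    draws = _draw_params(rng, est, se_map, names, n_mc)

    curves = np.empty((n_mc, grid.size))
    medians = np.empty(n_mc)
    eps_w = np.sqrt(REFERENCE_ARM_SIZE / arm_n)
    for i in range(n_mc):
        ok = False
        for _attempt in range(100):
            try:
                if endpoint == "OS":
                    p_i = dc_replace(params, mu=draws["mu"][i],
                                     sigm=draws["sigm"][i],
                                     theta_duration=draws.get(
                                         "theta_duration",
                                         np.zeros(n_mc))[i],
                                     theta_riluzole=draws.get(
                                         "theta_riluzole",
                                         np.zeros(n_mc))[i])
                else:
                    p_i = dc_replace(params, emax=min(draws["emax"][i], 48.0),
                                     et50=draws["et50"][i],
                                     gamma=draws["gamma"][i])
                ok = True
                break
            except ValueError:
                # invalid draw (e.g. nonpositive scale): redraw this index
                for name in names:
                    draws[name][i] = _draw_params(rng, est, se_map,
                                                  [name], 1)[name][0]
        if not ok:
            raise RuntimeError("could not draw valid parameters")
        eta = np.zeros(2)
        if include_eta:
            if endpoint == "OS":
                eta = rng.normal(0.0, [p_i.eta_sd_sigm, p_i.eta_sd_mu])
            else:
                eta = rng.normal(0.0, [p_i.eta_sd_emax, p_i.eta_sd_gamma])
        if endpoint == "OS":
            y = os_model.to_obs_scale(
                os_model.survival(grid, cov, p_i, eta), p_i.obs_scale)
            if include_eps and p_i.eps_sd > 0:
                y = y + rng.normal(0.0, p_i.eps_sd * eps_w, grid.size)
            s = os_model.from_obs_scale(y, p_i.obs_scale)
            curves[i] = np.minimum(s, 1.0)
            try:
                medians[i] = os_model.median_os(cov, p_i, eta)
            except ValueError:
                medians[i] = np.nan
        else:
            y = alsfrs_model.typical_change(grid, p_i, eta)
            if include_eps and p_i.eps_sd > 0:
                y = y + rng.normal(0.0, p_i.eps_sd * eps_w, grid.size)
            curves[i] = y

    lo, mid, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    summary: dict = {}
    if endpoint == "OS":
        med = medians[np.isfinite(medians)]
        summary["median_os_months"] = tuple(
            float(v) for v in np.percentile(med, [50.0, 2.5, 97.5]))
    else:
        for lm in SCORE_LANDMARKS:
            j = int(np.argmin(np.abs(grid - lm)))
            if abs(grid[j] - lm) < 0.51:
                summary[f"change_at_{int(lm)}m"] = tuple(
                    float(v) for v in np.percentile(curves[:, j],
                                                    [50.0, 2.5, 97.5]))
    return TypicalCourse(endpoint=endpoint, covariates=cov, grid=grid,
                         point=mid, lo95=lo, hi95=hi, n_mc=n_mc,
                         summary=summary)


def scenario_table(fit: Union[FitResult, OSParams],
                   scenarios: Sequence[CovariateProfile],
                   landmarks: Sequence[float] = (12.0, 24.0, 60.0)
                   ) -> pd.DataFrame:
    """Plug-in median OS and survival rates at landmark months per scenario.

    One row per covariate profile: duration, riluzole fraction, median OS
    (months) and S(t) at each landmark. Deterministic (no Monte Carlo).
    """
    if isinstance(fit, FitResult):
        params = fit.params
        if not isinstance(params, OSParams):
            raise ValueError("scenario_table needs an OS fit")
    else:
        params = fit
    rows = []
    for cov in scenarios:
        row = {"duration_months": cov.duration_months,
               "riluzole_frac": cov.riluzole_frac,
               "median_os_months": os_model.median_os(cov, params)}
        for lm in landmarks:
            row[f"surv_{int(lm)}m"] = os_model.survival(float(lm), cov, params)
        rows.append(row)
    return pd.DataFrame(rows)
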