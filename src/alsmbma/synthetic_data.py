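"""Synthetic corpora with the statistical structure of published ALS
placebo-arm meta-analysis data.

The generator emulates a corpus of ~30 OS arms and ~29 ALSFRS-R arms with
arm sizes, covariate ranges and variance components matching the published
study-characteristics table: arm n log-uniform over [11, 468] (median ~75),
disease duration log-uniform over [9, 36] months (median ~18), riluzole
fraction concentrated near 0.9, and between-study/residual variability
taken from the published model estimates. Observations are the structural
model curves perturbed by study-level random effects and size-weighted
residual noise on the fitting scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import isotonic_regression

from .trial_data import (Corpus, CovariateProfile, ScorePoint, StudyArm,
                         SurvivalPoint)
from . import os_model, alsfrs_model
from .os_model import OSParams
from .alsfrs_model import EmaxParams, REFERENCE_ARM_SIZE
from .reference import PLACEBO_OS_PARAMS, PLACEBO_EMAX_PARAMS

__all__ = ["GeneratorConfig", "generate", "generate_single_arm_trial"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design settings of the synthetic corpus.

    Arm sizes are log-uniform over [11, 468] (median ~= 72, matching the
    published median of 75); disease duration is log-uniform over [9, 36]
    months (median 18 ~= the published 17.6); the riluzole fraction is a
    mixture with 80% mass on [0.7, 1] reflecting near-universal background
    riluzole in recent trials. OS arms are observed every ``os_dt`` months
    to ``os_horizon``; score arms every ``score_dt`` months to an
    arm-specific follow-up drawn from {3, 6, ..., 48}.
    """

    n_os_arms: int = 30
    n_score_arms: int = 29
    n_range: tuple = (11, 468)
    duration_range: tuple = (9.0, 36.0)
    riluzole_hi: tuple = (0.7, 1.0)
    riluzole_lo: tuple = (0.0, 0.7)
    riluzole_hi_weight: float = 0.8
    age_range: tuple = (51.0, 65.0)
    male_range: tuple = (0.45, 0.72)
    bulbar_range: tuple = (0.10, 0.45)
    baseline_alsfrs_range: tuple = (31.0, 43.0)
    pub_year_range: tuple = (1994, 2022)
    os_dt: float = 3.0
    os_horizon: float = 60.0
    score_dt: float = 3.0
    score_horizon_choices: tuple = tuple(range(3, 49, 3))
    os_params: OSParams = PLACEBO_OS_PARAMS
    emax_params: EmaxParams = PLACEBO_EMAX_PARAMS
    monotonize_os: bool = True
    seed: int = 0


def _draw_covariates(rng: np.random.Generator, cfg: GeneratorConfig,
                     with_baseline: bool) -> CovariateProfile:
    lo, hi = cfg.duration_range
    duration = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if rng.uniform() < cfg.riluzole_hi_weight:
        ril = float(rng.uniform(*cfg.riluzole_hi))
    else:
        ril = float(rng.uniform(*cfg.riluzole_lo))
    return CovariateProfile(
        duration_months=duration,
        riluzole_frac=ril,
        age_onset_years=float(rng.uniform(*cfg.age_range)),
        male_frac=float(rng.uniform(*cfg.male_range)),
        bulbar_frac=float(rng.uniform(*cfg.bulbar_range)),
        baseline_alsfrs=(float(rng.uniform(*cfg.baseline_alsfrs_range))
                         if with_baseline else None),
        basic_treatment=bool(rng.uniform() < 0.5),
        pub_year=int(rng.integers(cfg.pub_year_range[0],
                                  cfg.pub_year_range[1] + 1)),
    )


def _draw_n(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    lo, hi = cfg.n_range
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _os_series(rng, cfg, cov, n, eta, hazard_mult: float = 1.0,
               noise: bool = True):
    p = cfg.os_params
    t = np.arange(cfg.os_dt, cfg.os_horizon + 1e-9, cfg.os_dt)
    s = os_model.survival(t, cov, p, eta) ** hazard_mult
    y = os_model.to_obs_scale(s, p.obs_scale)
    if noise and p.eps_sd > 0:
        y = y + rng.normal(0.0, p.eps_sd * np.sqrt(REFERENCE_ARM_SIZE / n),
                           size=t.size)
    if cfg.monotonize_os:
        # digitized KM curves are monotone; project the noisy series onto
        # the non-increasing cone (PAVA), which is mean-preserving, rather
        # than taking a running minimum, which biases the curve downward
        y = -isotonic_regression(-y).x
    s_obs = os_model.from_obs_scale(y, p.obs_scale)
    s_obs = np.clip(s_obs, 1e-6, 1.0)
    s_obs = np.minimum.accumulate(s_obs)  # guard against clip-induced ties
    return tuple(SurvivalPoint(float(ti), float(si))
                 for ti, si in zip(t, s_obs))


def _score_series(rng, cfg, n, eta, emax_mult: float = 1.0,
                  noise: bool = True, horizon: float | None = None):
    p = cfg.emax_params
    if horizon is None:
        horizon = float(rng.choice(cfg.score_horizon_choices))
    t = np.arange(cfg.score_dt, horizon + 1e-9, cfg.score_dt)
    p_eff = replace(p, emax=min(p.emax * emax_mult, 48.0))
    y = alsfrs_model.typical_change(t, p_eff, eta)
    if noise and p.eps_sd > 0:
        y = y + rng.normal(0.0, p.eps_sd * np.sqrt(REFERENCE_ARM_SIZE / n),
                           size=t.size)
    y = np.clip(y, -48.0, 48.0)
    return tuple(ScorePoint(float(ti), float(yi)) for ti, yi in zip(t, y))


def generate(config: GeneratorConfig = GeneratorConfig()) -> Corpus:
    """Draw a full synthetic corpus (OS arms then score arms).

    With a fixed ``config.seed`` the output is identical on repeated calls.
    Setting the eta SDs and eps_sd of the structural parameter objects to
    zero yields observations exactly on the typical curves.
    """
    rng = np.random.default_rng(config.seed)
    arms = []
    osp, emp = config.os_params, config.emax_params
    for i in range(config.n_os_arms):
        cov = _draw_covariates(rng, config, with_baseline=False)
        n = _draw_n(rng, config)
        eta = rng.normal(0.0, [osp.eta_sd_sigm, osp.eta_sd_mu])
        arms.append(StudyArm(f"OS{i:03d}", n, cov,
                             os_series=_os_series(rng, config, cov, n, eta)))
    for i in range(config.n_score_arms):
        cov = _draw_covariates(rng, config, with_baseline=True)
        n = _draw_n(rng, config)
        eta = rng.normal(0.0, [emp.eta_sd_emax, emp.eta_sd_gamma])
        arms.append(StudyArm(f"FS{i:03d}", n, cov,
                             score_series=_score_series(rng, config, n, eta)))
    return Corpus(tuple(arms))


def generate_single_arm_trial(config: GeneratorConfig, effect: float,
                              endpoint: str = "OS",
                              seed: int | None = None) -> StudyArm:
    """One trial arm whose structural model is scaled by a treatment effect.

    ``effect`` multiplies the hazard (OS; < 1 means longer survival) or the
    maximal decline Emax (ALSFRS; < 1 means slower decline). effect = 1
    reproduces a placebo arm. Used as fixtures for external-control checks.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = _draw_covariates(rng, config, with_baseline=(endpoint == "ALSFRS"))
    n = _draw_n(rng, config)
    if endpoint == "OS":
        eta = rng.normal(0.0, [config.os_params.eta_sd_sigm,
                               config.os_params.eta_sd_mu])
        series = _os_series(rng, config, cov, n, eta, hazard_mult=effect)
        return StudyArm("TRIAL", n, cov, os_series=series)
    if endpoint == "ALSFRS":
        eta = rng.normal(0.0, [config.emax_params.eta_sd_emax,
                               config.emax_params.eta_sd_gamma])
        series = _score_series(rng, config, n, eta, emax_mult=effect,
                               horizon=12.0)
        return StudyArm("TRIAL", n, cov, score_series=series)
    raise ValueError(f"unknown endpoint {endpoint!r}")
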