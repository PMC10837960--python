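"""Subgroup analysis by random-effects meta-analysis of per-study
empirical-Bayes parameters.

Arms are split into predefined subgroups (median split for continuous
covariates, a fixed cut for publication year, the flag itself for basic
treatment). Within each level, the per-study parameter estimates (on the
log scale, covariate effects already referenced out) are pooled with a
DerSimonian-Laird random-effects model, and the pooled distribution is
propagated to the course summary (median OS, or ALSFRS change at 12 months)
by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trial_data import Corpus, CovariateProfile
from . import os_model, alsfrs_model
from .nlme_fit import FitResult, empirical_bayes

__all__ = ["SubgroupSpec", "PooledEffect", "pool_random_effects",
           "subgroup_analysis", "PUB_YEAR_CUT"]

#: Publication-year subgroup cut: arms published before vs since this year.
PUB_YEAR_CUT = 2009


@dataclass(frozen=True)
class SubgroupSpec:
    """A subgroup split rule.

    For continuous covariates ``cutpoint`` None means the corpus median,
    recomputed from the loaded corpus. ``pub_year`` defaults to the 2009
    cut; ``basic_treatment`` splits on the flag.
    """

    variable: str
    cutpoint: Optional[float] = None


@dataclass(frozen=True)
class PooledEffect:
    """DerSimonian-Laird pooled estimate."""

    mean: float
    se: float
    tau2: float
    k: int
    q: float


def pool_random_effects(estimates: Sequence[float],
                        ses: Sequence[float]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; the pooled mean uses w* = 1/(se^2 + tau^2) and the
    pooled SE is 1/sqrt(sum w*). A single study is returned unchanged with
    tau^2 = 0.
    """
    x = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if x.size == 0:
        raise ValueError("pool_random_effects needs at least one study")
    if x.size != s.size:
        raise ValueError("estimates and ses differ in length")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = x.size
    if k == 1:
        return PooledEffect(float(x[0]), float(s[0]), 0.0, 1, 0.0)
    w = 1.0 / s ** 2
    xbar_fe = float((w * x).sum() / w.sum())
    q = float((w * (x - xbar_fe) ** 2).sum())
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s ** 2 + tau2)
    mean = float((w_star * x).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    return PooledEffect(mean, se, float(tau2), k, q)


def _assign(corpus: Corpus, fit: FitResult, spec: SubgroupSpec):
    """Split the endpoint arms into labeled groups; missing-covariate arms
    are excluded."""
    arms = [a for a in corpus.subset(fit.endpoint)
            if a.study_id in fit.eb_effects]
    if spec.variable == "basic_treatment":
        get = lambda a: a.covariates.basic_treatment
        groups = {"basic_treatment=yes": [], "basic_treatment=no": []}
        for a in arms:
            v = get(a)
            if v is None:
                continue
            groups["basic_treatment=yes" if v else "basic_treatment=no"].append(a)
        return groups
    if spec.variable == "sample_size":
        vals = {a.study_id: float(a.n) for a in arms}
    else:
        vals = {a.study_id: a.covariates.get(spec.variable) for a in arms}
        vals = {k: float(v) for k, v in vals.items() if v is not None}
    arms = [a for a in arms if a.study_id in vals]
    if not arms:
        return {}
    if spec.cutpoint is not None:
        cut = spec.cutpoint
    elif spec.variable == "pub_year":
        cut = PUB_YEAR_CUT
    else:
        cut = float(np.median(list(vals.values())))
    lo = [a for a in arms if vals[a.study_id] < cut]
    hi = [a for a in arms if vals[a.study_id] >= cut]
    return {f"{spec.variable}<{cut:g}": lo, f"{spec.variable}>={cut:g}": hi}


def _course_summary_draws(fit: FitResult, pooled: dict, n_mc: int,
                          rng: np.random.Generator,
                          ref_cov: CovariateProfile):
    """Monte Carlo the course summary from pooled log-parameter
    distributions, other parameters held at the point estimates."""
    params = fit.params
    out = np.empty(n_mc)
    for i in range(n_mc):
        if fit.endpoint == "OS":
            p = dc_replace(params,
                           sigm=np.exp(rng.normal(*pooled["sigm"])),
                           mu=np.exp(rng.normal(*pooled["mu"])),
                           theta_duration=0.0, theta_riluzole=0.0)
            try:
                out[i] = os_model.median_os(ref_cov, p)
            except ValueError:
                out[i] = np.nan
        else:
            p = dc_replace(params,
                           emax=min(np.exp(rng.normal(*pooled["emax"])), 48.0),
                           gamma=np.exp(rng.normal(*pooled["gamma"])))
            out[i] = alsfrs_model.typical_change(12.0, p)
    return out[np.isfinite(out)]


def subgroup_analysis(fit: FitResult, corpus: Corpus,
                      specs: Sequence[SubgroupSpec], n_mc: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Pooled typical values with 95% CI per predefined subgroup.

    Per subgroup level: the per-study empirical-Bayes estimates of the
    random-effect-bearing parameters are pooled on the log scale with
    :func:`pool_random_effects`; the pooled normal distributions are then
    propagated to the course summary (median OS at the reference covariate
    profile for OS fits; ALSFRS-R change at 12 months otherwise) with
    ``n_mc`` Monte Carlo draws. Empty levels are omitted.

    Returns a forest-plot-style frame: variable, level, k, pooled summary
    median, lo95, hi95.
    """
    eb = empirical_bayes(fit, corpus)
    eb = eb.set_index("study_id")
    pnames = [c for c in ("sigm", "mu", "emax", "gamma") if c in eb.columns]
    ref_cov = CovariateProfile(duration_months=17.8, riluzole_frac=0.9)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        groups = _assign(corpus, fit, spec)
        for level, arms in groups.items():
            if not arms:
                continue
            ids = [a.study_id for a in arms]
            pooled = {}
            for p in pnames:
                x = np.log(eb.loc[ids, p].to_numpy(dtype=float))
                s = (eb.loc[ids, f"se_{p}"].to_numpy(dtype=float)
                     / eb.loc[ids, p].to_numpy(dtype=float))
                s = np.maximum(s, 1e-6)
                pe = pool_random_effects(x, s)
                pooled[p] = (pe.mean, np.sqrt(pe.se ** 2 + 0.0))
            draws = _course_summary_draws(fit, pooled, n_mc, rng, ref_cov)
            lo, mid, hi = np.percentile(draws, [2.5, 50.0, 97.5])
            rows.append({"variable": spec.variable, "level": level,
                         "k": len(ids), "estimate": mid,
                         "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows, columns=["variable", "level", "k", "estimate",
                                       "lo95", "hi95"])
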