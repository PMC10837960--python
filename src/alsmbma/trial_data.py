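"""Containers and I/O for aggregate arm-level trial data.

The analysis operates on placebo arms extracted from published ALS trials.
Each arm carries study-level covariates, the arm sample size, and one or two
observation series: digitized Kaplan-Meier survival proportions (overall
survival, OS) and/or mean change from baseline in the revised ALS Functional
Rating Scale (ALSFRS-R, 0-48 points).

The on-disk format is a long CSV with one row per observation; see
:func:`read_corpus` for the schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateProfile",
    "SurvivalPoint",
    "ScorePoint",
    "StudyArm",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "summarize_corpus",
    "CorpusValidationError",
]

#: Columns of the long-CSV interchange format, in canonical order.
CSV_COLUMNS = [
    "study_id", "n", "endpoint", "time_months", "value", "se",
    "duration_months", "riluzole_frac", "age_onset_years", "male_frac",
    "bulbar_frac", "baseline_alsfrs", "basic_treatment", "pub_year",
]

_REQUIRED_COLUMNS = ["study_id", "n", "endpoint", "time_months", "value",
                     "duration_months", "riluzole_frac"]


class CorpusValidationError(ValueError):
    """Raised when input data violate the arm-level invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise CorpusValidationError(msg)


@dataclass(frozen=True)
class CovariateProfile:
    """Study-level covariates of one placebo arm.

    duration_months
        Time from first symptom onset to enrollment, months (> 0).
    riluzole_frac
        Proportion of patients on riluzole background therapy, in [0, 1].

    The remaining covariates are optional and only used by analyses that
    request them (covariate search, subgroup analysis).
    """

    duration_months: float
    riluzole_frac: float
    age_onset_years: Optional[float] = None
    male_frac: Optional[float] = None
    bulbar_frac: Optional[float] = None
    baseline_alsfrs: Optional[float] = None
    basic_treatment: Optional[bool] = None
    pub_year: Optional[int] = None

    def __post_init__(self) -> None:
        _check(self.duration_months > 0, "duration_months must be > 0")
        for name in ("riluzole_frac", "male_frac", "bulbar_frac"):
            v = getattr(self, name)
            if v is not None:
                _check(0.0 <= v <= 1.0, f"{name}={v} outside [0, 1]")
        if self.baseline_alsfrs is not None:
            _check(0.0 <= self.baseline_alsfrs <= 48.0,
                   f"baseline_alsfrs={self.baseline_alsfrs} outside [0, 48]")

    def get(self, name: str):
        """Covariate value by field name (None if missing)."""
        return getattr(self, name)


@dataclass(frozen=True)
class SurvivalPoint:
    """One digitized Kaplan-Meier point: S(time_months) = surv_prob in (0, 1]."""

    time_months: float
    surv_prob: float

    def __post_init__(self) -> None:
        _check(self.time_months >= 0, "time_months must be >= 0")
        _check(0.0 < self.surv_prob <= 1.0,
               f"surv_prob={self.surv_prob} outside (0, 1]")


@dataclass(frozen=True)
class ScorePoint:
    """Mean ALSFRS-R change from baseline (points; decline is negative)."""

    time_months: float
    mean_change: float
    se: Optional[float] = None

    def __post_init__(self) -> None:
        _check(self.time_months > 0, "time_months must be > 0")
        _check(abs(self.mean_change) <= 48.0,
               f"|mean_change|={abs(self.mean_change)} exceeds 48")
        if self.se is not None:
            _check(self.se > 0, "se must be positive when given")


@dataclass(frozen=True)
class StudyArm:
    """One placebo arm: covariates, sample size and observation series."""

    study_id: str
    n: int
    covariates: CovariateProfile
    os_series: tuple = ()
    score_series: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "os_series", tuple(self.os_series))
        object.__setattr__(self, "score_series", tuple(self.score_series))
        _check(self.n >= 11, f"arm {self.study_id}: n={self.n} < 11 "
               "(inclusion requires sample size greater than 10)")
        _check(len(self.os_series) + len(self.score_series) > 0,
               f"arm {self.study_id}: both series empty")
        for label, series in (("os", self.os_series), ("score", self.score_series)):
            times = [p.time_months for p in series]
            _check(all(b > a for a, b in zip(times, times[1:])),
                   f"arm {self.study_id}: {label} times not strictly increasing")
        probs = [p.surv_prob for p in self.os_series]
        _check(all(b <= a + 1e-12 for a, b in zip(probs, probs[1:])),
               f"arm {self.study_id}: survival proportions increase over time")

    @property
    def has_os(self) -> bool:
        return len(self.os_series) > 0

    @property
    def has_score(self) -> bool:
        return len(self.score_series) > 0


@dataclass(frozen=True)
class Corpus:
    """A collection of study arms with unique study identifiers."""

    arms: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        ids = [a.study_id for a in self.arms]
        _check(len(ids) == len(set(ids)), "duplicate study_id in corpus")

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    def subset(self, endpoint: str) -> "Corpus":
        """Arms carrying the given endpoint ('OS' or 'ALSFRS')."""
        if endpoint == "OS":
            return Corpus(tuple(a for a in self.arms if a.has_os))
        if endpoint == "ALSFRS":
            return Corpus(tuple(a for a in self.arms if a.has_score))
        raise ValueError(f"unknown endpoint {endpoint!r}")


def _opt(v):
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else v


def read_corpus(path) -> Corpus:
    """Read a long-CSV corpus (one row per observation).

    Required columns: study_id, n, endpoint (OS|ALSFRS), time_months, value,
    duration_months, riluzole_frac. Optional: se, age_onset_years, male_frac,
    bulbar_frac, baseline_alsfrs, basic_treatment (0/1), pub_year.
    For endpoint=OS, ``value`` is a survival proportion in (0, 1]; for
    endpoint=ALSFRS it is the mean change from baseline in points.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusValidationError(f"missing required column(s): {missing}")
    for c in CSV_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan

    arms = []
    for study_id, grp in df.groupby("study_id", sort=False):
        first = grp.iloc[0]
        cov = CovariateProfile(
            duration_months=float(first["duration_months"]),
            riluzole_frac=float(first["riluzole_frac"]),
            age_onset_years=_opt(first["age_onset_years"]),
            male_frac=_opt(first["male_frac"]),
            bulbar_frac=_opt(first["bulbar_frac"]),
            baseline_alsfrs=_opt(first["baseline_alsfrs"]),
            basic_treatment=(None if _opt(first["basic_treatment"]) is None
                             else bool(int(first["basic_treatment"]))),
            pub_year=(None if _opt(first["pub_year"]) is None
                      else int(first["pub_year"])),
        )
        os_pts, score_pts = [], []
        for idx, row in grp.iterrows():
            ep = str(row["endpoint"]).strip().upper()
            if ep == "OS":
                try:
                    os_pts.append(SurvivalPoint(float(row["time_months"]),
                                                float(row["value"])))
                except CorpusValidationError as e:
                    raise CorpusValidationError(
                        f"row {idx} (study {study_id}): {e}") from e
            elif ep == "ALSFRS":
                score_pts.append(ScorePoint(float(row["time_months"]),
                                            float(row["value"]),
                                            se=_opt(row["se"])))
            else:
                raise CorpusValidationError(
                    f"row {idx}: unknown endpoint {row['endpoint']!r}")
        os_pts.sort(key=lambda p: p.time_months)
        score_pts.sort(key=lambda p: p.time_months)
        for label, pts in (("OS", os_pts), ("ALSFRS", score_pts)):
            times = [p.time_months for p in pts]
            if len(set(times)) != len(times):
                raise CorpusValidationError(
                    f"study {study_id}: duplicate {label} time points")
        arms.append(StudyArm(str(study_id), int(first["n"]), cov,
                             tuple(os_pts), tuple(score_pts)))
    return Corpus(tuple(arms))


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus in the long-CSV interchange format (see read_corpus)."""
    rows = []
    for arm in corpus:
        cov = arm.covariates
        base = {
            "study_id": arm.study_id, "n": arm.n,
            "duration_months": cov.duration_months,
            "riluzole_frac": cov.riluzole_frac,
            "age_onset_years": cov.age_onset_years,
            "male_frac": cov.male_frac,
            "bulbar_frac": cov.bulbar_frac,
            "baseline_alsfrs": cov.baseline_alsfrs,
            "basic_treatment": (None if cov.basic_treatment is None
                                else int(cov.basic_treatment)),
            "pub_year": cov.pub_year,
        }
        for p in arm.os_series:
            rows.append({**base, "endpoint": "OS", "time_months": p.time_months,
                         "value": p.surv_prob, "se": None})
        for p in arm.score_series:
            rows.append({**base, "endpoint": "ALSFRS",
                         "time_months": p.time_months,
                         "value": p.mean_change, "se": p.se})
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if float(x) == int(x) and abs(x) < 1e6:
        return str(int(x))
    return f"{x:.4g}"


_SUMMARY_FIELDS = [
    ("sample_size", lambda a: a.n),
    ("age_onset_years", lambda a: a.covariates.age_onset_years),
    ("male_frac", lambda a: a.covariates.male_frac),
    ("duration_months", lambda a: a.covariates.duration_months),
    ("riluzole_frac", lambda a: a.covariates.riluzole_frac),
    ("bulbar_frac", lambda a: a.covariates.bulbar_frac),
    ("baseline_alsfrs", lambda a: a.covariates.baseline_alsfrs),
    ("pub_year", lambda a: a.covariates.pub_year),
]


def summarize_corpus(corpus: Corpus) -> pd.DataFrame:
    """Corpus characteristics as "median (min-max)" strings, split by endpoint.

    Returns a DataFrame indexed by characteristic with columns OS / ALSFRS /
    ALL. The first row counts arms; covariates that are missing in every arm
    of a column are reported as "NA".
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    cols = {}
    for label, arms in (("OS", corpus.subset("OS").arms),
                        ("ALSFRS", corpus.subset("ALSFRS").arms),
                        ("ALL", corpus.arms)):
        col = {"n_arms": str(len(arms))}
        for name, getter in _SUMMARY_FIELDS:
            vals = np.array([float(getter(a)) for a in arms
                             if getter(a) is not None], dtype=float)
            if vals.size == 0:
                col[name] = "NA"
            else:
                col[name] = (f"{_fmt(float(np.median(vals)))} "
                             f"({_fmt(float(vals.min()))}–{_fmt(float(vals.max()))})")
        cols[label] = col
    return pd.DataFrame(cols)
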