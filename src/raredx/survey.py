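"""Summaries of the specialist-consultation survey.

Respondents are patients with a physician-confirmed diagnosis who answered
a questionnaire on recurrent epistaxis (nosebleeds) and on whether they had
consulted an ear-nose-throat (ENT) or emergency-room (ER) physician for it
*before* being diagnosed.  The summary reproduces the standard table shape:
response proportion, demographic proportions, mean +/- SD ages, and the
mean consult-to-diagnosis interval in years — the headline measure of how
long a diagnosable patient sat in front of the wrong specialist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, SummaryError


@dataclass(frozen=True)
class SurveyRespondent:
    respondent_id: str
    physician_dx: bool
    age_now: float
    age_dx: float
    female: bool = False
    north_american: bool = False
    epistaxis: bool = False
    ent_consult_before_dx: bool = False
    age_first_ent: float | None = None
    er_consult_before_dx: bool = False
    age_first_er: float | None = None


@dataclass
class SurveySummary:
    """Table-shaped survey summary.  All percentages at full precision;
    mean/SD pairs are ``None`` when the defining subset is empty."""
    n_respondents: int
    n_contacts: int
    n_excluded_no_physician_dx: int
    response_percent: float
    female_percent: float
    north_american_percent: float
    epistaxis_percent: float
    ent_percent: float
    er_percent: float
    age_now_mean_sd: tuple[float, float] | None
    age_dx_mean_sd: tuple[float, float] | None
    age_first_ent_mean_sd: tuple[float, float] | None
    age_first_er_mean_sd: tuple[float, float] | None
    ent_interval_mean_sd: tuple[float, float] | None
    er_interval_mean_sd: tuple[float, float] | None


def _validate(r: SurveyRespondent) -> list[str]:
    problems = []
    if r.age_now < 0 or r.age_dx < 0:
        problems.append("negative age")
    if r.age_dx > r.age_now + 1e-9:
        problems.append("age at diagnosis exceeds current age")
    for flag, age, label in ((r.ent_consult_before_dx, r.age_first_ent, "ENT"),
                             (r.er_consult_before_dx, r.age_first_er, "ER")):
        if flag and age is None:
            problems.append(f"{label} consult flagged but consult age absent")
        if not flag and age is not None:
            problems.append(f"{label} consult age present without flag")
        if flag and age is not None:
            if age < 0:
                problems.append(f"negative {label} consult age")
            if age > r.age_dx + 1e-9:
                problems.append(f"{label} consult age exceeds age at diagnosis")
    return problems


def consult_interval(r: SurveyRespondent, kind: str = "ent") -> float | None:
    """Years from first consult (ENT by default) to diagnosis; None if no
    pre-diagnosis consult of that kind is recorded."""
    if kind == "ent":
        flag, age = r.ent_consult_before_dx, r.age_first_ent
    elif kind == "er":
        flag, age = r.er_consult_before_dx, r.age_first_er
    else:
        raise ValueError(f"unknown consult kind {kind!r}")
    if not flag or age is None:
        return None
    interval = r.age_dx - age
    if interval < -1e-9:
        raise DataError(f"respondent {r.respondent_id}: negative {kind} consult interval")
    return interval


def _mean_sd(values: Sequence[float]) -> tuple[float, float] | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def summarize_survey(respondents: Sequence[SurveyRespondent], n_contacts: int) -> SurveySummary:
    """Summarize respondent records against the number of survey contacts.

    Respondents without a physician-confirmed diagnosis are excluded first
    (the survey's target population), with the excluded count reported.
    Proportions are over the full retained respondent set; means +/- SD
    (sample SD, n-1) are over the subsets where each quantity is defined.
    """
    retained = [r for r in respondents if r.physician_dx]
    excluded = len(respondents) - len(retained)
    if not retained:
        raise SummaryError("no respondents with a physician-confirmed diagnosis")
    if n_contacts < len(retained):
        raise DataError("n_contacts smaller than the respondent count")

    errors = []
    for r in retained:
        for p in _validate(r):
            errors.append(f"{r.respondent_id}: {p}")
    if errors:
        raise DataError("invalid respondent records:\n" + "\n".join(errors[:20]))

    n = len(retained)
    pct = lambda k: 100.0 * k / n
    ent_intervals = [consult_interval(r, "ent") for r in retained]
    er_intervals = [consult_interval(r, "er") for r in retained]
    return SurveySummary(
        n_respondents=n,
        n_contacts=n_contacts,
        n_excluded_no_physician_dx=excluded,
        response_percent=100.0 * n / n_contacts,
        female_percent=pct(sum(r.female for r in retained)),
        north_american_percent=pct(sum(r.north_american for r in retained)),
        epistaxis_percent=pct(sum(r.epistaxis for r in retained)),
        ent_percent=pct(sum(r.ent_consult_before_dx for r in retained)),
        er_percent=pct(sum(r.er_consult_before_dx for r in retained)),
        age_now_mean_sd=_mean_sd([r.age_now for r in retained]),
        age_dx_mean_sd=_mean_sd([r.age_dx for r in retained]),
        age_first_ent_mean_sd=_mean_sd(
            [r.age_first_ent for r in retained if r.age_first_ent is not None]),
        age_first_er_mean_sd=_mean_sd(
            [r.age_first_er for r in retained if r.age_first_er is not None]),
        ent_interval_mean_sd=_mean_sd([v for v in ent_intervals if v is not None]),
        er_interval_mean_sd=_mean_sd([v for v in er_intervals if v is not None]),
    )


def format_summary(summary: SurveySummary) -> dict[str, str]:
    """Render a summary the way published tables print it: integer percents
    and one-decimal means/SDs."""
    out = {
        "Proportion of respondents (%)":
            f"{summary.n_respondents}/{summary.n_contacts} ({round(summary.response_percent)} %)",
        "Proportion of females (%)": f"{round(summary.female_percent)} %",
        "Proportion of North Americans (%)": f"{round(summary.north_american_percent)} %",
        "Proportion with recurrent epistaxis (%)": f"{round(summary.epistaxis_percent)} %",
        "Proportion with ENT consult prior to diagnosis (%)": f"{round(summary.ent_percent)} %",
        "Proportion with ER consult prior to diagnosis (%)": f"{round(summary.er_percent)} %",
    }
    pairs = {
        "Mean age +/- SD at time of survey": summary.age_now_mean_sd,
        "Mean age +/- SD at time of diagnosis": summary.age_dx_mean_sd,
        "Mean age +/- SD at first ENT consult": summary.age_first_ent_mean_sd,
        "Mean age +/- SD at first ER consult": summary.age_first_er_mean_sd,
        "Mean interval from first ENT consult to diagnosis": summary.ent_interval_mean_sd,
        "Mean interval from first ER consult to diagnosis": summary.er_interval_mean_sd,
    }
    for label, ms in pairs.items():
        if ms is not None and not any(map(math.isnan, ms)):
            out[label] = f"{ms[0]:.1f} +/- {ms[1]:.1f} years"
    return out
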