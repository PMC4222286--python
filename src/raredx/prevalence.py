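"""Diagnosed-prevalence (D-prevalence) analysis.

Takes a registry cohort of diagnosed patients and census denominators and
produces: the geocoding/exclusion funnel, crude rates per 5000 adults by
region set and age band, urban/rural and city-size stratifications,
chi-square comparisons of rates, a city-size-versus-rate regression, and a
benchmark-based under-diagnosis estimate (the fraction of true cases the
registry is presumed to miss, taking the highest large-city rate as a proxy
for the true prevalence).

Age bands are decade-aligned because census denominators are only published
by age decade; 20-49 is the union of the 20s/30s/40s decades and 50+ all
later ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_BANDS, AGE_DECADES, decades_in_band
from .errors import ConfigurationError, DataError, FitError, InconsistencyError

DEFAULT_SCALE = 5000  # rates are reported per this many adults


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseRecord:
    """One registry patient with region assignment and exclusion flags."""
    patient_id: str
    region_code: str
    age_years: int
    deceased: bool = False
    address_missing: bool = False
    out_of_study_area: bool = False
    geocode_failed: bool = False


@dataclass(frozen=True)
class CensusUnit:
    """A census geography with centroid, decade populations and metro flag."""
    unit_id: str
    unit_type: str                      # "CSD" or "DA"
    centroid: tuple[float, float]       # planar metres
    population_by_decade: Mapping[str, int]
    in_cma: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        for d, p in self.population_by_decade.items():
            if d not in AGE_DECADES:
                raise DataError(f"unit {self.unit_id}: unknown decade {d!r}")
            if p < 0:
                raise DataError(f"unit {self.unit_id}: negative population in {d}")

    @property
    def adult_population(self) -> int:
        return int(sum(self.population_by_decade.values()))

    def band_population(self, band: str) -> int:
        return int(sum(self.population_by_decade.get(d, 0) for d in decades_in_band(band)))


@dataclass
class FunnelReport:
    """Stage counts of the geocoding/exclusion funnel.

    Stage 1 removes deceased patients and those with no recorded address;
    stage 2 removes patients outside the study area and geocoding failures.
    A record matching several flags is counted once, under the first flag in
    funnel order, so included + all removals = input.
    """
    n_input: int
    removed: dict[str, int]
    n_after_stage1: int
    n_included: int


@dataclass
class PrevalenceCell:
    """Case count, denominator and crude rate for one (region set, band)."""
    region_set: frozenset[str]
    age_band: str
    case_count: int
    population: int
    scale: int = DEFAULT_SCALE

    @property
    def rate(self) -> float | None:
        """Crude rate per ``scale`` adults; None (undefined) if uninhabited."""
        if self.population == 0:
            return None
        return self.scale * self.case_count / self.population

    @property
    def rate_per_5000(self) -> float | None:
        if self.population == 0:
            return None
        return 5000 * self.case_count / self.population


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class UnderdiagnosisEstimate:
    """Benchmark-based estimate of the undiagnosed share of cases.

    The benchmark rate (e.g. the highest diagnosed rate seen in any large
    city) is taken as a proxy for the true prevalence; the undiagnosed
    fraction is 1 - overall/benchmark and the implied counts follow from
    applying the benchmark rate to the whole study population.
    """
    overall_rate_per_5000: float
    benchmark_rate_per_5000: float
    total_population: int
    diagnosed_count: int

    @property
    def undiagnosed_fraction(self) -> float:
        return 1.0 - self.overall_rate_per_5000 / self.benchmark_rate_per_5000

    @property
    def implied_true_cases(self) -> float:
        return self.benchmark_rate_per_5000 * self.total_population / 5000.0

    @property
    def implied_undiagnosed_count(self) -> float:
        return self.implied_true_cases - self.diagnosed_count


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

_FUNNEL_FLAGS_STAGE1 = ("deceased", "address_missing")
_FUNNEL_FLAGS_STAGE2 = ("out_of_study_area", "geocode_failed")


def apply_geocoding_funnel(cases: Sequence[CaseRecord]) -> tuple[list[CaseRecord], FunnelReport]:
    """Apply the two-stage exclusion funnel and account for every record."""
    ids = Counter(c.patient_id for c in cases)
    dups = sorted(i for i, n in ids.items() if n > 1)
    if dups:
        raise DataError(f"duplicate patient ids: {dups[:10]}")

    removed = {f: 0 for f in _FUNNEL_FLAGS_STAGE1 + _FUNNEL_FLAGS_STAGE2}
    after1: list[CaseRecord] = []
    for c in cases:
        for flag in _FUNNEL_FLAGS_STAGE1:
            if getattr(c, flag):
                removed[flag] += 1
                break
        else:
            after1.append(c)
    included: list[CaseRecord] = []
    for c in after1:
        for flag in _FUNNEL_FLAGS_STAGE2:
            if getattr(c, flag):
                removed[flag] += 1
                break
        else:
            included.append(c)
    report = FunnelReport(n_input=len(cases), removed=removed,
                          n_after_stage1=len(after1), n_included=len(included))
    return included, report


def compute_prevalence(cases: Sequence[CaseRecord], units: Sequence[CensusUnit],
                       region_set: Iterable[str] | None = None,
                       age_band: str = "all", scale: int = DEFAULT_SCALE) -> PrevalenceCell:
    """Crude diagnosed rate for one region set and age band.

    ``region_set=None`` means all units.  Every case's region code must
    resolve to a unit; cases in uninhabited regions raise an inconsistency
    error, while an uninhabited region with no cases yields an *undefined*
    rate (``rate is None``) rather than zero.
    """
    if age_band not in AGE_BANDS:
        raise ConfigurationError(f"unknown age band {age_band!r}")
    by_id = {u.unit_id: u for u in units}
    regions = frozenset(by_id) if region_set is None else frozenset(region_set)
    unknown_regions = regions - set(by_id)
    if unknown_regions:
        raise DataError(f"region set references unknown units: {sorted(unknown_regions)[:10]}")

    unresolved = sorted({c.region_code for c in cases} - set(by_id))
    if unresolved:
        raise DataError(f"cases with unresolvable region codes: {unresolved[:10]}")

    lo, hi = AGE_BANDS[age_band]
    count = sum(1 for c in cases
                if c.region_code in regions and lo <= c.age_years < hi)
    population = sum(by_id[r].band_population(age_band) for r in regions)
    if population == 0 and count > 0:
        raise InconsistencyError(
            f"{count} cases recorded in uninhabited region set (band {age_band})")
    return PrevalenceCell(region_set=regions, age_band=age_band,
                          case_count=count, population=population, scale=scale)


def classify_urban_rural(units: Sequence[CensusUnit],
                         min_urban_pop: int = 1000) -> dict[str, str]:
    """Urban iff inside a metropolitan area AND adult population >= threshold."""
    return {
        u.unit_id: "urban" if (u.in_cma and u.adult_population >= min_urban_pop) else "rural"
        for u in units
    }


def filter_cities(units: Sequence[CensusUnit], min_pop: float) -> list[CensusUnit]:
    """Units whose adult (>=20) population meets the size threshold."""
    if min_pop < 0:
        raise ConfigurationError("min_pop must be >= 0")
    return [u for u in units if u.adult_population >= min_pop]


def chi_square_compare(count_a: int, pop_a: int, count_b: int, pop_b: int,
                       correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 case/non-case by group table.

    No continuity correction by default (denominators here are whole census
    populations, where the correction is immaterial).
    """
    for name, (c, p) in {"a": (count_a, pop_a), "b": (count_b, pop_b)}.items():
        if c < 0 or p < 0 or c > p:
            raise DataError(f"group {name}: need 0 <= count <= population")
    table = np.array([[count_a, pop_a - count_a], [count_b, pop_b - count_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(table, correction=correction)
    return ChiSquareResult(statistic=float(res.statistic), df=int(res.dof),
                           p_value=float(res.pvalue))


def fit_population_vs_prevalence(cities: Sequence[PrevalenceCell]) -> tuple[float, float, float]:
    """OLS of city rate (per scale) on city adult population.

    Returns ``(slope, intercept, r_squared)``.  Cities with undefined rates
    are not accepted; at least two cities and a non-degenerate population
    spread are required.
    """
    pts = [(c.population, c.rate) for c in cities]
    if any(r is None for _, r in pts):
        raise FitError("cities with undefined rates cannot enter the fit")
    if len(pts) < 2:
        raise FitError("need at least 2 cities with defined rates")
    x = np.array([p for p, _ in pts], dtype=float)
    y = np.array([r for _, r in pts], dtype=float)
    if np.var(x) == 0:
        raise FitError("zero variance in city population")
    if np.var(y) == 0:
        # constant rates: flat line, no explainable variance
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def estimate_underdiagnosis(overall: PrevalenceCell | float,
                            benchmark_rate_per_5000: float,
                            diagnosed_count: int,
                            total_population: int) -> UnderdiagnosisEstimate:
    """Benchmark-based under-diagnosis estimate (see UnderdiagnosisEstimate)."""
    rate = overall.rate_per_5000 if isinstance(overall, PrevalenceCell) else float(overall)
    if rate is None or rate <= 0:
        raise DataError("overall rate must be positive and defined")
    if benchmark_rate_per_5000 < rate:
        raise DataError(
            f"benchmark rate {benchmark_rate_per_5000} below overall rate {rate}")
    return UnderdiagnosisEstimate(
        overall_rate_per_5000=rate,
        benchmark_rate_per_5000=float(benchmark_rate_per_5000),
        total_population=int(total_population),
        diagnosed_count=int(diagnosed_count))


def prevalence_table(cases: Sequence[CaseRecord], units: Sequence[CensusUnit],
                     bands: Sequence[str] = ("20-49", "50+"),
                     scale: int = DEFAULT_SCALE) -> pd.DataFrame:
    """Per-city prevalence table: population, cases, and per-band rates.

    Mirrors the usual published layout (one row per city, a column of total
    confirmed cases, and one rate column per age band).  Rates are left at
    full precision; round at the reporting layer.
    """
    rows = []
    for u in units:
        row: dict = {"city": u.name or u.unit_id, "unit_id": u.unit_id,
                     "population": u.adult_population}
        row["cases"] = compute_prevalence(cases, units, {u.unit_id}, "all", scale).case_count
        for band in bands:
            cell = compute_prevalence(cases, units, {u.unit_id}, band, scale)
            row[f"rate_{band}_per_{scale}"] = cell.rate
        rows.append(row)
    return pd.DataFrame(rows)
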