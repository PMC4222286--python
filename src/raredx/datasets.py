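"""Published summary inputs for the Ontario HHT under-diagnosis analysis.

The underlying patient and survey microdata are not public; what IS public
are the printed summary tables of the provincial registry study: the
geocoding funnel counts, the six very-large-city rows (adult population and
confirmed case counts), the province-wide age-band case counts and rates,
the survey margins, and the benchmark rate used for the under-diagnosis
estimate.  This module encodes those published numbers as package inputs
and provides fixtures that re-expand them into record-level objects.

All record-level fixtures here are SYNTHETIC re-expansions: they reproduce
the published counts exactly, but ages and identifiers are placeholders
(constructed, not observed).
"""

from __future__ import annotations

import pandas as pd

from .config import AGE_DECADES, _DEFAULT_AGE_WEIGHTS
from .prevalence import CaseRecord, CensusUnit
from .survey import SurveyRespondent

#: 2006 census adult (>=20) population of Ontario.
ONTARIO_ADULT_POPULATION = 9_116_380

#: Patients included after geocoding (the diagnosed count in the estimate).
DIAGNOSED_COUNT = 556

#: Province-wide diagnosed rate per 5000 as printed (~0.31).
REPORTED_OVERALL_RATE_PER_5000 = 0.31

#: Highest diagnosed rate per 5000 observed in a large (>=50k) city; the
#: benchmark proxy for true prevalence in the under-diagnosis estimate.
BENCHMARK_RATE_PER_5000 = 1.1

#: Geocoding funnel stage counts: 627 registry patients, two exclusion
#: stages (deceased / no address, then out-of-province / geocode failure).
FUNNEL_COUNTS = {
    "total": 627,
    "deceased": 35,
    "address_missing": 1,
    "out_of_study_area": 28,
    "geocode_failed": 7,
    "included": 556,
}

#: Province-wide diagnosed case counts and printed rates per 5000 by band.
AGE_BAND_CASES = {"20-49": 275, "50+": 281}
AGE_BAND_RATES_PER_5000 = {"20-49": 0.26, "50+": 0.36}

#: The six very-large (>=250,000 adults) cities: adult population, total
#: confirmed cases, and printed per-band rates per 5000.
VERY_LARGE_CITY_TABLE = pd.DataFrame(
    [
        ("London", 267_145, 14, 0.22, 0.31),
        ("Brampton", 303_700, 16, 0.20, 0.40),
        ("Hamilton", 379_780, 26, 0.24, 0.48),
        ("Mississauga", 486_270, 16, 0.16, 0.17),
        ("Ottawa", 614_770, 20, 0.16, 0.16),
        ("Toronto", 1_947_455, 134, 0.25, 0.48),
    ],
    columns=["city", "adult_population", "cases",
             "rate_20_49_per_5000", "rate_50plus_per_5000"],
)

#: Survey margins: 940 respondents of 2836 contacts; counts by item.
SURVEY_COUNTS = {
    "contacts": 2836,
    "respondents": 940,
    "female": 630,
    "north_american": 738,
    "epistaxis": 807,
    "ent_consult": 349,
    "er_consult": 154,
}


def band_populations_from_rates() -> dict[str, float]:
    """Back-compute the province-wide band denominators from the printed
    band rates: population = count * 5000 / rate."""
    return {band: AGE_BAND_CASES[band] * 5000 / AGE_BAND_RATES_PER_5000[band]
            for band in AGE_BAND_CASES}


def _spread_over_decades(total: int) -> dict[str, int]:
    """Allocate an adult population across decades with the default decade
    weights, largest-remainder rounding, exact conservation."""
    shares = {d: total * _DEFAULT_AGE_WEIGHTS[d] for d in AGE_DECADES}
    floors = {d: int(shares[d]) for d in AGE_DECADES}
    short = total - sum(floors.values())
    by_rem = sorted(AGE_DECADES, key=lambda d: shares[d] - floors[d], reverse=True)
    for d in by_rem[:short]:
        floors[d] += 1
    return floors


def very_large_city_units() -> list[CensusUnit]:
    """The six very-large cities as census units (synthetic decade split).

    Band-specific denominators were not published, so each city's adult
    population is spread across decades with the default weights; only
    all-adult aggregates should be asserted from these units.
    """
    units = []
    for i, row in VERY_LARGE_CITY_TABLE.iterrows():
        units.append(CensusUnit(
            unit_id=f"vlc-{i}", unit_type="CSD", centroid=(float(i) * 50_000.0, 0.0),
            population_by_decade=_spread_over_decades(int(row.adult_population)),
            in_cma=True, name=str(row.city)))
    return units


def very_large_city_cases() -> list[CaseRecord]:
    """Case records matching the published per-city counts (synthetic ages)."""
    cases = []
    k = 0
    for i, row in VERY_LARGE_CITY_TABLE.iterrows():
        for _ in range(int(row.cases)):
            cases.append(CaseRecord(patient_id=f"vlc-case-{k:04d}",
                                    region_code=f"vlc-{i}", age_years=40))
            k += 1
    return cases


def registry_funnel_cases() -> list[CaseRecord]:
    """627 registry records carrying the published exclusion-flag counts.

    The 556 included records split 275 / 281 across the two age bands as
    published (synthetic ages 35 and 65); flagged records reproduce the
    funnel stage counts exactly.
    """
    f = FUNNEL_COUNTS
    cases = []
    k = 0

    def add(n, **kw):
        nonlocal k
        for _ in range(n):
            cases.append(CaseRecord(patient_id=f"reg-{k:04d}",
                                    region_code="ontario", age_years=kw.pop("age", 40),
                                    **kw))
            k += 1

    add(f["deceased"], deceased=True)
    add(f["address_missing"], address_missing=True)
    add(f["out_of_study_area"], out_of_study_area=True)
    add(f["geocode_failed"], geocode_failed=True)
    add(AGE_BAND_CASES["20-49"], age=35)
    add(AGE_BAND_CASES["50+"], age=65)
    assert len(cases) == f["total"]
    return cases


def survey_margin_respondents() -> list[SurveyRespondent]:
    """940 respondents encoding the published survey count margins.

    Flag counts are exact (consult flags nested inside the epistaxis
    stratum, as the questionnaire posed them); ages are placeholder
    constants at the published means, so only proportions — not age or
    interval distributions — should be asserted from this fixture.
    """
    s = SURVEY_COUNTS
    n = s["respondents"]
    out = []
    for i in range(n):
        epistaxis = i < s["epistaxis"]
        ent = i < s["ent_consult"]                      # subset of epistaxis
        er = i < s["er_consult"]                        # subset of epistaxis
        female = i < s["female"]
        north_am = i < s["north_american"]
        age_first_ent = 27.8 if ent else None
        age_dx = (age_first_ent + 13.9) if ent else 37.1
        age_first_er = max(0.0, age_dx - 11.3) if er else None
        out.append(SurveyRespondent(
            respondent_id=f"svy-{i:04d}", physician_dx=True,
            age_now=max(54.1, age_dx), age_dx=age_dx,
            female=female, north_american=north_am, epistaxis=epistaxis,
            ent_consult_before_dx=ent, age_first_ent=age_first_ent,
            er_consult_before_dx=er, age_first_er=age_first_er))
    return out
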