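"""Prevalence operations against published funnel/table inputs and against
closed-form oracles."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from helpers import chi_square_oracle, ols_oracle
from raredx import datasets
from raredx.errors import DataError, FitError, InconsistencyError
from raredx.prevalence import (CaseRecord, CensusUnit, PrevalenceCell,
                               apply_geocoding_funnel, chi_square_compare,
                               classify_urban_rural, compute_prevalence,
                               estimate_underdiagnosis, filter_cities,
                               fit_population_vs_prevalence)


def unit(uid, pop_by_decade, in_cma=False, name=""):
    return CensusUnit(unit_id=uid, unit_type="CSD", centroid=(0.0, 0.0),
                      population_by_decade=pop_by_decade, in_cma=in_cma, name=name)


# ------------------------------------------------------------------ funnel

def test_registry_funnel_counts():
    """627 registry records with the published exclusion flags reduce to
    591 after the deceased/no-address stage and 556 included."""
    included, report = apply_geocoding_funnel(datasets.registry_funnel_cases())
    assert report.n_input == 627
    assert report.removed == {"deceased": 35, "address_missing": 1,
                              "out_of_study_area": 28, "geocode_failed": 7}
    assert report.n_after_stage1 == 591
    assert report.n_included == 556
    assert len(included) == 556
    # conservation: included plus every removal equals input
    assert report.n_included + sum(report.removed.values()) == report.n_input


def test_funnel_identity_and_degenerate():
    clean = [CaseRecord(f"p{i}", "u0", 30) for i in range(5)]
    included, report = apply_geocoding_funnel(clean)
    assert len(included) == 5 and report.n_after_stage1 == 5

    dead = [CaseRecord(f"p{i}", "u0", 30, deceased=True) for i in range(5)]
    included, report = apply_geocoding_funnel(dead)
    assert included == [] and report.removed["deceased"] == 5


def test_funnel_rejects_duplicate_ids():
    with pytest.raises(DataError):
        apply_geocoding_funnel([CaseRecord("p0", "u0", 30), CaseRecord("p0", "u1", 40)])


# ----------------------------------------------------------------- rates

def test_very_large_city_aggregate_rate():
    """The six-city aggregate (226 cases / 3,999,120 adults) rounds to the
    published 0.28 per 5000."""
    units = datasets.very_large_city_units()
    cases = datasets.very_large_city_cases()
    cell = compute_prevalence(cases, units, None, "all")
    assert cell.case_count == 226
    assert cell.population == 3_999_120
    assert round(cell.rate_per_5000, 2) == 0.28


def test_rate_scale_definition_and_linearity():
    u = unit("u0", {"20-29": 5000})
    cell = compute_prevalence([CaseRecord("p0", "u0", 25)], [u])
    assert cell.rate_per_5000 == 1.0
    cell10k = compute_prevalence([CaseRecord("p0", "u0", 25)], [u], scale=10_000)
    assert cell10k.rate == 2 * cell.rate_per_5000

    empty = compute_prevalence([], [u])
    assert empty.rate == 0.0


def test_aggregation_consistency():
    units = datasets.very_large_city_units()
    cases = datasets.very_large_city_cases()
    parts = [compute_prevalence(cases, units, {u.unit_id}, "all") for u in units]
    whole = compute_prevalence(cases, units, None, "all")
    assert sum(p.case_count for p in parts) == whole.case_count == 226
    assert sum(p.population for p in parts) == whole.population == 3_999_120


def test_uninhabited_region_handling():
    ghost = unit("ghost", {})
    cell = compute_prevalence([], [ghost], {"ghost"}, "all")
    assert cell.rate is None  # undefined, distinct from zero-case rate 0

    with pytest.raises(InconsistencyError):
        compute_prevalence([CaseRecord("p0", "ghost", 30)], [ghost], {"ghost"}, "all")


def test_unresolvable_region_listed():
    with pytest.raises(DataError, match="nowhere"):
        compute_prevalence([CaseRecord("p0", "nowhere", 30)],
                           [unit("u0", {"20-29": 10})])


def test_band_membership_is_decade_aligned():
    u = unit("u0", {"40-49": 100, "50-59": 100})
    cases = [CaseRecord("p0", "u0", 49), CaseRecord("p1", "u0", 50)]
    young = compute_prevalence(cases, [u], None, "20-49")
    old = compute_prevalence(cases, [u], None, "50+")
    assert (young.case_count, young.population) == (1, 100)
    assert (old.case_count, old.population) == (1, 100)


# ------------------------------------------------------ urban/rural, cities

def test_urban_rural_boundaries():
    units = [unit("a", {"20-29": 999}, in_cma=True),
             unit("b", {"20-29": 1000}, in_cma=True),
             unit("c", {"20-29": 1_000_000}, in_cma=False)]
    klass = classify_urban_rural(units)
    assert klass == {"a": "rural", "b": "urban", "c": "rural"}


def test_filter_cities_thresholds():
    units = datasets.very_large_city_units() + [unit("small", {"20-29": 100_000})]
    kept = filter_cities(units, 250_000)
    assert {u.name for u in kept} == set(datasets.VERY_LARGE_CITY_TABLE["city"])
    assert len(filter_cities(units, 0)) == len(units)
    assert filter_cities(units, 10**12) == []


# -------------------------------------------------------------- chi-square

def test_chi_square_equal_proportions():
    res = chi_square_compare(20, 100_000, 20, 100_000)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_chi_square_band_rates_significant():
    """Province band counts over denominators back-computed from the
    printed 0.26 / 0.36 per-5000 rates are significantly different."""
    pops = datasets.band_populations_from_rates()
    res = chi_square_compare(275, round(pops["20-49"]), 281, round(pops["50+"]))
    assert res.p_value < 0.0005


def test_chi_square_matches_formula_oracle():
    res = chi_square_compare(12, 1000, 30, 1000)
    assert res.statistic == pytest.approx(chi_square_oracle(12, 1000, 30, 1000),
                                          abs=1e-10)


def test_chi_square_small_table_sweep():
    """Exhaustive sweep of small 2x2 tables against sum((O-E)^2/E)."""
    for pa in (10, 25, 50):
        for pb in (10, 25, 50):
            for a in range(0, pa + 1):
                for b in range(0, pb + 1):
                    if a + b == 0 or (pa - a) + (pb - b) == 0:
                        continue
                    res = chi_square_compare(a, pa, b, pb)
                    assert res.statistic == pytest.approx(
                        chi_square_oracle(a, pa, b, pb), abs=1e-10)


@settings(derandomize=True, max_examples=200)
@given(a=st.integers(0, 500), extra_a=st.integers(1, 10**6),
       b=st.integers(0, 500), extra_b=st.integers(1, 10**6))
def test_chi_square_matches_oracle_property(a, extra_a, b, extra_b):
    """Pearson statistic equals sum((O-E)^2/E) on arbitrary valid tables."""
    pa, pb = a + extra_a, b + extra_b
    assume(a + b > 0)
    got = chi_square_compare(a, pa, b, pb).statistic
    assert got == pytest.approx(chi_square_oracle(a, pa, b, pb), rel=1e-9, abs=1e-9)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(DataError):
        chi_square_compare(0, 100, 0, 50)
    with pytest.raises(DataError):
        chi_square_compare(100, 100, 50, 50)


# --------------------------------------------------------------------- OLS

def _cells(pairs):
    return [PrevalenceCell(frozenset({f"u{i}"}), "all",
                           case_count=int(rate * pop / 5000), population=pop)
            for i, (pop, rate) in enumerate(pairs)]


def test_fit_exact_line_and_constant():
    cells = [PrevalenceCell(frozenset({"a"}), "all", 10, 50_000),
             PrevalenceCell(frozenset({"b"}), "all", 40, 100_000),
             PrevalenceCell(frozenset({"c"}), "all", 90, 150_000)]
    # rates 1.0, 2.0, 3.0 on populations 50k/100k/150k: an exact line
    slope, intercept, r2 = fit_population_vs_prevalence(cells)
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(1.0 / 50_000)

    const = [PrevalenceCell(frozenset({c}), "all", n, n * 1000)
             for c, n in (("a", 50), ("b", 100), ("c", 200))]
    assert fit_population_vs_prevalence(const)[2] == 0.0


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(5)
    pops = rng.integers(50_000, 2_000_000, size=10)
    counts = rng.integers(0, 200, size=10)
    cells = [PrevalenceCell(frozenset({f"u{i}"}), "all", int(c), int(p))
             for i, (p, c) in enumerate(zip(pops, counts))]
    got = fit_population_vs_prevalence(cells)
    want = ols_oracle([float(p) for p in pops],
                      [5000 * c / p for c, p in zip(counts, pops)])
    assert got == pytest.approx(want, abs=1e-9)


def test_fit_errors():
    with pytest.raises(FitError):
        fit_population_vs_prevalence([PrevalenceCell(frozenset({"a"}), "all", 1, 1000)])
    same_pop = [PrevalenceCell(frozenset({c}), "all", n, 1000)
                for c, n in (("a", 1), ("b", 2))]
    with pytest.raises(FitError):
        fit_population_vs_prevalence(same_pop)


# --------------------------------------------------------- under-diagnosis

def test_underdiagnosis_published_inputs():
    est = estimate_underdiagnosis(0.31, 1.1, 556, 9_116_380)
    assert est.undiagnosed_fraction == pytest.approx(1 - 0.31 / 1.1)
    assert est.undiagnosed_fraction == pytest.approx(0.7182, abs=5e-5)
    assert est.implied_undiagnosed_count == pytest.approx(1449.6, abs=0.05)


def test_underdiagnosis_degenerate_and_ordering():
    est = estimate_underdiagnosis(0.5, 0.5, 100, 1_000_000)
    assert est.undiagnosed_fraction == 0.0
    assert est.implied_undiagnosed_count == pytest.approx(
        est.implied_true_cases - 100)
    with pytest.raises(DataError):
        estimate_underdiagnosis(1.2, 1.1, 556, 9_116_380)
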