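"""End-to-end orchestration: synthesize -> prevalence -> access -> survey.

``run_pipeline`` executes the stages in dependency order on a single
configuration and returns a JSON-serializable report bundle containing the
exclusion funnel, prevalence tables and band comparisons, the city-size
regression, the benchmark under-diagnosis estimate, the drive-time coverage
profile, the survey summary, and a provenance block (seed, config hash)
from which the whole bundle is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .access import build_travel_graph, coverage_profile
from .config import SyntheticConfig
from .errors import DataError, FitError
from .prevalence import (CaseRecord, CensusUnit, apply_geocoding_funnel,
                         chi_square_compare, classify_urban_rural,
                         compute_prevalence, estimate_underdiagnosis,
                         filter_cities, fit_population_vs_prevalence,
                         prevalence_table)
from .survey import summarize_survey
from . import datasets, synthetic

log = logging.getLogger("raredx")


@dataclasses.dataclass
class RunConfig:
    """Options for one pipeline run over a synthetic world."""
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    bands: tuple[str, str] = ("20-49", "50+")
    large_city_min_pop: int = 50_000
    very_large_city_min_pop: int = 250_000
    min_urban_pop: int = 1000
    access_thresholds_s: tuple[float, ...] = (1800.0, 3600.0, 5400.0)
    snap_radius_m: float = 500.0
    grade_beta: float = 2.0


def _cell_dict(cell) -> dict:
    return {"age_band": cell.age_band, "case_count": cell.case_count,
            "population": cell.population, "rate_per_5000": cell.rate_per_5000}


def analyze(cases: Sequence[CaseRecord], units: Sequence[CensusUnit],
            run: RunConfig) -> dict:
    """Prevalence-side analysis of one cohort against one set of units."""
    included, funnel = apply_geocoding_funnel(cases)
    log.info("funnel: %d in, %d included, removed %s",
             funnel.n_input, funnel.n_included, funnel.removed)

    overall = compute_prevalence(included, units, None, "all")
    band_cells = {b: compute_prevalence(included, units, None, b) for b in run.bands}

    band_chi = None
    b1, b2 = run.bands
    try:
        band_chi = chi_square_compare(
            band_cells[b1].case_count, band_cells[b1].population,
            band_cells[b2].case_count, band_cells[b2].population)
    except DataError:
        pass

    klass = classify_urban_rural(units, run.min_urban_pop)
    urban_ids = {u for u, k in klass.items() if k == "urban"}
    rural_ids = {u for u, k in klass.items() if k == "rural"}
    urban = compute_prevalence(included, units, urban_ids, "all") if urban_ids else None
    rural = compute_prevalence(included, units, rural_ids, "all") if rural_ids else None
    urban_rural_chi = None
    if urban and rural and urban.population and rural.population:
        urban_rural_chi = chi_square_compare(
            urban.case_count, urban.population, rural.case_count, rural.population)

    large = filter_cities(units, run.large_city_min_pop)
    very_large = filter_cities(units, run.very_large_city_min_pop)
    large_cells = [compute_prevalence(included, units, {u.unit_id}, "all") for u in large]
    fit = None
    try:
        fit = fit_population_vs_prevalence([c for c in large_cells if c.rate is not None])
    except FitError:
        pass

    vl_cell = None
    if very_large:
        vl_cell = compute_prevalence(included, units, {u.unit_id for u in very_large}, "all")

    # benchmark = highest defined large-city rate; if no large city exceeds
    # the overall rate, fall back to the highest city rate anywhere (the max
    # unit rate always bounds the pooled rate from above)
    rates = [c.rate_per_5000 for c in large_cells if c.rate_per_5000 is not None]
    if not rates or (overall.rate_per_5000 and max(rates) < overall.rate_per_5000):
        all_rates = [compute_prevalence(included, units, {u.unit_id}, "all").rate_per_5000
                     for u in units]
        rates = [r for r in all_rates if r is not None]
    estimate = None
    if rates and overall.rate_per_5000 and max(rates) >= overall.rate_per_5000:
        est = estimate_underdiagnosis(overall, max(rates), funnel.n_included,
                                      overall.population)
        estimate = {
            "overall_rate_per_5000": est.overall_rate_per_5000,
            "benchmark_rate_per_5000": est.benchmark_rate_per_5000,
            "undiagnosed_fraction": est.undiagnosed_fraction,
            "implied_true_cases": est.implied_true_cases,
            "implied_undiagnosed_count": est.implied_undiagnosed_count,
        }

    return {
        "funnel": dataclasses.asdict(funnel),
        "overall": _cell_dict(overall),
        "bands": {b: _cell_dict(c) for b, c in band_cells.items()},
        "band_chi_square": dataclasses.asdict(band_chi) if band_chi else None,
        "urban": _cell_dict(urban) if urban else None,
        "rural": _cell_dict(rural) if rural else None,
        "urban_rural_chi_square":
            dataclasses.asdict(urban_rural_chi) if urban_rural_chi else None,
        "n_large_cities": len(large),
        "n_very_large_cities": len(very_large),
        "population_rate_fit":
            None if fit is None else dict(zip(("slope", "intercept", "r_squared"), fit)),
        "very_large_aggregate": _cell_dict(vl_cell) if vl_cell else None,
        "underdiagnosis": estimate,
        "prevalence_table": prevalence_table(included, units, run.bands),
    }


def run_pipeline(run: RunConfig, out_dir=None) -> dict:
    """Execute all stages on a synthetic world and assemble the bundle."""
    world = synthetic.generate_world(run.synthetic)
    bundle = {"prevalence": analyze(world["cases"], world["units"], run)}

    graph = build_travel_graph(world["nodes"], world["segments"],
                               world["penalties"], run.grade_beta)
    profile = coverage_profile(graph, world["clinics"], run.access_thresholds_s,
                               world["units"], run.snap_radius_m)
    bundle["access"] = [{"threshold_s": c.threshold_s,
                         "covered_population": c.covered_population,
                         "total_population": c.total_population,
                         "percent": c.percent} for c in profile]

    summary = summarize_survey(world["respondents"], run.synthetic.survey.n_contacts)
    bundle["survey"] = dataclasses.asdict(summary)

    bundle["provenance"] = {
        "seed": run.synthetic.seed,
        "config_hash": run.synthetic.config_hash(),
        "raredx_version": __version__,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def published_benchmarks() -> dict:
    """Re-run the analysis on the published summary inputs.

    Uses the printed registry funnel, the six very-large-city rows, the
    back-computed band denominators, the survey margins and the benchmark
    rate (see :mod:`raredx.datasets`) — everything that IS reproducible
    without the proprietary provincial microdata.
    """
    included, funnel = apply_geocoding_funnel(datasets.registry_funnel_cases())

    vl_units = datasets.very_large_city_units()
    vl_cases = datasets.very_large_city_cases()
    vl_cell = compute_prevalence(vl_cases, vl_units, None, "all")

    pops = datasets.band_populations_from_rates()
    counts = datasets.AGE_BAND_CASES
    band_chi = chi_square_compare(
        counts["20-49"], round(pops["20-49"]), counts["50+"], round(pops["50+"]))

    est = estimate_underdiagnosis(
        datasets.REPORTED_OVERALL_RATE_PER_5000,
        datasets.BENCHMARK_RATE_PER_5000,
        datasets.DIAGNOSED_COUNT,
        datasets.ONTARIO_ADULT_POPULATION)

    summary = summarize_survey(datasets.survey_margin_respondents(),
                               datasets.SURVEY_COUNTS["contacts"])

    return {
        "funnel": dataclasses.asdict(funnel),
        "very_large_aggregate": _cell_dict(vl_cell),
        "band_chi_square": dataclasses.asdict(band_chi),
        "underdiagnosis": {
            "undiagnosed_fraction": est.undiagnosed_fraction,
            "implied_true_cases": est.implied_true_cases,
            "implied_undiagnosed_count": est.implied_undiagnosed_count,
        },
        "survey": dataclasses.asdict(summary),
    }


# ------------------------------------------------------------------ output

def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the bundle as JSON, CSV tables and schematic figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(_jsonable(bundle), indent=2, default=float), encoding="utf-8")

    table = bundle["prevalence"].get("prevalence_table")
    if isinstance(table, pd.DataFrame):
        table.to_csv(out / "prevalence_table.csv", index=False)
    if "access" in bundle:
        pd.DataFrame(bundle["access"]).to_csv(out / "coverage.csv", index=False)
        _plot_figures(bundle, out)


def _plot_figures(bundle: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = bundle["prevalence"].get("prevalence_table")
    if isinstance(table, pd.DataFrame) and not table.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        rate_cols = [c for c in table.columns if c.startswith("rate_")]
        if rate_cols:
            ax.scatter(table["population"], table[rate_cols[0]], s=18)
            ax.set_xlabel("adult population")
            ax.set_ylabel(rate_cols[0].replace("_", " "))
            ax.set_title("City size versus diagnosed prevalence")
            fig.tight_layout()
            fig.savefig(out / "city_size_vs_rate.png", dpi=120)
        plt.close(fig)

    cov = pd.DataFrame(bundle["access"])
    if not cov.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar([f"{t/60:.0f} min" for t in cov["threshold_s"]], cov["percent"])
        ax.set_ylabel("population covered (%)")
        ax.set_ylim(0, 100)
        ax.set_title("Clinic drive-time coverage")
        fig.tight_layout()
        fig.savefig(out / "coverage.png", dpi=120)
        plt.close(fig)
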