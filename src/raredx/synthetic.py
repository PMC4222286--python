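"""Seeded synthetic study systems.

Generates everything the downstream analysis consumes, with the statistical
structure the analysis assumes: a jittered road lattice with road classes,
speed limits and occasional one-way segments; census units with multinomial
age-decade populations and a metropolitan flag; a diagnosed-case cohort
drawn from a fixed true prevalence thinned by age-band- and region-specific
detection probabilities, with optional founder-family clustering; clinic
placements; and survey respondents matching configured marginals.

Determinism contract: identical config (including seed) reproduces outputs
field for field.  Each generator draws from its own seed-derived stream
(see ``SyntheticConfig.rng``), so generators never perturb one another.
The detection step consumes its uniform variates in a fixed order given the
set of true cases, so raising any detection probability under common random
numbers can only convert undiagnosed cases to diagnosed ones.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .access import (DEFAULT_SPEED_BY_CLASS, Clinic, Node, RoadSegment,
                     TurnPenaltyTable)
from .config import AGE_DECADES, DECADE_RANGES, SurveyParams, SyntheticConfig, decades_in_band
from .errors import ConfigurationError
from .prevalence import CaseRecord, CensusUnit
from .survey import SurveyRespondent

_ROAD_CLASS_PROBS = {"primary": 0.1, "secondary": 0.2, "local": 0.7}


# --------------------------------------------------------------------------
# road network
# --------------------------------------------------------------------------

def generate_road_network(config: SyntheticConfig
                          ) -> tuple[list[Node], list[RoadSegment], TurnPenaltyTable]:
    """Connected jittered lattice with classed segments and default penalties.

    A ``grid_rows x grid_cols`` lattice of intersections spaced
    ``cell_length_m`` apart, coordinates jittered by up to
    ``coord_jitter_frac`` of a cell, elevations drawn so that typical grades
    are a few percent.  Orthogonal neighbours are joined by segments whose
    length is the jittered Euclidean distance, with a road class drawn at
    fixed proportions, the class's speed limit, and (at ``oneway_fraction``)
    a forward-only restriction.
    """
    rng = config.rng("road_network")
    R, C, cell = config.grid_rows, config.grid_cols, config.cell_length_m
    jit = config.coord_jitter_frac * cell

    nodes: list[Node] = []
    coords: dict[str, tuple[float, float]] = {}
    for r in range(R):
        for c in range(C):
            x = c * cell + rng.uniform(-jit, jit)
            y = r * cell + rng.uniform(-jit, jit)
            elev = float(rng.normal(200.0, 0.01 * cell))
            nid = f"n{r}_{c}"
            nodes.append(Node(nid, x, y, elev))
            coords[nid] = (x, y)

    classes = list(_ROAD_CLASS_PROBS)
    probs = np.array([_ROAD_CLASS_PROBS[c] for c in classes])
    segments: list[RoadSegment] = []
    k = 0
    for r in range(R):
        for c in range(C):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr >= R or cc >= C:
                    continue
                a, b = f"n{r}_{c}", f"n{rr}_{cc}"
                (xa, ya), (xb, yb) = coords[a], coords[b]
                length = math.hypot(xb - xa, yb - ya)
                cls = classes[rng.choice(len(classes), p=probs)]
                oneway = "forward_only" if rng.uniform() < config.oneway_fraction else "both"
                segments.append(RoadSegment(
                    segment_id=f"s{k}", from_node=a, to_node=b, length_m=length,
                    speed_kmh=DEFAULT_SPEED_BY_CLASS[cls], road_class=cls, oneway=oneway))
                k += 1
    return nodes, segments, TurnPenaltyTable()


# --------------------------------------------------------------------------
# census units
# --------------------------------------------------------------------------

def generate_census_units(config: SyntheticConfig, nodes: Sequence[Node]) -> list[CensusUnit]:
    """Census units anchored near network nodes with multinomial populations.

    Unit weights are Dirichlet-distributed (units differ in size, as real
    municipalities do); the joint unit-by-decade allocation is a single
    multinomial draw, so populations sum to ``total_population`` exactly.
    Units at or above the median population are flagged as metropolitan
    (populous units stand in for CMA membership).
    """
    rng = config.rng("census_units")
    n = config.n_census_units
    anchors = rng.choice(len(nodes), size=n, replace=n > len(nodes))
    decade_w = np.array([config.age_decade_weights[d] for d in AGE_DECADES])
    unit_w = rng.dirichlet(np.ones(n))
    joint = np.outer(unit_w, decade_w).ravel()
    joint = joint / joint.sum()
    counts = rng.multinomial(config.total_population, joint).reshape(n, len(AGE_DECADES))

    totals = counts.sum(axis=1)
    median = float(np.median(totals))
    units = []
    for i in range(n):
        node = nodes[anchors[i]]
        cx = node.x + rng.normal(0.0, 0.05 * config.cell_length_m)
        cy = node.y + rng.normal(0.0, 0.05 * config.cell_length_m)
        units.append(CensusUnit(
            unit_id=f"u{i:03d}", unit_type="CSD", centroid=(cx, cy),
            population_by_decade={d: int(counts[i, j]) for j, d in enumerate(AGE_DECADES)},
            in_cma=bool(totals[i] >= median and totals[i] > 0),
            name=f"City {i:03d}"))
    return units


# --------------------------------------------------------------------------
# diagnosed-case cohort
# --------------------------------------------------------------------------

def generate_cases(config: SyntheticConfig, units: Sequence[CensusUnit],
                   return_truth: bool = False):
    """Diagnosed cohort from a binomial true-case / thinned-detection model.

    True cases per (unit, band) are binomial(population, prevalence); at
    founder units each case seeds a geometric family cluster of configured
    mean size (capped by the band population).  Each true case is then
    diagnosed with probability detect_prob_by_ageband[band] times an
    optional per-region multiplier; only diagnosed cases yield records.

    With ``return_truth`` also returns a per-(unit, band) DataFrame of true
    and diagnosed counts (diagnosed <= true by construction).
    """
    bands = ("20-49", "50+")
    for b in bands:
        if b not in config.detect_prob_by_ageband:
            raise ConfigurationError(f"no detection probability configured for band {b!r}")
    p_true = min(1.0, config.true_prevalence_per_5000 / 5000.0)

    rng_true = config.rng("cases_true")
    rng_detect = config.rng("cases_detect")
    rng_age = config.rng("cases_age")

    n_units = len(units)
    n_founders = int(round(config.founder_unit_fraction * n_units))
    founder_ids = set()
    if n_founders > 0:
        founder_ids = {units[i].unit_id
                       for i in rng_true.choice(n_units, size=n_founders, replace=False)}

    records: list[CaseRecord] = []
    truth_rows = []
    pid = 0
    for unit in units:
        mult = config.detect_prob_region_multiplier.get(unit.unit_id, 1.0)
        for band in bands:
            pop = unit.band_population(band)
            n_true = int(rng_true.binomial(pop, p_true)) if pop > 0 else 0
            if n_true > 0 and unit.unit_id in founder_ids and config.family_cluster_mean_size > 1:
                sizes = rng_true.geometric(1.0 / config.family_cluster_mean_size, size=n_true)
                n_true = int(min(pop, sizes.sum()))
            p_detect = config.detect_prob_by_ageband[band] * mult
            n_diag = 0
            if n_true > 0:
                u = rng_detect.uniform(size=n_true)
                diagnosed = u < p_detect
                decades = decades_in_band(band)
                w = np.array([unit.population_by_decade.get(d, 0) for d in decades], dtype=float)
                w = w / w.sum()
                for hit in diagnosed:
                    if not hit:
                        continue
                    d = decades[rng_age.choice(len(decades), p=w)]
                    lo, hi = DECADE_RANGES[d]
                    age = int(rng_age.integers(lo, hi))
                    records.append(CaseRecord(
                        patient_id=f"case-{pid:06d}", region_code=unit.unit_id,
                        age_years=age))
                    pid += 1
                    n_diag += 1
            truth_rows.append({"unit_id": unit.unit_id, "band": band,
                               "true_cases": n_true, "diagnosed_cases": n_diag})
    if return_truth:
        return records, pd.DataFrame(truth_rows)
    return records


# --------------------------------------------------------------------------
# clinics
# --------------------------------------------------------------------------

def place_clinics(config: SyntheticConfig, nodes: Sequence[Node]) -> list[Clinic]:
    """Seeded selection of distinct network nodes as clinic anchors."""
    if config.n_clinics > len(nodes):
        raise ConfigurationError(
            f"n_clinics={config.n_clinics} exceeds node count {len(nodes)}")
    rng = config.rng("clinics")
    idx = rng.choice(len(nodes), size=config.n_clinics, replace=False)
    return [Clinic(clinic_id=f"clinic-{j}", node_id=nodes[i].node_id,
                   x=nodes[i].x, y=nodes[i].y)
            for j, i in enumerate(sorted(int(i) for i in idx))]


# --------------------------------------------------------------------------
# survey respondents
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _matched_truncnorm_params(mean: float, sd: float, lower: float = 0.0
                              ) -> tuple[float, float]:
    """Underlying (mu, sigma) whose lower-truncated normal has the target
    mean and SD.  Trivial when the truncation point is far in the tail."""
    if sd == 0:
        return mean, 0.0
    if lower <= mean - 8 * sd:
        return mean, sd

    def eqs(p):
        mu, log_s = p
        s = math.exp(log_s)
        a = (lower - mu) / s
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    feasible = sd < 0.99 * (mean - lower)  # truncated-normal CV is bounded by 1
    if feasible:
        sol, _info, ok, _msg = optimize.fsolve(eqs, [mean, math.log(sd)], full_output=True)
        if ok == 1:
            return float(sol[0]), float(math.exp(sol[1]))
    # Requested CV is infeasible (or the solver stalled): keep sigma and
    # match the mean alone, which is monotone in mu.
    def mean_err(mu):
        a = (lower - mu) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)) - mean

    lo, hi = mean - 20 * sd, mean + 2 * sd
    mu = optimize.brentq(mean_err, lo, hi)
    return float(mu), float(sd)


def _truncnorm_sample(mean: float, sd: float, size: int, rng: np.random.Generator,
                      lower: float = 0.0) -> np.ndarray:
    """Non-negative draws whose sample distribution has the configured
    mean/SD (moment-matched truncated normal)."""
    if sd == 0:
        return np.full(size, mean)
    mu, s = _matched_truncnorm_params(mean, sd, lower)
    a = (lower - mu) / s
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=s, size=size, random_state=rng)


def generate_survey(config: SyntheticConfig) -> list[SurveyRespondent]:
    """Respondents with configured marginal proportions and age structure.

    Consult flags are drawn within the epistaxis stratum (consult questions
    are only posed to epistaxis reporters), scaled so the whole-sample
    marginals match the configured proportions.  For ENT consulters the
    diagnosis age is consult age plus a directly drawn consult-to-diagnosis
    interval, so the configured interval marginal is matched exactly in
    distribution; the diagnosis-age marginal for consulters is then implied
    rather than configured.  ER consult ages are derived to respect
    consult-age <= diagnosis-age.
    """
    sp: SurveyParams = config.survey
    n = sp.n_respondents
    if n == 0:
        return []
    rng = config.rng("survey")

    female = rng.uniform(size=n) < sp.prop_female
    north_am = rng.uniform(size=n) < sp.prop_north_american
    epistaxis = rng.uniform(size=n) < sp.prop_epistaxis
    p_ent_given_epi = sp.prop_ent_consult / sp.prop_epistaxis if sp.prop_epistaxis > 0 else 0.0
    p_er_given_epi = sp.prop_er_consult / sp.prop_epistaxis if sp.prop_epistaxis > 0 else 0.0
    ent = epistaxis & (rng.uniform(size=n) < p_ent_given_epi)
    er = epistaxis & (rng.uniform(size=n) < p_er_given_epi)

    age_dx = _truncnorm_sample(sp.age_dx_mean, sp.age_dx_sd, n, rng)
    age_first_ent = _truncnorm_sample(sp.age_first_ent_mean, sp.age_first_ent_sd, n, rng)
    ent_interval = _truncnorm_sample(sp.ent_interval_mean, sp.ent_interval_sd, n, rng)
    age_first_er = _truncnorm_sample(sp.age_first_er_mean, sp.age_first_er_sd, n, rng)
    er_interval = _truncnorm_sample(sp.er_interval_mean, sp.er_interval_sd, n, rng)
    age_now_draw = _truncnorm_sample(sp.age_now_mean, sp.age_now_sd, n, rng)

    respondents = []
    for i in range(n):
        if ent[i]:
            a_ent = float(age_first_ent[i])
            a_dx = a_ent + float(ent_interval[i])
        else:
            a_ent = None
            a_dx = float(age_dx[i])
        if er[i]:
            if ent[i]:
                a_er = max(0.0, a_dx - float(er_interval[i]))
            else:
                a_er = float(age_first_er[i])
                a_dx = a_er + float(er_interval[i])
        else:
            a_er = None
        a_now = max(a_dx, float(age_now_draw[i]))
        respondents.append(SurveyRespondent(
            respondent_id=f"resp-{i:05d}", physician_dx=True,
            age_now=a_now, age_dx=a_dx,
            female=bool(female[i]), north_american=bool(north_am[i]),
            epistaxis=bool(epistaxis[i]),
            ent_consult_before_dx=bool(ent[i]), age_first_ent=a_ent,
            er_consult_before_dx=bool(er[i]), age_first_er=a_er))
    return respondents


# --------------------------------------------------------------------------
# whole-world convenience
# --------------------------------------------------------------------------

def generate_world(config: SyntheticConfig) -> dict:
    """Generate every synthetic data family for one configuration."""
    nodes, segments, penalties = generate_road_network(config)
    units = generate_census_units(config, nodes)
    cases, truth = generate_cases(config, units, return_truth=True)
    clinics = place_clinics(config, nodes)
    respondents = generate_survey(config)
    return {"nodes": nodes, "segments": segments, "penalties": penalties,
            "units": units, "cases": cases, "truth": truth,
            "clinics": clinics, "respondents": respondents}
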