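"""Configuration objects for the synthetic generators and the pipeline.

All free parameters of the synthetic world live here.  Defaults describe a
province-scale study system: an age-structured adult population spread over
census units anchored to a sparse road lattice, a hereditary disease whose
true prevalence is uniform but whose *diagnosed* prevalence is depressed by
age-band- and region-specific detection probabilities, a handful of
specialist clinics, and a patient survey with the marginal structure of a
consultation-gap questionnaire.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigurationError

#: Age decades covered by census population counts (adults only; the census
#: reports age structure by decade, so every band boundary must be a decade
#: boundary).
AGE_DECADES: tuple[str, ...] = (
    "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+",
)

#: The two analysis age bands, keyed by label.  ``(lo, hi)`` is closed-open.
AGE_BANDS: dict[str, tuple[int, int]] = {
    "20-49": (20, 50),
    "50+": (50, 200),
    "all": (20, 200),
}

#: Decade label -> closed-open year range.
DECADE_RANGES: dict[str, tuple[int, int]] = {
    "20-29": (20, 30), "30-39": (30, 40), "40-49": (40, 50),
    "50-59": (50, 60), "60-69": (60, 70), "70-79": (70, 80),
    "80+": (80, 90),
}

# Adult age-decade weights loosely shaped like a 2006 Canadian provincial
# age pyramid (younger decades heaviest, thin 80+ tail).
_DEFAULT_AGE_WEIGHTS: dict[str, float] = {
    "20-29": 0.175, "30-39": 0.175, "40-49": 0.21,
    "50-59": 0.17, "60-69": 0.12, "70-79": 0.09, "80+": 0.06,
}

# Benchmark-style defaults: true prevalence equal to the highest large-city
# diagnosed rate (1.1/5000), detection probabilities chosen so diagnosed band
# rates come out near 0.26 and 0.36 per 5000.
_DEFAULT_DETECT = {"20-49": 0.26 / 1.1, "50+": 0.36 / 1.1}


def decades_in_band(band: str) -> list[str]:
    """Return the census decades fully contained in an analysis age band."""
    if band not in AGE_BANDS:
        raise ConfigurationError(f"unknown age band {band!r}; expected one of {sorted(AGE_BANDS)}")
    lo, hi = AGE_BANDS[band]
    return [d for d, (dlo, dhi) in DECADE_RANGES.items() if dlo >= lo and dhi <= hi]


def band_of_age(age_years: float) -> str | None:
    """Map an age in years to the analysis band it falls in (None if <20)."""
    if age_years >= 50:
        return "50+"
    if age_years >= 20:
        return "20-49"
    return None


@dataclass
class SurveyParams:
    """Marginal structure of the synthetic consultation survey.

    Defaults encode the published survey margins of a 940-respondent cohort
    of physician-diagnosed patients (2836 contacts): proportions of females,
    North Americans, recurrent-epistaxis reporters and pre-diagnosis
    ENT / emergency-room consulters, plus mean +/- SD of the age at survey,
    age at diagnosis, ages at first consult, and consult-to-diagnosis
    intervals in years.
    """

    n_respondents: int = 940
    n_contacts: int = 2836
    prop_female: float = 630 / 940
    prop_north_american: float = 738 / 940
    prop_epistaxis: float = 807 / 940
    prop_ent_consult: float = 349 / 940
    prop_er_consult: float = 154 / 940
    age_now_mean: float = 54.1
    age_now_sd: float = 14.1
    age_dx_mean: float = 37.1
    age_dx_sd: float = 15.5
    age_first_ent_mean: float = 27.8
    age_first_ent_sd: float = 16.8
    age_first_er_mean: float = 30.1
    age_first_er_sd: float = 17.4
    ent_interval_mean: float = 13.9
    ent_interval_sd: float = 12.2
    er_interval_mean: float = 11.3
    er_interval_sd: float = 12.6

    def __post_init__(self) -> None:
        if self.n_respondents < 0 or self.n_contacts < 0:
            raise ConfigurationError("respondent and contact counts must be non-negative")
        if self.n_contacts < self.n_respondents:
            raise ConfigurationError("n_contacts must be >= n_respondents")
        for name in ("prop_female", "prop_north_american", "prop_epistaxis",
                     "prop_ent_consult", "prop_er_consult"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in dataclasses.asdict(self):
            if name.endswith("_sd") and getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        # Consult questions are only posed to epistaxis reporters, so the
        # consult marginals cannot exceed the epistaxis marginal.
        if self.prop_ent_consult > self.prop_epistaxis + 1e-12:
            raise ConfigurationError("prop_ent_consult cannot exceed prop_epistaxis")
        if self.prop_er_consult > self.prop_epistaxis + 1e-12:
            raise ConfigurationError("prop_er_consult cannot exceed prop_epistaxis")


@dataclass
class SyntheticConfig:
    """Free parameters of the synthetic study system.

    The road lattice is ``grid_rows x grid_cols`` intersections spaced
    ``cell_length_m`` apart (default 5 km: a sparse, regional-scale network),
    with planar coordinates jittered by ``coord_jitter_frac`` of a cell.
    ``total_population`` adults are allocated over ``n_census_units`` units
    and the seven census age decades.  True cases arise at
    ``true_prevalence_per_5000`` and are diagnosed with band-specific
    probability ``detect_prob_by_ageband`` times an optional per-region
    multiplier; founder-style family clustering inflates case counts at a
    seeded subset of units.
    """

    seed: int = 42
    grid_rows: int = 12
    grid_cols: int = 12
    cell_length_m: float = 5000.0
    coord_jitter_frac: float = 0.1
    n_census_units: int = 40
    total_population: int = 2_000_000
    age_decade_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_WEIGHTS))
    true_prevalence_per_5000: float = 1.1
    detect_prob_by_ageband: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DETECT))
    detect_prob_region_multiplier: dict[str, float] = field(default_factory=dict)
    family_cluster_mean_size: float = 3.0
    founder_unit_fraction: float = 0.05
    oneway_fraction: float = 0.05
    n_clinics: int = 3
    survey: SurveyParams = field(default_factory=SurveyParams)

    def __post_init__(self) -> None:
        if isinstance(self.survey, Mapping):
            self.survey = SurveyParams(**self.survey)
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        if self.cell_length_m <= 0:
            raise ConfigurationError("cell_length_m must be positive")
        if not 0.0 <= self.coord_jitter_frac < 0.4:
            raise ConfigurationError("coord_jitter_frac must lie in [0, 0.4)")
        if self.n_census_units < 1:
            raise ConfigurationError("n_census_units must be >= 1")
        if self.total_population < 0:
            raise ConfigurationError("total_population must be >= 0")
        missing = set(AGE_DECADES) - set(self.age_decade_weights)
        if missing:
            raise ConfigurationError(f"age_decade_weights missing decades: {sorted(missing)}")
        w = np.array([self.age_decade_weights[d] for d in AGE_DECADES], dtype=float)
        if (w < 0).any():
            raise ConfigurationError("age_decade_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"age_decade_weights sum to {w.sum()}, not 1")
        if self.true_prevalence_per_5000 < 0:
            raise ConfigurationError("true_prevalence_per_5000 must be >= 0")
        for band, p in self.detect_prob_by_ageband.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"detection probability for band {band!r} outside [0,1]")
        for region, m in self.detect_prob_region_multiplier.items():
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(f"region multiplier for {region!r} outside [0,1]")
        if self.family_cluster_mean_size < 1:
            raise ConfigurationError("family_cluster_mean_size must be >= 1")
        if not 0.0 <= self.founder_unit_fraction <= 1.0:
            raise ConfigurationError("founder_unit_fraction must lie in [0, 1]")
        if not 0.0 <= self.oneway_fraction <= 1.0:
            raise ConfigurationError("oneway_fraction must lie in [0, 1]")
        if self.n_clinics < 0:
            raise ConfigurationError("n_clinics must be >= 0")

    # -- seeded substream derivation -------------------------------------
    def rng(self, label: str) -> np.random.Generator:
        """Independent RNG stream for one generator operation.

        Streams are derived from the master seed plus a fixed per-operation
        label, so adding a new generator never perturbs another's output.
        """
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), zlib.crc32(label.encode("utf-8"))]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load from a YAML (or JSON, a YAML subset) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance blocks."""
        import hashlib
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]
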