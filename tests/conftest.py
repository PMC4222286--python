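import pytest

from raredx.config import SurveyParams, SyntheticConfig


@pytest.fixture
def small_config():
    """A fast, fully exercised synthetic world."""
    return SyntheticConfig(seed=7, grid_rows=4, grid_cols=4, cell_length_m=2000.0,
                           n_census_units=8, total_population=100_000, n_clinics=2,
                           survey=SurveyParams(n_respondents=200, n_contacts=600))


@pytest.fixture
def one_unit_config():
    """One census unit with a million adults in each analysis band."""
    weights = {d: 0.0 for d in ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")}
    weights["20-29"] = 0.5
    weights["50-59"] = 0.5
    return SyntheticConfig(seed=1, grid_rows=1, grid_cols=2, n_census_units=1,
                           total_population=2_000_000, age_decade_weights=weights,
                           true_prevalence_per_5000=1.0,
                           detect_prob_by_ageband={"20-49": 1.0, "50+": 1.0},
                           family_cluster_mean_size=1.0, founder_unit_fraction=0.0,
                           n_clinics=0)
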