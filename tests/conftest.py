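import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import farmbird as fb
from farmbird._rng import substream

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_regions():
    return fb.generate_regions(20, 42)


@pytest.fixture(scope="session")
def small_species():
    return fb.generate_species(4, 2, 42)


@pytest.fixture(scope="session")
def glmm_profile():
    """A species with known coefficients for simulation-based checks."""
    prof = fb.generate_species(1, 0, 7)[0]
    prof.alpha = float(np.log(5.0))
    prof.beta_climate = 0.8
    prof.beta_farmland = 0.5
    prof.beta_effort = 0.0
    prof.beta_crops = np.zeros(len(fb.CROPS))
    prof.random_sd_region = 0.3
    prof.random_sd_year = 0.1
    prof.random_sd_obs = 0.2
    return prof


def make_recovery_dataset(seed: int, n_regions: int = 200, n_years: int = 5,
                          sd_region=0.3, sd_year=0.1, sd_obs=0.2) -> pd.DataFrame:
    """Region x year counts from known coefficients, with varying covariates."""
    regions = fb.generate_regions(n_regions, seed)
    rng = substream(seed, "recovery-covariates")
    for r in regions:
        r.farmland_prop_current = float(rng.uniform(0.2, 0.9))
    prof = fb.generate_species(1, 0, 7)[0]
    prof.alpha = float(np.log(5.0))
    prof.beta_climate = 0.8
    prof.beta_farmland = 0.5
    prof.beta_effort = 0.0
    prof.beta_crops = np.zeros(len(fb.CROPS))
    prof.random_sd_region = sd_region
    prof.random_sd_year = sd_year
    prof.random_sd_obs = sd_obs
    return fb.simulate_regional_counts(regions, prof, range(2001, 2001 + n_years), seed)


@pytest.fixture
def tiny_visits():
    """Hand-built visit table exercising the preparation rules.

    Region A, square sq0: 5 of 10 points in farmland (retained).
    Region A, square sq1: 4 of 10 points in farmland (dropped).
    """
    rows = []
    for k in range(10):
        is_farm = k < 5
        # resident species: visits (3, 5) on point 0, zeros elsewhere
        rows.append(("resident", "A", 2001, "A-sq0", f"A-sq0-pt{k}",
                     3 if k == 0 else 0, 5 if k == 0 else 0, is_farm))
        # migrant species: visits (7, 2) on point 1
        rows.append(("migrant", "A", 2001, "A-sq0", f"A-sq0-pt{k}",
                     7 if k == 1 else 0, 2 if k == 1 else 0, is_farm))
    for k in range(10):
        is_farm = k < 4
        rows.append(("resident", "A", 2001, "A-sq1", f"A-sq1-pt{k}", 9, 9, is_farm))
        rows.append(("migrant", "A", 2001, "A-sq1", f"A-sq1-pt{k}", 9, 9, is_farm))
    return pd.DataFrame(
        rows,
        columns=["species_id", "region_id", "year", "square_id", "point_id",
                 "visit1_count", "visit2_count", "point_is_farmland"],
    )


@pytest.fixture
def tiny_species_frame():
    return pd.DataFrame(
        {"species_id": ["resident", "migrant"], "migrant_second_visit_only": [False, True]}
    )
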