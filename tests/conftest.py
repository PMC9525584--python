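import numpy as np
import pandas as pd
import pytest

from airequity import SyntheticRegionSpec, generate_region


@pytest.fixture
def toy_tracts() -> pd.DataFrame:
    """Four tracts in two counties with handpicked values."""
    return pd.DataFrame(
        {
            "tract_id": ["T0", "T1", "T2", "T3"],
            "county_id": ["A", "A", "B", "B"],
            "population": [1000.0, 3000.0, 2000.0, 4000.0],
            "incidence_per_person_year": [0.008, 0.009, 0.007, 0.010],
            "vulnerability_score": [10.0, 90.0, 40.0, 80.0],
        }
    )


@pytest.fixture(scope="session")
def small_region():
    """A deterministic 120-tract synthetic region shared across tests."""
    spec = SyntheticRegionSpec(
        n_tracts=120, n_counties=5, grid_rows=16, grid_cols=16,
        benefit_vulnerability_rho=0.6, seed=42,
    )
    return generate_region(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
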