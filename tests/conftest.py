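"""Shared fixtures: synthetic landscapes at two scales.

``study_*`` fixtures are the default study conditions (60x60 grid, 3 years,
50 presences per month per year); ``small_*`` fixtures are a reduced landscape
for fast unit tests.  All are session-scoped and deterministic.
"""

import numpy as np
import pandas as pd
import pytest

from seasonsdm import LandscapeConfig, generate_env_stack, sample_occurrences
from seasonsdm.synthgrid import default_virtual_species

MODEL_VARIABLES = ["MINTEMP", "PRECIPI", "EVAPO", "NDVI", "RFD"]


@pytest.fixture(scope="session")
def study_config():
    return LandscapeConfig(seed=1)


@pytest.fixture(scope="session")
def study_stack(study_config):
    return generate_env_stack(study_config)


@pytest.fixture(scope="session")
def species():
    return default_virtual_species()


@pytest.fixture(scope="session")
def study_presences(species, study_stack):
    return sample_occurrences(species, study_stack, {m: 50 for m in range(1, 13)}, seed=2)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(n_rows=24, n_cols=24, cell_size_km=40.0, years=(2014, 2015), seed=11)


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_env_stack(small_config)


@pytest.fixture(scope="session")
def small_presences(species, small_stack):
    return sample_occurrences(species, small_stack, {m: 12 for m in range(1, 13)}, seed=12)


def simulate_mixed_logistic(
    n_per_year: int,
    betas: dict[str, float],
    intercept: float,
    sigma: float,
    years=(2011, 2012, 2013, 2014),
    seed: int = 0,
) -> pd.DataFrame:
    """Direct simulation from the fitted model family (for recovery tests)."""
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        u = rng.normal(0, sigma)
        X = {v: rng.normal(0, 1, n_per_year) for v in betas}
        eta = intercept + u + sum(b * X[v] for v, b in betas.items())
        y = rng.uniform(size=n_per_year) < 1 / (1 + np.exp(-eta))
        rows.append(pd.DataFrame({**X, "year": year, "label": y.astype(int)}))
    return pd.concat(rows, ignore_index=True)
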