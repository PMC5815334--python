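import numpy as np
import pandas as pd
import pytest

from ipwmort.population import PopulationParams, generate_population
from ipwmort.sampling import SamplingParams, apply_nonresponse, draw_sample


@pytest.fixture(scope="session")
def medium_population() -> pd.DataFrame:
    """One 200k population at the 10%-death setting, shared across tests."""
    return generate_population(
        PopulationParams(n_individuals=200_000, target_death_fraction=0.10, seed=42)
    )


@pytest.fixture(scope="session")
def sampled_population(medium_population) -> pd.DataFrame:
    """The shared population with sample and response flags (10% / 25%)."""
    params = SamplingParams(sampling_fraction=0.10, nonresponse_fraction=0.25, seed=7)
    return apply_nonresponse(draw_sample(medium_population, params), params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
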