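import numpy as np
import pytest

from sdmnet import SimulationConfig, generate_cohort, generate_design


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default synthetic cohort (8/6/6 fish), shared across tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def design(default_config):
    return generate_design(default_config.group_sizes, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
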