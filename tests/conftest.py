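import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microsoc import SyntheticConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One generated dataset shared across tests (design defaults, 81 plots)."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def latent(dataset) -> pd.DataFrame:
    return dataset.latent


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
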