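import numpy as np
import pytest

from phytotea.assumptions import default_registry
from phytotea.growth_model import GrowthModelParams
from phytotea.synthetic_data import (
    SYNTHETIC_TRUE_PARAMS,
    SyntheticExperimentDesign,
    synth_chamber_data,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def true_params() -> GrowthModelParams:
    return SYNTHETIC_TRUE_PARAMS


@pytest.fixture(scope="session")
def clean_chambers(true_params):
    """Noise-free chamber datasets generated from the forward model."""
    return synth_chamber_data(
        SyntheticExperimentDesign(noise_sd=0.0, true_params=true_params, seed=0)
    )


@pytest.fixture(scope="session")
def noisy_chambers(true_params):
    """Chamber datasets with 0.5 g/plant Gaussian dry-weight noise."""
    return synth_chamber_data(
        SyntheticExperimentDesign(noise_sd=0.5, true_params=true_params, seed=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
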