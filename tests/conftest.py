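import numpy as np
import pytest
from hypothesis import settings

from crossfeed.model import ModelParams, PopulationState

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """The reference parameter set of the two-strain model."""
    return ModelParams()


@pytest.fixture(scope="session")
def saddle_node_a(default_params) -> float:
    from crossfeed.equilibria import saddle_node_point

    return saddle_node_point(default_params)


@pytest.fixture(scope="session")
def exclusion_a(default_params) -> float:
    from crossfeed.equilibria import exclusion_threshold

    return exclusion_threshold(default_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def interior_state() -> PopulationState:
    return PopulationState(0.25, 0.25)
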