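import numpy as np
import pytest

from fearcast.synthetic_population import PopulationSpec, generate


@pytest.fixture(scope="session")
def small_pop():
    """10k-agent population shared across engine tests."""
    return generate(PopulationSpec(n_agents=10_000, households_per_community=100, rng_seed=1))


@pytest.fixture(scope="session")
def tiny_pop():
    """2k-agent population for event-logged runs."""
    return generate(PopulationSpec(n_agents=2_000, households_per_community=50, rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
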