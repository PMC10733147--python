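import numpy as np
import pytest

from svscape.synthetic import SimulationConfig, default_library, simulate_bundle


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic cohort, shared across tests."""
    return simulate_bundle(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
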