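import numpy as np
import pytest
from hypothesis import settings

from selfid import SimParams, RNGStream, initialize_population, run_simulation

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return RNGStream(12345)


@pytest.fixture
def tiny_params():
    return SimParams(N=50, generations=20, window=10, seed=7)


@pytest.fixture(scope="session")
def small_equilibrium():
    """A small population run to selection-mutation-drift balance.

    Shared across metric tests that only need *some* equilibrated
    population with selfing-rate and load variation.
    """
    params = SimParams(
        N=400, U=0.5, s=0.2, h=0.1, generations=400, window=100, seed=42
    )
    result = run_simulation(params, assay_start=300)
    return result
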