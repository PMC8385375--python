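import numpy as np
import pytest
from hypothesis import settings

from ddadapt import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def small_pop() -> ModelParams:
    """Down-scaled population for fast stochastic tests (same rates)."""
    return ModelParams(n0=200, nmax=1000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
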