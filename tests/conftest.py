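import numpy as np
import pytest
from hypothesis import settings

from iccs import ModelParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def params():
    """Default study parameters (36 trials, m=0.85, linear curve)."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class StubRNG:
    """Feeds a fixed sequence of 'uniform' draws; counts consumption."""

    def __init__(self, draws):
        self.draws = list(draws)
        self.i = 0

    def random(self):
        u = self.draws[self.i]
        self.i += 1
        return u


@pytest.fixture
def stub_rng():
    return StubRNG
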