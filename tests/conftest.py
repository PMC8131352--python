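import numpy as np
import pytest

from condpun.params import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A fast, valid condition for unit tests (not the study condition)."""
    return ModelParams(n_agents=20, generations=10, initial_donations=2)
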