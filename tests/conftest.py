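import numpy as np
import pytest

from ssevec import MatchParams
from ssevec.synthetic import random_representation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params_exact():
    """Exact-match settings: narrow Gaussian, small Monte-Carlo budget."""
    return MatchParams(delta=0.1, mc_samples=1000, seed=7)


@pytest.fixture
def params_fuzzy():
    """Classification-style settings with a wider Gaussian."""
    return MatchParams(delta=0.3, mc_samples=1000, seed=7)


@pytest.fixture
def rep8():
    return random_representation(8, seed=3)


@pytest.fixture
def rep_all_helix():
    return random_representation(6, helix_fraction=1.0, seed=5)
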