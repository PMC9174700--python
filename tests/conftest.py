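import numpy as np
import pytest

from flashodh import (
    DEFAULT_RESPONSE,
    LinearDepletionModel,
    LingDepletionModel,
)


@pytest.fixture
def response():
    return DEFAULT_RESPONSE


@pytest.fixture
def fig2_model():
    """The worked linear-depletion example: 7 Torr, 0.6 Torr/Gy."""
    return LinearDepletionModel(o2_0=7.0, rate_r=0.6)


@pytest.fixture
def ling_model():
    return LingDepletionModel(o2_0=20.0, g_yield=4.0, dose_d=10.0, lam=1e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
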