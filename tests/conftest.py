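import numpy as np
import pytest

from nosepoke import VirtualMouseParams, build_threshold_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return VirtualMouseParams()


@pytest.fixture
def threshold_schedule(default_params):
    a_star = default_params.detect.a
    concs = list(a_star * np.logspace(-1.2, 1.2, 7))
    return build_threshold_series("AA", concs)
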