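import numpy as np
import pytest

from tempreg import ObserverParams, TrialCondition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ObserverParams()


@pytest.fixture
def noiseless_toj_params():
    """Deterministic TOJ responder: no latency noise, no lapses."""
    return ObserverParams(visual_latency_sd=0.0, lapse_rate=0.0)


@pytest.fixture
def exp1_condition():
    return TrialCondition("exp1", "regular", 0.0, -40.0, None, 0)


@pytest.fixture
def exp2_condition():
    return TrialCondition("exp2", "regular", 0.0, -40.0, 80.0, 0)
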