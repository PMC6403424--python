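import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import toroidyn as td

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_rates():
    """All channels switched off (valid configuration)."""
    return td.RateParameters(
        k_open=0, k_close=0, k_nuc=0, k_el=0, k_join=0,
        k_relax_free=0, k_relax_chain=0,
    )


@pytest.fixture
def small_state():
    """A mixed state with free species and a few chains (300 units)."""
    return td.SystemState(
        time=0.0,
        n_inactive=100,
        n_active_closed=120,
        n_active_open=50,
        chains=[2, 5, 10, 13],
        volume_litres=td.volume_for(300, 30.0),
    )
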