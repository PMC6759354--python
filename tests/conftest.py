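import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ebnet import build_network
from ebnet.stimuli import constant_pulse

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_neuron_spec():
    """Two-neuron network: strongly (w=1) and weakly (w=2) excitable."""
    return build_network([1.0, 2.0], mu=0.02, tau=25.0, tau_a=1000.0)


@pytest.fixture(scope="session")
def ten_neuron_spec():
    """Heterogeneous population with decoding weights 1..10."""
    return build_network(np.arange(1, 11, dtype=float), mu=0.2, tau=5.0, tau_a=1000.0)


@pytest.fixture(scope="session")
def pulse_2s():
    return constant_pulse(10.0, 2000.0, dt=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
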