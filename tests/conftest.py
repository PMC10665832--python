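import numpy as np
import pytest

from bmbu import ObserverParams, ProtocolSpec, generate_observer_dataset


@pytest.fixture
def default_params():
    return ObserverParams(mu0=0.1, sigma0=1.0, sigma_m=0.5, kappa=0.7)


@pytest.fixture
def small_dataset(default_params):
    """Four 26-trial runs from one simulated observer."""
    return generate_observer_dataset(ProtocolSpec(n_runs=4), default_params, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
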