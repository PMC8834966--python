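import numpy as np
import pytest

from medibench.mediator_sim import MediatorParams, SimConfig, sample_mediator_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Two species, one chemical; hand-checkable coupling."""
    return MediatorParams(
        n=2, m=1, r=[0.1, 0.1], K=1.0, delta=0.01,
        kappa=[[1e-3], [1e-3]],
        rho_plus=[[0.2], [0.0]], rho_minus=[[0.0], [0.1]],
        alpha=[[0.0, 0.0]], beta=[[0.1, 0.05]],
    )


@pytest.fixture
def default_params(rng):
    return sample_mediator_params(rng)


@pytest.fixture
def quiet_config():
    """Deterministic, short integration for unit tests."""
    return SimConfig(sigma=0.0, eps=0.0, t_max=500, t0=100, seed=0)
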