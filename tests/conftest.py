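import numpy as np
import pytest

from magefc import SimSpec, StateBasis, StateTimeCourses, random_basis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_basis(rng):
    """A valid 3-state basis on 4 channels."""
    spec = SimSpec(n_channels=4, n_timepoints=100, n_states_mean=3, n_states_fc=3)
    return random_basis(spec, rng)


@pytest.fixture
def small_tcs(rng):
    """Random simplex-valued time courses for the small basis."""
    T, P = 20, 3
    a = rng.dirichlet(np.ones(P), size=T)
    b = rng.dirichlet(np.ones(P), size=T)
    return StateTimeCourses(alpha=a, beta=b, gamma=a.copy())


def random_spd(rng, n, cond_floor=0.1):
    """Random well-conditioned SPD matrix."""
    W = rng.standard_normal((n, n))
    return W @ W.T + cond_floor * n * np.eye(n)
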