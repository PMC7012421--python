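import numpy as np
import pytest

from flare.model import EventMatrix, Hyperparameters, VariationalState
from flare import simulate


def blank_state(M, K, D, beta0=500.0, sigma0=None, nu0=None):
    """A structurally valid state with neutral parameters, for hand-set tests."""
    sigma0 = 6.0 * D if sigma0 is None else sigma0
    nu0 = 6.0 * D if nu0 is None else nu0
    eye = np.eye(D)
    return VariationalState(
        r=[np.zeros((1, K)) for _ in range(M)],
        log_rho=[np.zeros((1, K)) for _ in range(M)],
        alpha=np.ones((M, K)),
        Nk=np.zeros((M, K)),
        xbar=np.zeros((M, K, D)),
        S=np.zeros((M, K, D, D)),
        omega=np.zeros((M, K, D)),
        Gamma=np.broadcast_to(eye / beta0, (M, K, D, D)).copy(),
        xi=np.zeros((K, D)),
        Upsilon=np.broadcast_to(eye, (K, D, D)).copy() / (1.0 + beta0 * M),
        Psi=np.broadcast_to(eye, (M, K, D, D)).copy(),
        sigma=np.full((M, K), sigma0 + 1.0),
        Phi=np.broadcast_to(eye, (K, D, D)).copy(),
        nu=nu0 + M * sigma0,
    )


@pytest.fixture
def three_cluster_spec():
    """Small well-separated 3-sample dataset used across integration tests."""
    return simulate.SimulationSpec(
        M=3, D=4, K_true=3,
        events_per_sample=[2000, 2000, 2000],
        weights=np.tile([0.5, 0.3, 0.2], (3, 1)),
        prototype_means=np.array(
            [[0, 0, 0, 0], [4, 4, 0, 0], [0, 4, 4, 0]], dtype=float
        ),
        prototype_covs=np.stack([np.eye(4)] * 3),
        seed=11,
    )


@pytest.fixture
def three_cluster_data(three_cluster_spec):
    return simulate.generate(three_cluster_spec)


@pytest.fixture
def small_fit(three_cluster_data):
    from flare.inference import fit

    data, truth = three_cluster_data
    return fit(data, Hyperparameters(K=5), seed=3, max_sweeps=120), data, truth


def single_event(x, D=1):
    return EventMatrix("s", np.full((1, D), float(x)), [f"m{i}" for i in range(D)])
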