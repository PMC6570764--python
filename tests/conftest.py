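import numpy as np
import pytest

import ecomotifs as em


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_counts():
    """Perfectly separable two-block abundance matrix."""
    return em.CountMatrix([[10, 0], [0, 10]], ["a", "b"], ["sp1", "sp2"])


@pytest.fixture
def small_counts(rng):
    vals = rng.integers(0, 20, size=(6, 8))
    vals[:, 0] += 1  # guarantee no all-zero row
    return em.CountMatrix(vals)


@pytest.fixture(scope="session")
def geo_fixture():
    """Shared banded range/site fixture for dispersion + structure tests."""
    ranges, sites, lists = em.simulate_ranges(seed=4)
    return ranges, sites, lists


def random_valid_fit(N, G, K, model_kind, rng):
    """A random parameter set satisfying the model constraints (not fitted)."""
    omega = rng.dirichlet(np.ones(K), size=N)
    if model_kind == "multinomial":
        theta = rng.dirichlet(np.ones(G), size=K)
    else:
        theta = rng.uniform(0.05, 0.95, size=(K, G))
    return em.MotifFit(
        model_kind=model_kind, K=K, omega=omega, theta=theta,
        loglik_trace=np.empty(0), log_bf=0.0, seed=None, converged=True,
    )
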