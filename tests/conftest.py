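import numpy as np
import pytest

import connctl as cc


@pytest.fixture(scope="session")
def parcellation():
    """Small modular parcellation shared across tests."""
    return cc.generate_parcellation(40, seed=11)


@pytest.fixture(scope="session")
def ground_truth(parcellation):
    return cc.default_ground_truth(parcellation, seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    sizes = {"SZ": 6, "BD": 5, "MDD": 5, "HC": 6}
    return cc.generate_cohort(sizes, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def random_stable_symmetric(rng, n, radius=0.9):
    """Random symmetric matrix rescaled to the requested spectral radius."""
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    rho = np.max(np.abs(np.linalg.eigvalsh(m)))
    return m * (radius * rng.uniform(0.3, 1.0) / rho)
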