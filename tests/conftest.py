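import numpy as np
import pytest

from fireardl import DgpSpec, EcmSpec, fit_ecm, generate_ecm_system

#: two-driver system used where a compact, well-conditioned fit suffices
SMALL_KAPPA = {"wind": 20.81, "t_max": 8.651}


@pytest.fixture(scope="session")
def full_system():
    """Default 7-regressor cointegrated system with its truth record."""
    ds, truth = generate_ecm_system(DgpSpec(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def full_fit(full_system):
    ds, truth = full_system
    spec = EcmSpec("area_burned", tuple(truth.long_run_elasticities))
    return fit_ecm(ds, spec)


@pytest.fixture(scope="session")
def small_system():
    ds, truth = generate_ecm_system(
        DgpSpec(seed=7, long_run_elasticities=dict(SMALL_KAPPA))
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_fit(small_system):
    ds, truth = small_system
    spec = EcmSpec("area_burned", tuple(SMALL_KAPPA))
    return fit_ecm(ds, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
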