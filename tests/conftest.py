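import numpy as np
import pytest

from longimode import CohortConfig, build_default_registry, generate_cohort
from longimode.pipeline import RunConfig


@pytest.fixture(scope="session")
def full_registry():
    return build_default_registry("full")


@pytest.fixture(scope="session")
def toy_registry():
    return build_default_registry("toy")


@pytest.fixture(scope="session")
def toy_cohort():
    """Small planted-mode cohort shared across read-only tests."""
    cfg = CohortConfig(n_pool=400, n_select=60, group_sizes=(32, 28),
                       profile="toy", rho_star=0.9, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_runconfig():
    return RunConfig.toy(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
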