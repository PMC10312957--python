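import dataclasses

import numpy as np
import pytest

from pvgamma.netmodel import NetworkConfig
from pvgamma.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config, seed=1234)


@pytest.fixture(scope="session")
def null_config() -> CohortConfig:
    """Cohort config with every group effect switched off."""
    cfg = CohortConfig()
    return dataclasses.replace(
        cfg, sz_effects={k: 1.0 for k in cfg.sz_effects})


@pytest.fixture(scope="session")
def fast_net_config() -> NetworkConfig:
    """Short-duration network config for cheap simulation tests."""
    return dataclasses.replace(
        NetworkConfig(), duration_ms=1500.0, transient_ms=500.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
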