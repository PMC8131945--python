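import warnings

import numpy as np
import pytest

from repmetrics import SimConfig, evidence_table, run_scenario

# boost's noncentral-t emits harmless deep-tail quadrature warnings
warnings.filterwarnings("ignore", message=".*exp_sinh.*")


@pytest.fixture(scope="session")
def cfg_small() -> SimConfig:
    """Small but structurally complete simulation design."""
    return SimConfig(seed=7, iter_per_cell=150)


@pytest.fixture(scope="session")
def scenario100_small(cfg_small):
    return run_scenario(cfg_small, 100)


@pytest.fixture(scope="session")
def scenario0_small(cfg_small):
    return run_scenario(cfg_small, 0)


@pytest.fixture(scope="session")
def evidence100_small(cfg_small, scenario100_small):
    """All seven evidence statistics for the published pairs at 100% bias."""
    return evidence_table(scenario100_small, cfg_small)


@pytest.fixture(scope="session")
def evidence50_small(cfg_small):
    """Mixed significant/non-significant originals (replication BF gets NA)."""
    frame = run_scenario(cfg_small, 50)
    return evidence_table(frame, cfg_small)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
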