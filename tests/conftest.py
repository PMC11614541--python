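import numpy as np
import pytest

from nutrigeom.simulate import SimConfig, simulate_no_choice


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One simulated no-choice cohort shared across read-only tests."""
    return simulate_no_choice(default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
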