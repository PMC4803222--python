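import numpy as np
import pytest

from glspipe.synth import SimConfig, make_environment, simulate_tracks


@pytest.fixture(scope="session")
def env():
    """Shared synthetic environment (full-size grid, all months)."""
    return make_environment(seed=5)


@pytest.fixture(scope="session")
def small_tracks(env):
    """A small two-colony simulation reused across tests."""
    cfg = SimConfig(seed=3, n_birds={"CI": 3, "SG": 3})
    return cfg, simulate_tracks(env, cfg, start="2012-06-01", n_days=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
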