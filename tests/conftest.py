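import numpy as np
import pytest

from actema.simulate import SyntheticConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_minute_sim():
    """A small study simulated down to the minute trace (shared, read-only)."""
    cfg = SyntheticConfig(n_participants=8, n_days=2, signal_level="minute",
                          seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def observation_sim():
    """Observation-level study at moderate scale for model-grid tests."""
    cfg = SyntheticConfig(n_participants=40, n_days=5, seed=21,
                          likert_mode="discrete")
    return simulate(cfg)
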