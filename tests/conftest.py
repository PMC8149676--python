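import numpy as np
import pytest

from sleepreplay import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A light configuration for fast unit tests (3 channels: Cz + mastoids)."""
    return SimConfig(
        n_participants=4,
        n_channels=3,
        nap_duration=900.0,
        n_localizer_trials=40,
        seed=11,
    )


@pytest.fixture
def nap_cfg():
    """A 30-min nap at full channel count, for detector validation."""
    return SimConfig(nap_duration=1800.0, seed=1)
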