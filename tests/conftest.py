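import numpy as np
import pytest

import mdtsim as m


@pytest.fixture
def tube():
    """Straight tube with the pulsatile (repaired) waveform."""
    return m.straight_tube_network()


@pytest.fixture
def steady_tube():
    """Straight tube with a constant mean velocity of 0.2 m/s."""
    return m.straight_tube_network(constant_mean_velocity=0.2)


@pytest.fixture
def magnet():
    return m.MagnetModel()


@pytest.fixture
def chi():
    return m.MagneticSusceptibilitySpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
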