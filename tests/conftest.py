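import numpy as np
import pytest

from autobilayer.simulate import ChannelScenario, NoiseSpec, load_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def e71a():
    scenario, noise = load_preset("kcsa_e71a_decane")
    return scenario, noise


@pytest.fixture
def wt_control():
    scenario, noise = load_preset("kcsa_wt_control")
    return scenario, noise


@pytest.fixture
def simple_scenario():
    """Single-channel, symmetric kinetics, 100 pS: unitary 10 pA at 100 mV."""
    return ChannelScenario(
        name="simple",
        conductance_g=100.0,
        reversal_E=0.0,
        open_prob=0.5,
        mean_open=50.0,
        fixed_channel_count=1,
    )


@pytest.fixture
def no_noise():
    return NoiseSpec.none()
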