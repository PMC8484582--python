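import pytest

from windsock.channels import get_channel
from windsock.flowmeter import STUDY_PROTOCOL
from windsock.rod import RodParams, ThermalEnv


@pytest.fixture(scope="session")
def rod():
    """Default 5 µm × 12 nm nanotube."""
    return RodParams()


@pytest.fixture(scope="session")
def env():
    """Water at 20 °C, automatic time step."""
    return ThermalEnv()


@pytest.fixture(scope="session")
def glass_channel():
    """The channel used for glass-anchored rods (µ-slide VI 0.5)."""
    return get_channel("ibidi_VI_0.5")


@pytest.fixture(scope="session")
def cell_channel():
    """The channel used for cell-anchored rods (µ-slide VI 0.4)."""
    return get_channel("ibidi_VI_0.4")


@pytest.fixture(scope="session")
def protocol():
    return STUDY_PROTOCOL
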