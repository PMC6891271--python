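import numpy as np
import pytest

from uterosim.channels import ChannelSpec, GateSpec, TauSpec
from uterosim.clamp import ClampProtocol


@pytest.fixture
def sodium_channel() -> ChannelSpec:
    """Sodium channel with the myometrium-fitted Boltzmann gates."""
    return ChannelSpec(
        name="na", gbar=8.0, e_rev=83.0,
        gates=[
            GateSpec(name="m", kind="activation", v_half=-20.3, slope=6.2,
                     exponent=3, tau=TauSpec(ms=0.45)),
            GateSpec(name="h", kind="inactivation", v_half=-46.2, slope=7.2,
                     exponent=1, tau=TauSpec(ms=30.0)),
        ])


@pytest.fixture
def potassium_channel() -> ChannelSpec:
    """Voltage-gated potassium channel (K1) with fitted n and q gates."""
    return ChannelSpec(
        name="k1", gbar=2.0, e_rev=-80.0,
        gates=[
            GateSpec(name="n", kind="activation", v_half=-13.0, slope=13.0,
                     exponent=4, tau=TauSpec(ms=20.0)),
            GateSpec(name="q", kind="inactivation", v_half=-38.0, slope=6.0,
                     exponent=1, tau=TauSpec(ms=400.0)),
        ])


@pytest.fixture
def na_protocol() -> ClampProtocol:
    return ClampProtocol(holding_mV=-80.0, steps_mV=[-40.0, -20.0, 0.0],
                         onset_ms=11.0, duration_ms=100.0, dt_ms=0.1)


@pytest.fixture
def k_protocol() -> ClampProtocol:
    return ClampProtocol(holding_mV=-80.0,
                         steps_mV=[-20.0, 0.0, 20.0, 40.0, 60.0],
                         onset_ms=11.0, duration_ms=400.0, dt_ms=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
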