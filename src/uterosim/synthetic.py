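"""Seeded synthetic voltage-clamp data.

Generates clamp traces from a known channel specification plus additive
Gaussian noise (standard deviation expressed as a fraction of each step's
post-stimulus peak), emulating normalized patch-clamp recordings from human
myometrial cells.  All randomness flows through one ``numpy`` generator
seeded from the spec, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .channels import ChannelSpec
from .clamp import ClampExperiment, ClampProtocol, simulate_clamp

__all__ = ["SyntheticSpec", "generate_clamp_fixture", "calcium_pulse",
           "sodium_fixture_spec", "potassium_fixture_spec",
           "NA_FIT_PROTOCOL", "NA_MORPHOLOGY_PROTOCOL", "K1_FIT_PROTOCOL"]

# Study protocols for the synthetic myometrial clamp fixtures.  The sodium
# stimulus lands at 11 ms; fitting sweeps are short and transient-focused
# (that is where the kinetic information is), while the morphology sweep is
# long enough to show the full inactivation decay.
NA_FIT_PROTOCOL = dict(holding_mV=-80.0, steps_mV=[-40.0, -20.0, 0.0],
                       onset_ms=11.0, duration_ms=20.0, dt_ms=0.05)
NA_MORPHOLOGY_PROTOCOL = dict(holding_mV=-80.0, steps_mV=[-40.0, -20.0, 0.0],
                              onset_ms=11.0, duration_ms=100.0, dt_ms=0.1)
K1_FIT_PROTOCOL = dict(holding_mV=-80.0,
                       steps_mV=[-20.0, 0.0, 20.0, 40.0, 60.0],
                       onset_ms=30.0, duration_ms=70.0, dt_ms=0.25)


class SyntheticSpec(BaseModel):
    """Generating channel, protocol, noise level and seed for one fixture."""

    model_config = ConfigDict(extra="forbid")

    channel: ChannelSpec
    protocol: ClampProtocol = Field(default_factory=ClampProtocol)
    noise_sd: float = Field(0.0, ge=0.0)   # fraction of per-step peak |I|
    seed: int = 0


def generate_clamp_fixture(spec: SyntheticSpec) -> ClampExperiment:
    """Simulate clamp traces and add seeded Gaussian noise.

    With ``noise_sd = 0`` the output equals :func:`simulate_clamp` exactly;
    identical seeds give identical traces.
    """
    exp = simulate_clamp(spec.channel, spec.protocol)
    traces = exp.traces.copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        onset = int(round(spec.protocol.onset_ms / spec.protocol.dt_ms))
        for i in range(traces.shape[0]):
            peak = np.max(np.abs(traces[i, onset:]))
            traces[i] += rng.normal(0.0, spec.noise_sd * peak, size=traces.shape[1])
    meta = dict(exp.metadata, synthetic=True, seed=spec.seed,
                noise_sd=spec.noise_sd)
    return ClampExperiment(protocol=exp.protocol, time_ms=exp.time_ms,
                           traces=traces, metadata=meta)


def sodium_fixture_spec(noise_sd: float = 0.05, seed: int = 42,
                        morphology: bool = False) -> SyntheticSpec:
    """Synthetic sodium-clamp fixture emulating the myometrial recordings."""
    from .defaults import CLAMP_REFERENCE_CHANNELS
    proto = NA_MORPHOLOGY_PROTOCOL if morphology else NA_FIT_PROTOCOL
    return SyntheticSpec(channel=CLAMP_REFERENCE_CHANNELS["na"],
                         protocol=ClampProtocol(**proto),
                         noise_sd=noise_sd, seed=seed)


def potassium_fixture_spec(noise_sd: float = 0.05, seed: int = 43) -> SyntheticSpec:
    """Synthetic potassium (K1) clamp fixture."""
    from .defaults import CLAMP_REFERENCE_CHANNELS
    return SyntheticSpec(channel=CLAMP_REFERENCE_CHANNELS["k1"],
                         protocol=ClampProtocol(**K1_FIT_PROTOCOL),
                         noise_sd=noise_sd, seed=seed)


def calcium_pulse(duration_ms: float = 30000.0, dt_ms: float = 10.0,
                  baseline_uM: float = 0.1, peak_uM: float = 0.8,
                  onset_ms: float = 1000.0, rise_ms: float = 300.0,
                  decay_ms: float = 2500.0) -> tuple[np.ndarray, np.ndarray]:
    """Smooth synthetic calcium transient (time_ms, ca_uM) for driving the
    cross-bridge model without a cell simulation."""
    t = dt_ms * np.arange(int(round(duration_ms / dt_ms)) + 1)
    dtp = np.clip(t - onset_ms, 0.0, None)
    shape = (1.0 - np.exp(-dtp / rise_ms)) * np.exp(-dtp / decay_ms)
    shape[t < onset_ms] = 0.0
    peak = shape.max()
    if peak > 0:
        shape /= peak
    return t, baseline_uM + (peak_uM - baseline_uM) * shape
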