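"""Hodgkin-Huxley gate kinetics and ionic current formulas.

Each ionic channel is described by a maximal conductance ``gbar``, a constant
reversal potential ``e_rev`` (Goldman-derived, supplied in configuration) and
a set of first-order gates.  A gate relaxes towards a voltage-dependent
Boltzmann steady state

    x_inf(V) = 1 / (1 + exp(-s (V - V_half) / k)),      s = +1 activation,
                                                        s = -1 inactivation,

with kinetics ``dx/dt = (x_inf - x) / tau``.  Calcium-driven gates (the
calcium-dependent inactivation of the L-type channel, the calcium-activated
chloride gate) use a Hill function of intracellular calcium instead of a
Boltzmann function of voltage.

Sign convention: currents are ``gbar * prod(gates) * (V - e_rev)``, i.e.
positive = outward, negative = inward.  The membrane equation is
``Cm dV/dt = -sum(I) + I_stim``.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import expit

from .errors import ConfigurationError

__all__ = [
    "TauSpec",
    "GateSpec",
    "ChannelSpec",
    "CalciumGateSet",
    "boltzmann_steady_state",
    "steady_state",
    "gate_tau",
    "gate_derivative",
    "hh_current",
    "ical_current",
    "icat_current",
    "nernst_potential",
]

FARADAY = 96485.332  # C/mol
GAS_R = 8.314462     # J/(mol K)


class TauSpec(BaseModel):
    """Time-constant model for one gate.

    ``constant`` is a fixed value in ms.  ``bell`` adds a Gaussian bump on a
    baseline, ``tau(V) = base + amp * exp(-((V - v_mid)/width)^2)``, the usual
    shape for voltage-dependent time constants.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["constant", "bell"] = "constant"
    ms: float = Field(1.0, gt=0.0)
    amp: float = Field(0.0, ge=0.0)
    v_mid: float = 0.0
    width: float = Field(10.0, gt=0.0)

    def __call__(self, v: float) -> float:
        if self.kind == "constant":
            return self.ms
        return self.ms + self.amp * math.exp(-(((v - self.v_mid) / self.width) ** 2))


class GateSpec(BaseModel):
    """One activation or inactivation gate.

    Voltage-driven gates (``driver='v'``) follow the Boltzmann steady state
    above; calcium-driven gates (``driver='ca'``) follow a Hill function with
    half-saturation ``ca_half`` (uM) and coefficient ``hill``.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    kind: Literal["activation", "inactivation"]
    exponent: int = Field(1, ge=1)
    driver: Literal["v", "ca"] = "v"
    v_half: float = 0.0
    slope: float = Field(1.0, gt=0.0)
    ca_half: float = Field(1.0, gt=0.0)
    hill: float = Field(2.0, gt=0.0)
    tau: TauSpec = Field(default_factory=TauSpec)
    sign: Optional[int] = None  # +1 activation-style, -1 inactivation-style

    @field_validator("tau", mode="before")
    @classmethod
    def _coerce_tau(cls, value):
        if isinstance(value, (int, float)):
            return TauSpec(ms=float(value))
        return value

    @model_validator(mode="after")
    def _default_sign(self):
        expected = 1 if self.kind == "activation" else -1
        if self.sign is None:
            object.__setattr__(self, "sign", expected)
        elif self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        return self


def boltzmann_steady_state(spec: GateSpec, v: float):
    """Boltzmann open probability of a voltage-driven gate at potential ``v``.

    Uses the numerically safe logistic, so it cannot overflow for any finite
    voltage.  Activation gates increase with ``v``; inactivation gates
    decrease.
    """
    if spec.driver != "v":
        raise ConfigurationError(f"gate '{spec.name}' is not voltage-driven")
    return expit(spec.sign * (np.asarray(v, dtype=float) - spec.v_half) / spec.slope)


def _hill_steady_state(spec: GateSpec, ca: float):
    ca = np.maximum(np.asarray(ca, dtype=float), 1e-12)
    r = (ca / spec.ca_half) ** spec.hill
    frac = r / (1.0 + r)
    return frac if spec.kind == "activation" else 1.0 - frac


def steady_state(spec: GateSpec, v: float, ca: float | None = None):
    """Steady-state value of a gate given voltage and, if needed, calcium."""
    if spec.driver == "v":
        return boltzmann_steady_state(spec, v)
    if ca is None:
        raise ConfigurationError(f"gate '{spec.name}' needs a calcium value")
    return _hill_steady_state(spec, ca)


def gate_tau(spec: GateSpec, v: float) -> float:
    """Time constant of a gate at potential ``v`` (ms)."""
    tau = spec.tau(v)
    if tau <= 0.0:
        raise ConfigurationError(f"gate '{spec.name}': non-positive tau at V={v}")
    return tau


def gate_derivative(spec: GateSpec, v: float, x, ca: float | None = None):
    """First-order relaxation rate ``(x_inf - x)/tau`` in 1/ms.

    The fixed point is ``x = x_inf(v)``; under constant voltage the solution
    is the usual exponential relaxation with time constant ``tau(v)``.
    """
    return (steady_state(spec, v, ca) - np.asarray(x, dtype=float)) / gate_tau(spec, v)


class CaGainSpec(BaseModel):
    """Instantaneous calcium modulation of a conductance.

    Multiplier ``floor + (1-floor) * ca^h / (ca^h + ca_half^h)`` in
    ``[floor, 1]`` -- a stand-in for calcium-activated conductances whose
    gating kinetics are not resolved here.
    """

    model_config = ConfigDict(extra="forbid")

    ca_half: float = Field(1.0, gt=0.0)
    hill: float = Field(1.0, gt=0.0)
    floor: float = Field(0.0, ge=0.0, le=1.0)

    def __call__(self, ca: float):
        ca = np.maximum(np.asarray(ca, dtype=float), 1e-12)
        r = (ca / self.ca_half) ** self.hill
        return self.floor + (1.0 - self.floor) * r / (1.0 + r)


class WeightedGateGroup(BaseModel):
    """Convex combination of parallel inactivation gates, e.g. the L-type
    calcium channel's ``0.8 f1 + 0.2 f2``."""

    model_config = ConfigDict(extra="forbid")

    weights: list[float]
    gates: list[GateSpec]

    @model_validator(mode="after")
    def _check(self):
        if len(self.weights) != len(self.gates):
            raise ValueError("weights and gates must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        return self


class ChannelSpec(BaseModel):
    """One ionic current.

    ``form='ohmic'`` (default): I = gbar * O * (V - e_rev), with the open
    fraction O the product of the gate terms.  ``form='source'`` drops the
    driving force and uses I = amp * O -- used for the pump/exchanger
    stand-ins, which are not conductance-like.

    ``inst_gates`` are instantaneous voltage factors (gates assumed at steady
    state, no ODE); ``ca_gain`` is an instantaneous calcium factor.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    gbar: float = Field(0.0, ge=0.0)
    e_rev: float = 0.0
    form: Literal["ohmic", "source"] = "ohmic"
    amp: float = 0.0  # signed, used only by form='source'
    gates: list[GateSpec] = Field(default_factory=list)
    weighted: Optional[WeightedGateGroup] = None
    inst_gates: list[GateSpec] = Field(default_factory=list)
    ca_gain: Optional[CaGainSpec] = None
    oxy_sensitive: bool = False

    def state_gates(self) -> list[GateSpec]:
        """Gates integrated as state variables, in state-vector order."""
        out = list(self.gates)
        if self.weighted is not None:
            out.extend(self.weighted.gates)
        return out

    def open_fraction(self, gate_values: Sequence[float], v: float, ca: float) -> float:
        """Product of all gate terms for the given state-gate values."""
        ngate = len(self.gates)
        expected = ngate + (len(self.weighted.gates) if self.weighted else 0)
        if len(gate_values) != expected:
            raise ConfigurationError(
                f"channel '{self.name}': expected {expected} gate values, "
                f"got {len(gate_values)}"
            )
        o = 1.0
        for spec, x in zip(self.gates, gate_values[:ngate]):
            o *= float(x) ** spec.exponent
        if self.weighted is not None:
            o *= float(
                sum(w * float(x) for w, x in zip(self.weighted.weights, gate_values[ngate:]))
            )
        for spec in self.inst_gates:
            o *= float(steady_state(spec, v, ca))
        if self.ca_gain is not None:
            o *= float(self.ca_gain(ca))
        return o

    def current(self, gate_values: Sequence[float], v: float, ca: float = 0.0) -> float:
        o = self.open_fraction(gate_values, v, ca)
        if self.form == "source":
            return self.amp * o
        return self.gbar * o * (v - self.e_rev)


def hh_current(spec: ChannelSpec, gate_values: Sequence[float], v: float) -> float:
    """Hodgkin-Huxley current ``gbar * prod(x_i^p_i) * (V - e_rev)``.

    ``gate_values`` must supply one value per gate of ``spec`` (simple gates
    only).  Positive return = outward current.
    """
    if len(gate_values) != len(spec.gates):
        raise ConfigurationError(
            f"channel '{spec.name}': expected {len(spec.gates)} gate values, "
            f"got {len(gate_values)}"
        )
    o = 1.0
    for g, x in zip(spec.gates, gate_values):
        o *= float(x) ** g.exponent
    return spec.gbar * o * (v - spec.e_rev)


class CalciumGateSet(BaseModel):
    """Gate values for the two calcium channels at one instant.

    ``d``/``b`` activation, ``f1``/``f2``/``g`` inactivation, ``f_ca`` the
    calcium-dependent inhibition factor.  The two L-type inactivation gates
    combine with fixed weights 0.8/0.2.
    """

    model_config = ConfigDict(extra="forbid")

    d: float = Field(ge=0.0, le=1.0)
    b: float = Field(ge=0.0, le=1.0)
    f1: float = Field(ge=0.0, le=1.0)
    f2: float = Field(ge=0.0, le=1.0)
    g: float = Field(ge=0.0, le=1.0)
    f_ca: float = Field(ge=0.0, le=1.0)
    w1: float = 0.8
    w2: float = 0.2

    @model_validator(mode="after")
    def _weights(self):
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError("w1 + w2 must equal 1")
        return self


def ical_current(params, d: float, f1: float, f2: float, f_ca: float, v: float,
                 w1: float = 0.8, w2: float = 0.2) -> float:
    """L-type calcium current: ``gCaL d^2 fCa (w1 f1 + w2 f2) (V - ECaL)``.

    ``params`` is any object with ``gbar`` and ``e_rev`` attributes (normally
    a :class:`ChannelSpec`).
    """
    return params.gbar * d * d * f_ca * (w1 * f1 + w2 * f2) * (v - params.e_rev)


def icat_current(params, b: float, g: float, v: float) -> float:
    """T-type calcium current: ``gCaT b^2 g (V - ECaT)``."""
    return params.gbar * b * b * g * (v - params.e_rev)


def nernst_potential(valence: int, conc_in: float, conc_out: float,
                     temperature_c: float = 37.0) -> float:
    """Nernst equilibrium potential in mV from concentrations (same units).

    Convenience helper only; the model itself takes reversal potentials as
    configuration constants.
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ConfigurationError("concentrations must be positive")
    t_kelvin = temperature_c + 273.15
    return 1000.0 * GAS_R * t_kelvin / (valence * FARADAY) * math.log(conc_out / conc_in)
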