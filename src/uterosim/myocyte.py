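"""Single-cell membrane model of the uterine myocyte.

The cell model assembles ionic channels (Kirchhoff's current law) into

    Cm dV/dt = -sum(I_ionic) + I_stim,

with first-order Hodgkin-Huxley gate kinetics and a lumped intracellular
calcium balance

    d[Ca]/dt = -alpha (I_CaL + I_CaT) - ([Ca] - [Ca]_rest) / tau_Ca.

Two variants are supported: the *full* model (all configured currents) and
the *simplified* model retaining the five currents that dominate the
stability of the resting state (I_CaL, I_CaT, I_K1, I_K2, I_NSCC; thirteen
state variables).  The simplified model integrates its own potential V_sim
and reports the output action potential V_ap = V_sim + V_b, with V_b a
constant background offset.

State-vector layout: ``[V, Ca, gate_1, ..., gate_n]`` with gates in channel
order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.integrate import solve_ivp
from scipy.special import expit

from .channels import ChannelSpec, GateSpec, steady_state
from .errors import ConfigurationError, InputError, IntegrationError
from .oxytocin import OxytocinSetting, oxy_gain

__all__ = [
    "MembraneSpec",
    "CalciumSpec",
    "CellConfig",
    "CellState",
    "StimulusProtocol",
    "SimplifiedModelSpec",
    "SimulationResult",
    "APFeatures",
    "Model",
    "full_model_rhs",
    "simplified_model_rhs",
    "calcium_balance",
    "simulate",
    "extract_ap_features",
]

SIMPLIFIED_CURRENTS = ("cal", "cat", "k1", "k2", "nscc")


class MembraneSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cm: float = Field(1.0, gt=0.0)     # membrane capacitance (uF per unit area)
    vb: float = 0.0                    # reporting offset V_ap = V_sim + V_b (mV)
    v_init: float = -45.0              # initial potential before equilibration


class CalciumSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(0.004, ge=0.0)   # uM per (current unit x ms)
    tau_ms: float = Field(2000.0, gt=0.0)
    rest_uM: float = Field(0.1, gt=0.0)
    floor_uM: float = Field(1e-4, gt=0.0)


class OxytocinParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a: float = Field(0.37, gt=0.0)
    c: float = 0.946


class CellConfig(BaseModel):
    """Complete parameterization of one cell model variant."""

    model_config = ConfigDict(extra="forbid")

    name: str = "cell"
    variant: Literal["full", "simplified"] = "full"
    membrane: MembraneSpec = Field(default_factory=MembraneSpec)
    calcium: CalciumSpec = Field(default_factory=CalciumSpec)
    oxytocin: OxytocinParams = Field(default_factory=OxytocinParams)
    channels: list[ChannelSpec] = Field(default_factory=list)
    ca_sources: list[str] = Field(default_factory=lambda: ["cal", "cat"])

    @model_validator(mode="after")
    def _unique_names(self):
        cnames = [c.name for c in self.channels]
        if len(set(cnames)) != len(cnames):
            raise ValueError("duplicate channel names")
        gnames = [g.name for c in self.channels for g in c.state_gates()]
        if len(set(gnames)) != len(gnames):
            raise ValueError("duplicate gate names across channels")
        if {"v", "ca"} & set(gnames):
            raise ValueError("gate names 'v' and 'ca' are reserved")
        for src in self.ca_sources:
            if src not in cnames:
                raise ValueError(f"ca_sources entry '{src}' is not a channel")
        return self

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def state_names(self) -> list[str]:
        return ["v", "ca"] + [g.name for c in self.channels for g in c.state_gates()]

    def fingerprint(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CellState:
    """Named view of one point in state space."""

    v: float
    ca: float
    gates: dict[str, float]

    def to_vector(self, config: CellConfig) -> np.ndarray:
        names = config.state_names()[2:]
        return np.array([self.v, self.ca] + [self.gates[n] for n in names])

    @classmethod
    def from_vector(cls, config: CellConfig, y: Sequence[float]) -> "CellState":
        names = config.state_names()
        if len(y) != len(names):
            raise InputError(f"state vector length {len(y)} != {len(names)}")
        return cls(v=float(y[0]), ca=float(y[1]),
                   gates={n: float(x) for n, x in zip(names[2:], y[2:])})


class StimulusProtocol(BaseModel):
    """Square current pulse(s): ``repeats`` pulses of ``duration_ms`` starting
    every ``interval_ms`` from ``onset_ms``."""

    model_config = ConfigDict(extra="forbid")

    onset_ms: float = Field(0.0, ge=0.0)
    duration_ms: float = Field(0.0, ge=0.0)
    amplitude: float = 0.0
    repeats: int = Field(1, ge=1)
    interval_ms: float = Field(0.0, ge=0.0)

    @model_validator(mode="after")
    def _finite(self):
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if self.repeats > 1 and self.interval_ms < self.duration_ms:
            raise ValueError("interval_ms must be >= duration_ms for pulse trains")
        return self

    def current(self, t: float) -> float:
        if self.amplitude == 0.0 or self.duration_ms == 0.0:
            return 0.0
        dt = t - self.onset_ms
        if dt < 0:
            return 0.0
        if self.repeats > 1 and self.interval_ms > 0:
            k = np.floor(dt / self.interval_ms)
            if k >= self.repeats:
                return 0.0
            dt = dt - k * self.interval_ms
        elif dt > self.duration_ms:
            return 0.0
        return self.amplitude if 0.0 <= dt <= self.duration_ms else 0.0

    def edges(self) -> list[float]:
        """Discontinuity times, for segmented integration."""
        out = []
        step = self.interval_ms if self.repeats > 1 else 0.0
        for k in range(self.repeats):
            t0 = self.onset_ms + k * step
            out.extend([t0, t0 + self.duration_ms])
        return sorted(set(out))


class SimplifiedModelSpec(BaseModel):
    """The reduced five-current model (13 state variables).

    Holds the retained channel specifications plus membrane capacitance and
    the background offset V_b used to report V_ap = V_sim + V_b.
    """

    model_config = ConfigDict(extra="forbid")

    channels: list[ChannelSpec]
    cm: float = Field(1.0, gt=0.0)
    vb: float = 0.0
    calcium: CalciumSpec = Field(default_factory=CalciumSpec)
    oxytocin: OxytocinParams = Field(default_factory=OxytocinParams)
    warnings_: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        if not self.channels:
            raise ValueError("simplified model needs at least one current")
        names = {c.name for c in self.channels}
        if names == set(SIMPLIFIED_CURRENTS) and self.n_state_vars != 13:
            raise ValueError(
                f"canonical simplified model must have 13 state variables, "
                f"got {self.n_state_vars}")
        return self

    @property
    def n_state_vars(self) -> int:
        return 2 + sum(len(c.state_gates()) for c in self.channels)

    def to_cell_config(self, name: str = "simplified") -> CellConfig:
        ca_src = [n for n in ("cal", "cat") if any(c.name == n for c in self.channels)]
        return CellConfig(
            name=name, variant="simplified",
            membrane=MembraneSpec(cm=self.cm, vb=self.vb),
            calcium=self.calcium, oxytocin=self.oxytocin,
            channels=self.channels, ca_sources=ca_src,
        )


# ---------------------------------------------------------------------------
# compiled model


class Model:
    """A :class:`CellConfig` compiled for fast right-hand-side evaluation.

    The oxytocin gain is applied once at construction to the conductances of
    the channels flagged ``oxy_sensitive`` (the L- and T-type calcium
    channels in the shipped configurations).
    """

    def __init__(self, config: CellConfig, oxy: float = 0.0):
        self.config = config
        self.oxy = float(oxy)
        self.gain = oxy_gain(OxytocinSetting(oxy=oxy, a=config.oxytocin.a,
                                             c=config.oxytocin.c))
        self.state_names = config.state_names()
        self.n = len(self.state_names)

        gates: list[GateSpec] = []
        self._channels = []
        pos = 0
        for ch in config.channels:
            sg = ch.state_gates()
            idx = np.arange(pos, pos + len(sg))
            gates.extend(sg)
            pos += len(sg)
            nsimple = len(ch.gates)
            exps = np.array([g.exponent for g in ch.gates], dtype=float)
            wts = (np.array(ch.weighted.weights) if ch.weighted is not None else None)
            gbar = ch.gbar * (self.gain if ch.oxy_sensitive else 1.0)
            self._channels.append({
                "spec": ch, "idx": idx, "nsimple": nsimple, "exps": exps,
                "wts": wts, "gbar": gbar,
            })
        self.gate_specs = gates
        self.n_gates = len(gates)

        # vectorized gate-kinetics tables
        self._is_v = np.array([g.driver == "v" for g in gates], dtype=bool)
        self._is_act = np.array([g.kind == "activation" for g in gates], dtype=bool)
        self._sign = np.array([g.sign for g in gates], dtype=float)
        self._vh = np.array([g.v_half for g in gates])
        self._sl = np.array([g.slope for g in gates])
        self._cah = np.array([g.ca_half for g in gates])
        self._hill = np.array([g.hill for g in gates])
        self._tau0 = np.array([g.tau.ms for g in gates])
        self._bells = [(i, g.tau) for i, g in enumerate(gates) if g.tau.kind == "bell"]
        self._ca_src = [i for i, e in enumerate(self._channels)
                        if e["spec"].name in config.ca_sources]
        self._ca_warned = False

    # -- gate kinetics ------------------------------------------------------

    def gate_steady(self, v: float, ca: float) -> np.ndarray:
        x = np.empty(self.n_gates)
        if self._is_v.any():
            m = self._is_v
            x[m] = expit(self._sign[m] * (v - self._vh[m]) / self._sl[m])
        if (~self._is_v).any():
            m = ~self._is_v
            r = (max(ca, 1e-12) / self._cah[m]) ** self._hill[m]
            frac = r / (1.0 + r)
            x[m] = np.where(self._is_act[m], frac, 1.0 - frac)
        return x

    def gate_tau(self, v: float) -> np.ndarray:
        tau = self._tau0.copy()
        for i, spec in self._bells:
            tau[i] = spec(v)
        return tau

    # -- currents -----------------------------------------------------------

    def _open_fraction(self, entry, gates, v, ca):
        ch: ChannelSpec = entry["spec"]
        g = gates[entry["idx"]]
        ns = entry["nsimple"]
        o = np.prod(g[:ns] ** entry["exps"]) if ns else 1.0
        if entry["wts"] is not None:
            o = o * float(entry["wts"] @ g[ns:])
        for spec in ch.inst_gates:
            o = o * float(steady_state(spec, v, ca))
        if ch.ca_gain is not None:
            o = o * float(ch.ca_gain(ca))
        return o

    def channel_current(self, entry, gates, v, ca) -> float:
        ch: ChannelSpec = entry["spec"]
        o = self._open_fraction(entry, gates, v, ca)
        if ch.form == "source":
            return ch.amp * o
        return entry["gbar"] * o * (v - ch.e_rev)

    def currents(self, y: Sequence[float]) -> dict[str, float]:
        """Per-channel currents at one state point (positive = outward)."""
        y = np.asarray(y, dtype=float)
        v, ca, gates = y[0], y[1], y[2:]
        return {e["spec"].name: self.channel_current(e, gates, v, ca)
                for e in self._channels}

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray,
            istim: Optional[Callable[[float], float]] = None) -> np.ndarray:
        v, ca = y[0], max(y[1], 1e-12)
        gates = y[2:]
        dy = np.empty_like(y)

        x_inf = self.gate_steady(v, ca)
        dy[2:] = (x_inf - gates) / self.gate_tau(v)

        i_tot = 0.0
        i_ca = 0.0
        for j, entry in enumerate(self._channels):
            i = self.channel_current(entry, gates, v, ca)
            i_tot += i
            if j in self._ca_src:
                i_ca += i
        stim = istim(t) if istim is not None else 0.0
        dy[0] = (-i_tot + stim) / self.config.membrane.cm

        cs = self.config.calcium
        dca = -cs.alpha * i_ca - (ca - cs.rest_uM) / cs.tau_ms
        if ca <= cs.floor_uM and dca < 0.0:
            if not self._ca_warned:
                warnings.warn("intracellular calcium clipped at floor", stacklevel=2)
                self._ca_warned = True
            dca = 0.0
        dy[1] = dca

        if not np.all(np.isfinite(dy)):
            bad = [e["spec"].name for e in self._channels
                   if not np.isfinite(self.channel_current(e, gates, v, ca))]
            raise IntegrationError(
                f"non-finite derivative at t={t} (channels: {bad or 'gate/ca terms'})")
        return dy

    def initial_state(self, v: float | None = None, ca: float | None = None) -> np.ndarray:
        v = self.config.membrane.v_init if v is None else v
        ca = self.config.calcium.rest_uM if ca is None else ca
        return np.concatenate([[v, ca], self.gate_steady(v, ca)])


_MODEL_CACHE: dict[tuple[str, float], Model] = {}


def get_model(config: CellConfig, oxy: float = 0.0) -> Model:
    key = (config.fingerprint(), round(float(oxy), 12))
    if key not in _MODEL_CACHE:
        if len(_MODEL_CACHE) > 64:
            _MODEL_CACHE.clear()
        _MODEL_CACHE[key] = Model(config, oxy)
    return _MODEL_CACHE[key]


def full_model_rhs(state: Sequence[float], t: float, config: CellConfig,
                   oxy: float = 0.0,
                   istim: Optional[Callable[[float], float]] = None) -> np.ndarray:
    """State derivative of the full cell model at one point."""
    return get_model(config, oxy).rhs(t, np.asarray(state, dtype=float), istim)


def simplified_model_rhs(state: Sequence[float], t: float,
                         spec: SimplifiedModelSpec | CellConfig,
                         oxy: float = 0.0,
                         istim: Optional[Callable[[float], float]] = None) -> np.ndarray:
    """State derivative of the reduced five-current model."""
    config = spec.to_cell_config() if isinstance(spec, SimplifiedModelSpec) else spec
    return get_model(config, oxy).rhs(t, np.asarray(state, dtype=float), istim)


def calcium_balance(ca: float, i_cal: float, i_cat: float, config: CellConfig) -> float:
    """d[Ca]/dt (uM/ms) for given calcium-channel currents.

    Inward (negative) calcium currents raise the concentration; a linear
    extrusion/buffering term relaxes it back to the resting level.
    """
    if ca <= 0:
        raise InputError("ca must be positive")
    cs = config.calcium
    return -cs.alpha * (i_cal + i_cat) - (ca - cs.rest_uM) / cs.tau_ms


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulationResult:
    """Trajectories on a uniform output grid.

    ``time_ms < 0`` is the pre-stimulus equilibration phase; the stimulus
    protocol runs on ``time_ms >= 0``.  ``v`` is the *reported* potential
    (V_ap = V_sim + V_b for the simplified variant; V_b = 0 for the full
    model).
    """

    time_ms: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    gates: dict[str, np.ndarray]
    currents: dict[str, np.ndarray]
    stim: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time_ms)
        if np.any(np.diff(self.time_ms) <= 0):
            raise InputError("time grid must be strictly increasing")
        for arr in [self.v, self.ca, self.stim, *self.gates.values(),
                    *self.currents.values()]:
            if len(arr) != n:
                raise InputError("all trajectories must share the time grid")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time_ms, "v_mV": self.v, "ca_uM": self.ca}
        for k, arr in self.gates.items():
            data[f"gate_{k}"] = arr
        for k, arr in self.currents.items():
            data[f"i_{k}"] = arr
        data["i_stim"] = self.stim
        return pd.DataFrame(data)


def _integrate(model: Model, y0: np.ndarray, t0: float, t1: float,
               istim, dt_out: float, rtol: float, atol: float,
               method: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one smooth segment; returns (t_samples, y_samples, y_end).

    Samples fall on the global ``dt_out`` grid; the segment end ``t1`` is
    always included so stimulus edges are resolved exactly.
    """
    k0 = int(np.floor(t0 / dt_out + 1e-9)) + 1
    grid = dt_out * np.arange(k0, int(np.floor(t1 / dt_out + 1e-9)) + 1)
    grid = grid[(grid > t0 + 1e-9) & (grid < t1 - 1e-9)]
    t_eval = np.concatenate([grid, [t1]])
    sol = solve_ivp(lambda t, y: model.rhs(t, y, istim), (t0, t1), y0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        v_last = sol.y[0, -1] if sol.y.size else y0[0]
        raise IntegrationError(
            f"solver failed on [{t0}, {t1}]: {sol.message}; last v={v_last:.3f}")
    return sol.t, sol.y, sol.y[:, -1].copy()


def simulate(config: CellConfig,
             protocol: StimulusProtocol,
             duration_ms: float,
             oxy: float = 0.0,
             equil_ms: float = 10000.0,
             dt_out: float = 1.0,
             rtol: float = 1e-7,
             atol: float = 1e-9,
             method: str = "LSODA",
             y0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate the cell model under a stimulus protocol.

    The run starts with a stimulus-free equilibration phase of ``equil_ms``
    (reported at negative times) so that the resting potential used by
    feature extraction is a model steady state rather than an initial
    condition.  Integration is segmented at stimulus edges so the square
    pulse is resolved exactly.
    """
    if duration_ms <= 0:
        raise InputError("duration_ms must be positive")
    model = get_model(config, oxy)
    y = model.initial_state() if y0 is None else np.asarray(y0, dtype=float)

    edges = [t for t in protocol.edges() if 0.0 < t < duration_ms]
    breakpoints = [-float(equil_ms), 0.0] + edges + [float(duration_ms)]
    breakpoints = sorted(set(breakpoints))

    ts, ys = [np.array([breakpoints[0]])], [y[:, None].copy()]
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        istim = (None if t1 <= 0 else protocol.current)
        seg_t, seg_y, y = _integrate(model, y, t0, t1, istim,
                                     dt_out, rtol, atol, method)
        if seg_t.size:
            ts.append(seg_t)
            ys.append(seg_y)
    time = np.concatenate(ts)
    traj = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(time) > 1e-12])
    time, traj = time[keep], traj[:, keep]

    vb = config.membrane.vb
    gate_names = model.state_names[2:]
    gates = {n: traj[2 + i] for i, n in enumerate(gate_names)}
    cur: dict[str, np.ndarray] = {e["spec"].name: np.empty(len(time))
                                  for e in model._channels}
    for k in range(len(time)):
        for e in model._channels:
            cur[e["spec"].name][k] = model.channel_current(
                e, traj[2:, k], traj[0, k], traj[1, k])
    stim = np.array([protocol.current(t) if t >= 0 else 0.0 for t in time])

    meta = {
        "config": config.name,
        "variant": config.variant,
        "config_hash": config.fingerprint(),
        "oxy": float(oxy),
        "oxy_gain": model.gain,
        "vb": vb,
        "solver": {"method": method, "rtol": rtol, "atol": atol, "dt_out": dt_out},
        "equil_ms": float(equil_ms),
        "stim_onset_ms": protocol.onset_ms,
        "protocol": protocol.model_dump(),
    }
    return SimulationResult(time_ms=time, v=traj[0] + vb, ca=traj[1],
                            gates=gates, currents=cur, stim=stim, metadata=meta)


# ---------------------------------------------------------------------------
# feature extraction


@dataclass
class APFeatures:
    """Operational action-potential features.

    resting      mean reported V over the final 20 % of the equilibration
    peak         global maximum of V at t >= 0
    amplitude    peak - resting
    v_range      max - min of V at t >= 0
    plateau_s    total time (s) with V > resting + 10 mV after stimulus onset
    n_spikes     upward crossings of resting + amplitude/2, >= 50 ms apart
    """

    resting: float
    peak: float
    amplitude: float
    v_range: float
    plateau_s: float
    n_spikes: int
    spike_times_ms: list[float]

    def to_dict(self) -> dict:
        return {
            "resting_mV": self.resting, "peak_mV": self.peak,
            "amplitude_mV": self.amplitude, "range_mV": self.v_range,
            "plateau_s": self.plateau_s, "n_spikes": self.n_spikes,
            "spike_times_ms": list(self.spike_times_ms),
        }


def extract_ap_features(result: SimulationResult,
                        plateau_offset_mV: float = 10.0,
                        spike_refractory_ms: float = 50.0) -> APFeatures:
    """Extract resting potential, amplitude, range, plateau duration and
    spike count from a simulation that includes an equilibration window."""
    t, v = result.time_ms, result.v
    pre = t < 0
    if not pre.any():
        raise InputError("result has no pre-stimulus equilibration window")
    t_pre = t[pre]
    window = t_pre >= t_pre[0] + 0.8 * (t_pre[-1] - t_pre[0])
    resting = float(np.mean(v[pre][window]))

    post = t >= 0
    v_post, t_post = v[post], t[post]
    peak = float(np.max(v_post))
    amplitude = peak - resting
    v_range = float(np.max(v_post) - np.min(v_post))

    onset = float(result.metadata.get("stim_onset_ms", 0.0))
    after = t_post >= onset
    plateau_ms = 0.0
    if after.sum() > 1:
        ta, va = t_post[after], v_post[after]
        above = va > resting + plateau_offset_mV
        seg = np.diff(ta)
        plateau_ms = float(np.sum(seg * (above[:-1] & above[1:])))

    thresh = resting + 0.5 * amplitude
    spike_times: list[float] = []
    if amplitude > 1.0:
        crossings = np.flatnonzero((v_post[:-1] <= thresh) & (v_post[1:] > thresh))
        for i in crossings:
            tc = float(t_post[i + 1])
            if not spike_times or tc - spike_times[-1] >= spike_refractory_ms:
                spike_times.append(tc)

    return APFeatures(resting=resting, peak=peak, amplitude=amplitude,
                      v_range=v_range, plateau_s=plateau_ms / 1000.0,
                      n_spikes=len(spike_times), spike_times_ms=spike_times)
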