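"""Voltage-clamp simulation and Boltzmann parameter fitting.

A clamp sweep holds the membrane at a fixed potential, steps to a test
potential at the stimulus onset (11 ms by convention for the myometrial
recordings this module emulates), and records the channel current.  Under a
constant potential every gate relaxes along the closed-form exponential

    x(t) = x_inf(V_step) + (x(0) - x_inf(V_step)) exp(-t / tau(V_step)),

so clamp traces are computed analytically -- no ODE solver involved.

Fitting recovers gate parameters (V_half, slope, tau) from normalized traces
jointly across step potentials by trust-region nonlinear least squares with
seeded multistart.  Traces are normalized by their post-stimulus peak
magnitude (as clamp data are usually plotted), which deliberately makes the
maximal conductance unidentifiable: gbar stays fixed, only the kinetic
parameters are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import least_squares

from .channels import ChannelSpec, GateSpec, TauSpec, gate_tau, steady_state
from .errors import FitError, InputError

__all__ = [
    "ClampProtocol",
    "ClampExperiment",
    "FitResult",
    "simulate_clamp",
    "normalize_trace",
    "trace_similarity",
    "fit_channel",
]


class ClampProtocol(BaseModel):
    """Timing and potentials of a voltage-clamp experiment."""

    model_config = ConfigDict(extra="forbid")

    holding_mV: float = -80.0
    steps_mV: list[float] = Field(default_factory=lambda: [-40.0, -20.0, 0.0])
    onset_ms: float = Field(11.0, ge=0.0)
    duration_ms: float = Field(100.0, gt=0.0)
    dt_ms: float = Field(0.1, gt=0.0)

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration_ms / self.dt_ms))
        return self.dt_ms * np.arange(n + 1)


@dataclass
class ClampExperiment:
    """Recorded (or simulated) per-step current traces on a uniform grid."""

    protocol: ClampProtocol
    time_ms: np.ndarray
    traces: np.ndarray  # shape (n_steps, n_samples)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape != (len(self.protocol.steps_mV), len(self.time_ms)):
            raise InputError(
                f"traces shape {self.traces.shape} does not match "
                f"{len(self.protocol.steps_mV)} steps x {len(self.time_ms)} samples")
        dt = np.diff(self.time_ms)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0] + 1e-12):
            raise InputError("clamp traces must be uniformly sampled")


def simulate_clamp(channel: ChannelSpec, protocol: ClampProtocol) -> ClampExperiment:
    """Analytic clamp traces for one channel under a step protocol.

    Gates start at their holding-potential steady state and relax
    exponentially after the step; the current follows the Hodgkin-Huxley
    product at each sample.
    """
    t = protocol.time_grid()
    post = np.clip(t - protocol.onset_ms, 0.0, None)
    traces = np.empty((len(protocol.steps_mV), len(t)))
    for i, v_step in enumerate(protocol.steps_mV):
        o = np.ones_like(t)
        for g in channel.gates:
            x0 = float(steady_state(g, protocol.holding_mV))
            xinf = float(steady_state(g, v_step))
            tau = gate_tau(g, v_step)
            x = np.where(t < protocol.onset_ms, x0,
                         xinf + (x0 - xinf) * np.exp(-post / tau))
            o = o * x ** g.exponent
        v = np.where(t < protocol.onset_ms, protocol.holding_mV, v_step)
        traces[i] = channel.gbar * o * (v - channel.e_rev)
    return ClampExperiment(protocol=protocol, time_ms=t, traces=traces,
                           metadata={"channel": channel.name, "synthetic": False})


def normalize_trace(trace: Sequence[float], onset_index: int = 0) -> np.ndarray:
    """Scale a trace by its maximum absolute value after the stimulus.

    The result lies in [-1, 1] and is idempotent under repeated
    normalization.  An (all-but-)zero trace raises :class:`InputError`.
    """
    trace = np.asarray(trace, dtype=float)
    peak = np.max(np.abs(trace[onset_index:]))
    if peak == 0.0:
        raise InputError("cannot normalize an all-zero trace")
    return trace / peak


def trace_similarity(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and mean squared error between two traces."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("traces must have equal length")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise InputError("correlation undefined for a zero-variance trace")
    corr = float(np.corrcoef(a, b)[0, 1])
    mse = float(np.mean((a - b) ** 2))
    return corr, mse


@dataclass
class FitResult:
    """Recovered channel parameters and per-step goodness of fit."""

    channel: ChannelSpec
    correlations: list[float]
    mse: list[float]
    converged: bool
    cost: float
    n_starts: int

    def __post_init__(self):
        for c in self.correlations:
            if not -1.0 - 1e-9 <= c <= 1.0 + 1e-9:
                raise InputError(f"correlation {c} outside [-1, 1]")
        if any(m < 0 for m in self.mse):
            raise InputError("MSE must be non-negative")


def _apply_theta(template: ChannelSpec, theta: np.ndarray) -> ChannelSpec:
    gates = []
    for i, g in enumerate(template.gates):
        vh, sl, tau = theta[3 * i: 3 * i + 3]
        gates.append(GateSpec(name=g.name, kind=g.kind, exponent=g.exponent,
                              v_half=float(vh), slope=float(sl),
                              tau=TauSpec(ms=float(tau))))
    return template.model_copy(update={"gates": gates})


def _normalized_traces(channel: ChannelSpec, protocol: ClampProtocol) -> np.ndarray:
    sim = simulate_clamp(channel, protocol)
    onset = int(round(protocol.onset_ms / protocol.dt_ms))
    out = np.empty_like(sim.traces)
    for i, tr in enumerate(sim.traces):
        peak = np.max(np.abs(tr[onset:]))
        out[i] = tr / peak if peak > 0 else tr
    return out


def fit_channel(experiment: ClampExperiment, template: ChannelSpec,
                seed: int = 0, n_starts: int = 5,
                tol: float = 1e-8) -> FitResult:
    """Fit gate parameters (V_half, slope, tau per gate) to clamp traces.

    Operates on normalized traces jointly across all step potentials, so
    ``gbar`` is fixed by design.  Uses trust-region reflective least squares
    with ``n_starts`` seeded multistart points jittered around the template;
    non-convergence is flagged, with the best-so-far parameters returned.
    """
    if len(experiment.protocol.steps_mV) < 2:
        raise FitError("need at least two step potentials to fit")
    if not template.gates:
        raise FitError("template channel has no gates to fit")
    protocol = experiment.protocol
    onset = int(round(protocol.onset_ms / protocol.dt_ms))
    target = np.array([normalize_trace(tr, onset) for tr in experiment.traces])

    theta0 = np.array([p for g in template.gates
                       for p in (g.v_half, g.slope, g.tau.ms)])
    lo = np.array([p for g in template.gates for p in (-150.0, 0.5, 0.02)])
    hi = np.array([p for g in template.gates for p in (100.0, 60.0, 5000.0)])

    def residuals(theta):
        sim = _normalized_traces(_apply_theta(template, theta), protocol)
        return (sim - target).ravel()

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(n_starts, 1)):
        if k == 0:
            start = theta0
        else:
            jitter = rng.normal(0.0, 1.0, size=theta0.size)
            start = theta0 + jitter * np.array(
                [s for g in template.gates for s in (8.0, 0.2 * g.slope, 0.3 * g.tau.ms)])
        start = np.clip(start, lo, hi)
        try:
            res = least_squares(residuals, start, bounds=(lo, hi),
                                method="trf", xtol=tol, ftol=tol, gtol=tol)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all optimization starts failed")

    fitted = _apply_theta(template, best.x)
    sim = _normalized_traces(fitted, protocol)
    corrs, mses = [], []
    for i in range(len(target)):
        c, m = trace_similarity(sim[i], target[i])
        corrs.append(c)
        mses.append(m)
    converged = bool(best.status > 0)
    return FitResult(channel=fitted, correlations=corrs, mse=mses,
                     converged=converged, cost=float(best.cost),
                     n_starts=max(n_starts, 1))
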