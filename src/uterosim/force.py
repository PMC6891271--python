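"""Hai-Murphy four-state cross-bridge model of smooth-muscle force.

Myosin cycles between four states: detached dephosphorylated (M), detached
phosphorylated (Mp), attached phosphorylated (AMp) and attached
dephosphorylated -- the slowly cycling "latch" bridge (here ``ama`` to avoid
a symbol clash with the oxytocin amplifier):

    d[M]/dt   = -K1 [M] + K2 [Mp] + K7 [AMa]
    d[Mp]/dt  =  K4 [AMp] + K1 [M] - (K2 + K3) [Mp]
    d[AMp]/dt =  K3 [Mp] + K6 [AMa] - (K4 + K5) [AMp]
    d[AMa]/dt =  K5 [AMp] - (K7 + K6) [AMa]

Calcium-dependent myosin-light-chain phosphorylation is the only regulatory
mechanism: K1 = K6 = k_max Ca^n / (Ca^n + k_half^n); K2..K5 and K7 are
constants.  Normalized stress is scale * ([AMp] + [AMa]).  Rates are in 1/s;
the slow latch detachment K7 makes force relax over tens of seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, InputError, IntegrationError
from .myocyte import CellConfig, SimulationResult, StimulusProtocol, simulate

__all__ = [
    "CrossBridgeState",
    "CrossBridgeRates",
    "StressOutput",
    "crossbridge_rhs",
    "crossbridge_steady_state",
    "stress_from_calcium",
    "coupled_simulation",
]


@dataclass
class CrossBridgeState:
    """Fractions of the four myosin states (sum to 1)."""

    m_frac: float
    mp_frac: float
    amp_frac: float
    ama_frac: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < -1e-12) or np.any(vals > 1.0 + 1e-12):
            raise InputError("cross-bridge fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise InputError("cross-bridge fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_frac, self.mp_frac, self.amp_frac, self.ama_frac])


class CrossBridgeRates(BaseModel):
    """Rate constants in 1/s; K1 = K6 is a Hill function of calcium (uM)."""

    model_config = ConfigDict(extra="forbid")

    k2: float = Field(0.5, ge=0.0)
    k3: float = Field(0.4, ge=0.0)
    k4: float = Field(0.1, ge=0.0)
    k5: float = Field(0.5, ge=0.0)
    k7: float = Field(0.08, ge=0.0)
    k_max: float = Field(1.2, ge=0.0)
    k_half: float = Field(1.6, gt=0.0)
    hill: float = Field(4.0, gt=0.0)

    def phosphorylation_rate(self, ca) -> np.ndarray:
        """K1 = K6 as a function of intracellular calcium."""
        ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
        r = (ca / self.k_half) ** self.hill
        return self.k_max * r / (1.0 + r)

    def matrix(self, k1: float) -> np.ndarray:
        """Generator matrix A with d(state)/dt = A @ state for fixed K1=K6."""
        k6 = k1
        return np.array([
            [-k1, self.k2, 0.0, self.k7],
            [k1, -(self.k2 + self.k3), self.k4, 0.0],
            [0.0, self.k3, -(self.k4 + self.k5), k6],
            [0.0, 0.0, self.k5, -(self.k7 + k6)],
        ])


def crossbridge_rhs(state: CrossBridgeState | Sequence[float],
                    rates: CrossBridgeRates, k1: float) -> np.ndarray:
    """Time derivative of the four fractions (1/s) for a given K1 = K6.

    The columns of the rate matrix sum to zero, so the total myosin fraction
    is conserved exactly.
    """
    if k1 < 0:
        raise ConfigurationError("rate constants must be non-negative")
    y = state.as_array() if isinstance(state, CrossBridgeState) else np.asarray(state, float)
    return rates.matrix(k1) @ y


def crossbridge_steady_state(rates: CrossBridgeRates, ca: float) -> CrossBridgeState:
    """Stationary distribution at constant calcium (null space of the rate
    matrix, normalized to sum to 1)."""
    k1 = float(rates.phosphorylation_rate(ca))
    a = rates.matrix(k1)
    # replace one balance equation by the conservation constraint
    sys = np.vstack([a[:3], np.ones(4)])
    rhs = np.array([0.0, 0.0, 0.0, 1.0])
    sol = np.linalg.solve(sys, rhs)
    sol = np.clip(sol, 0.0, None)
    sol = sol / sol.sum()
    return CrossBridgeState(*sol)


@dataclass
class StressOutput:
    """Normalized stress trajectory scale * ([AMp] + [AMa])."""

    time_ms: np.ndarray
    fractions: np.ndarray   # shape (4, n): M, Mp, AMp, AMa
    stress: np.ndarray
    scale: float
    metadata: dict = field(default_factory=dict)


def stress_from_calcium(ca_trajectory: Sequence[float],
                        time_ms: Sequence[float],
                        rates: CrossBridgeRates | None = None,
                        scale: float = 1.0,
                        y0: CrossBridgeState | None = None) -> StressOutput:
    """Drive the cross-bridge model with a calcium trajectory.

    ``k1 = k6`` follows the (interpolated) calcium signal; the four-state
    system is integrated in seconds and sampled back on the input grid.  The
    initial state defaults to the stationary distribution at the initial
    calcium level, so a resting calcium trace yields a constant baseline.
    """
    rates = rates or CrossBridgeRates()
    t_ms = np.asarray(time_ms, dtype=float)
    ca = np.asarray(ca_trajectory, dtype=float)
    if t_ms.shape != ca.shape or t_ms.ndim != 1 or len(t_ms) < 2:
        raise InputError("calcium trajectory and time grid must match (>= 2 points)")
    if np.any(ca <= 0):
        raise InputError("calcium trajectory must be positive")

    t_s = (t_ms - t_ms[0]) / 1000.0
    k1_samples = rates.phosphorylation_rate(ca)

    def k1_of_t(ts: float) -> float:
        return float(np.interp(ts, t_s, k1_samples))

    start = y0 or crossbridge_steady_state(rates, float(ca[0]))

    def rhs(ts, y):
        return rates.matrix(k1_of_t(ts)) @ y

    # cap the step so the solver cannot leap over a brief calcium transient
    # when starting from the resting steady state
    max_step = max(0.1, 5.0 * float(np.median(np.diff(t_s))))
    sol = solve_ivp(rhs, (t_s[0], t_s[-1]), start.as_array(), method="LSODA",
                    t_eval=t_s, rtol=1e-8, atol=1e-10, max_step=max_step)
    if not sol.success:
        raise IntegrationError(f"cross-bridge integration failed: {sol.message}")
    frac = sol.y
    stress = scale * (frac[2] + frac[3])
    return StressOutput(time_ms=t_ms, fractions=frac, stress=stress, scale=scale,
                        metadata={"rates": rates.model_dump()})


def coupled_simulation(config: CellConfig,
                       protocol: StimulusProtocol,
                       duration_ms: float,
                       oxy: float = 0.0,
                       rates: CrossBridgeRates | None = None,
                       scale: float = 1.0,
                       **sim_kwargs) -> tuple[SimulationResult, StressOutput]:
    """Run the cell model, then feed its calcium trajectory into the
    cross-bridge model.  Both outputs share the same time grid."""
    result = simulate(config, protocol, duration_ms, oxy=oxy, **sim_kwargs)
    stress = stress_from_calcium(result.ca, result.time_ms, rates=rates, scale=scale)
    return result, stress
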