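"""Stability-based model reduction.

The full cell model is linearized at a steady state; a perturbation delta is
added to one diagonal element of the Jacobian at a time, and the smallest
|delta| that moves every eigenvalue into the left half-plane is recorded.
Variables whose diagonal needs only a small perturbation participate
strongly in the unstable mode, so their currents are the dynamically
important ones.  Currents are ranked by the smallest perturbation over their
gate variables; the top four are retained, plus the current of largest
magnitude at the steady state (the non-selective cation current in the
shipped configuration), yielding the reduced five-current model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

from .channels import ChannelSpec
from .errors import ConfigurationError, InputError, IntegrationError
from .myocyte import (CellConfig, CellState, Model, SimplifiedModelSpec,
                      get_model)

__all__ = [
    "StabilityReport",
    "find_steady_state",
    "jacobian",
    "max_real_eig",
    "min_stabilizing_perturbation",
    "rank_and_select",
]

UNSTABILIZABLE = math.inf


def find_steady_state(config: CellConfig, oxy: float = 0.0,
                      guess: Optional[Sequence[float]] = None,
                      tol: float = 1e-12) -> CellState:
    """Root of the autonomous right-hand side with ||rhs|| < 1e-10.

    Uses a nested strategy: gates are eliminated analytically (at steady
    state they sit on their (in)activation curves for the current V and Ca),
    leaving a 2-D root problem in (V, Ca) that seeds a full-dimensional
    polish.
    """
    model = get_model(config, oxy)

    def reduced_residual(z):
        v, ca = z
        y = np.concatenate([[v, max(ca, 1e-9)], model.gate_steady(v, max(ca, 1e-9))])
        dy = model.rhs(0.0, y)
        return [dy[0], dy[1] * 1e3]  # calcium equation rescaled to mV/ms order

    if guess is not None:
        y0 = np.asarray(guess, dtype=float)
        v_tries = (float(y0[0]),)
        ca0 = float(y0[1])
    else:
        v_tries = (config.membrane.v_init, -45.0, -30.0, -20.0, -55.0)
        ca0 = config.calcium.rest_uM

    best = None
    for v_try in v_tries:
        sol2 = root(reduced_residual, [v_try, ca0], method="hybr", tol=1e-13)
        y = np.concatenate([[sol2.x[0], max(sol2.x[1], 1e-9)],
                            model.gate_steady(sol2.x[0], max(sol2.x[1], 1e-9))])
        res = np.max(np.abs(model.rhs(0.0, y)))
        if best is None or res < best[0]:
            best = (res, y)
        if guess is None and res < 1e-11:
            break
    y = best[1]

    solf = root(lambda s: model.rhs(0.0, s), y, method="hybr", tol=tol)
    if solf.success and np.max(np.abs(model.rhs(0.0, solf.x))) <= np.max(np.abs(model.rhs(0.0, y))):
        y = solf.x
    resid = np.max(np.abs(model.rhs(0.0, y)))
    if resid > 1e-10:
        raise IntegrationError(
            f"steady-state search did not converge: max|rhs| = {resid:.3e}")
    return CellState.from_vector(config, y)


def jacobian(config: CellConfig, state: CellState | Sequence[float],
             oxy: float = 0.0, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the autonomous RHS at ``state``.

    Steps adapt to each variable's magnitude (with a per-variable floor so
    near-zero gates still get a sensible step).
    """
    model = get_model(config, oxy)
    y = (state.to_vector(config) if isinstance(state, CellState)
         else np.asarray(state, dtype=float))
    n = len(y)
    typical = np.ones(n)
    typical[0] = 50.0          # mV scale
    typical[1] = max(abs(y[1]), 0.01)
    jac = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), typical[j])
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        jac[:, j] = (model.rhs(0.0, yp) - model.rhs(0.0, ym)) / (2.0 * h)
    return jac


def max_real_eig(mat: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(mat).real))


def _scan_stable(jac: np.ndarray, index: int, deltas: np.ndarray) -> np.ndarray:
    """Vectorized stability test of jac + delta e_i e_i^T over many deltas."""
    stack = np.broadcast_to(jac, (len(deltas), *jac.shape)).copy()
    stack[:, index, index] += deltas
    eigs = np.linalg.eigvals(stack)
    return np.max(eigs.real, axis=1) < 0.0


def min_stabilizing_perturbation(jac: np.ndarray, index: int,
                                 bound: float = 1e3,
                                 rtol: float = 1e-6,
                                 coarse_step: float = 2e-3) -> float:
    """Smallest |delta| such that adding delta to diagonal element ``index``
    makes every eigenvalue's real part negative.

    Both signs of delta are searched; returns 0.0 for an already-stable
    matrix and ``math.inf`` if no |delta| <= ``bound`` stabilizes.  The scan
    uses a fine linear grid near zero, a geometric tail out to the bound,
    and bisection refinement on the first stable bracket.
    """
    jac = np.asarray(jac, dtype=float)
    if jac.ndim != 2 or jac.shape[0] != jac.shape[1]:
        raise InputError("jacobian must be square")
    if max_real_eig(jac) < 0.0:
        return 0.0

    lin_max = min(20.0, bound)
    mags = np.arange(coarse_step, lin_max + coarse_step / 2, coarse_step)
    if bound > lin_max:
        tail = np.geomspace(lin_max, bound, 400)[1:]
        mags = np.concatenate([mags, tail])

    best = UNSTABILIZABLE
    for sign in (1.0, -1.0):
        deltas = sign * mags
        stable = np.empty(len(deltas), dtype=bool)
        chunk = 4096
        first = -1
        for k0 in range(0, len(deltas), chunk):
            sl = slice(k0, k0 + chunk)
            stable[sl] = _scan_stable(jac, index, deltas[sl])
            hit = np.flatnonzero(stable[sl])
            if hit.size:
                first = k0 + hit[0]
                break
        if first < 0:
            continue
        lo = mags[first - 1] if first > 0 else 0.0
        hi = mags[first]
        while hi - lo > rtol * max(hi, 1.0):
            mid = 0.5 * (lo + hi)
            if _scan_stable(jac, index, np.array([sign * mid]))[0]:
                hi = mid
            else:
                lo = mid
        best = min(best, hi)
    return best


@dataclass
class StabilityReport:
    """Outcome of the diagonal-perturbation sensitivity analysis."""

    state_names: list[str]
    steady_state: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    perturbations: dict[str, float]        # per state variable
    current_scores: dict[str, float]       # per current (min over its gates)
    current_magnitudes: dict[str, float]   # |I| at the steady state
    ranking: list[str]                     # state variables, most sensitive first
    selected: list[str]                    # retained currents
    spec: Optional[SimplifiedModelSpec]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "state_names": self.state_names,
            "steady_state": [float(x) for x in self.steady_state],
            "eigenvalues": [[float(z.real), float(z.imag)]
                            for z in self.eigenvalues],
            "perturbations": {k: (None if math.isinf(p) else float(p))
                              for k, p in self.perturbations.items()},
            "current_scores": {k: (None if math.isinf(p) else float(p))
                               for k, p in self.current_scores.items()},
            "current_magnitudes": {k: float(v)
                                   for k, v in self.current_magnitudes.items()},
            "variable_ranking": self.ranking,
            "selected_currents": self.selected,
            "n_selected_state_vars": (self.spec.n_state_vars if self.spec else None),
            "warnings": self.warnings,
        }


def rank_and_select(config: CellConfig,
                    oxy: float = 0.0,
                    candidates: Optional[Sequence[str]] = None,
                    n_rank: int = 4,
                    bound: float = 1e3,
                    simplified_template: Optional[CellConfig] = None) -> StabilityReport:
    """Full sensitivity analysis: steady state, Jacobian, per-variable
    stabilizing perturbations, current ranking and reduced-model selection.

    Currents are scored by the smallest stabilizing perturbation over their
    gate variables (ascending; ties broken by current magnitude at the
    steady state).  The ``n_rank`` best are retained together with the
    largest-magnitude current among the remaining candidates.  If a
    ``simplified_template`` configuration is given and the selection matches
    its channels, the emitted reduced-model spec takes its (re-calibrated)
    parameters; otherwise parameters are inherited from ``config``.
    """
    model = get_model(config, oxy)
    names = model.state_names
    candidates = list(candidates) if candidates is not None else [
        c.name for c in config.channels]

    # The analysis is anchored at an unstable steady state when one exists
    # (a spontaneously active cell); enumerate roots from a spread of
    # voltage guesses and prefer the unstable one.
    roots: list[tuple[CellState, np.ndarray, np.ndarray]] = []
    for v_try in (-50.0, -44.0, -38.0, -32.0, -25.0, -18.0):
        try:
            guess = np.concatenate([[v_try, config.calcium.rest_uM],
                                    model.gate_steady(v_try, config.calcium.rest_uM)])
            cand = find_steady_state(config, oxy, guess=guess)
        except (IntegrationError, Exception):
            continue
        if any(abs(cand.v - r[0].v) < 0.05 for r in roots):
            continue
        jc = jacobian(config, cand, oxy)
        roots.append((cand, jc, np.linalg.eigvals(jc)))
    if not roots:
        raise IntegrationError("no steady state found for stability analysis")
    unstable = [r for r in roots if np.max(r[2].real) > 1e-6]
    ss, jac, eigs = max(unstable, key=lambda r: np.max(r[2].real)) if unstable else roots[0]
    y = ss.to_vector(config)

    perts = {nm: min_stabilizing_perturbation(jac, i, bound=bound)
             for i, nm in enumerate(names)}
    order = sorted(names, key=lambda nm: (perts[nm], nm))
    mags = {k: abs(v) for k, v in model.currents(y).items()}

    gate_owner = {g.name: c.name for c in config.channels for g in c.state_gates()}
    scores: dict[str, float] = {}
    for cname in candidates:
        gvars = [g for g, owner in gate_owner.items() if owner == cname]
        scores[cname] = min((perts[g] for g in gvars), default=UNSTABILIZABLE)

    warns: list[str] = []
    gated = [c for c in candidates if math.isfinite(scores[c])]
    gated.sort(key=lambda c: (scores[c], -mags[c]))
    top = gated[:n_rank]
    if len(gated) < n_rank:
        warns.append(f"only {len(gated)} currents have finite stabilizing "
                     f"perturbations (requested {n_rank})")
    remaining = [c for c in candidates if c not in top]
    if remaining:
        top.append(max(remaining, key=lambda c: mags[c]))
    else:
        warns.append("no remaining candidate for the magnitude-based slot; "
                     "emitting a reduced model without it")
    selected = top

    template = simplified_template
    spec = None
    try:
        if template is not None and {c.name for c in template.channels} == set(selected):
            spec = SimplifiedModelSpec(
                channels=[template.channel(n) for n in selected],
                cm=template.membrane.cm, vb=template.membrane.vb,
                calcium=template.calcium, oxytocin=template.oxytocin,
                warnings_=warns)
        else:
            spec = SimplifiedModelSpec(
                channels=[config.channel(n) for n in selected],
                cm=config.membrane.cm, vb=config.membrane.vb,
                calcium=config.calcium, oxytocin=config.oxytocin,
                warnings_=warns)
    except (ValueError, ConfigurationError) as exc:  # degenerate selections
        warns.append(f"could not emit reduced-model spec: {exc}")
    for w in warns:
        warnings.warn(w, stacklevel=2)

    return StabilityReport(
        state_names=names, steady_state=y, jacobian=jac, eigenvalues=eigs,
        perturbations=perts, current_scores=scores, current_magnitudes=mags,
        ranking=order, selected=selected, spec=spec, warnings=warns)
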