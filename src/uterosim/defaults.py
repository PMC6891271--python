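"""Shipped default parameterizations and named stimulus presets.

The sodium and potassium (K1) steady-state gate parameters are the
Boltzmann constants fitted to human-myometrium voltage-clamp recordings:

    m: V_half = -20.3 mV, slope = 6.2 (activation, cubed)
    h: V_half = -46.2 mV, slope = 7.2 (inactivation)
    n: V_half = -13 mV,   slope = 13  (activation, fourth power)
    q: V_half = -38 mV,   slope = 6   (inactivation)

Everything else -- gate time constants, the calcium-channel kinetics, and
every current for which no closed form is fitted here (K2, transient K,
K(Ca), Cl(Ca), hyperpolarization-activated, background, pump, exchanger,
non-selective cation) -- is a config-parameterized stand-in patterned after
published uterine smooth-muscle models.  The defaults were calibrated so
that the cell reproduces the single-spike, plateau and bursting
action-potential morphologies, the reported oxytocin responses, and the
stability structure used by the model reduction:

* ``default_full_config`` is the *base* cell: a spontaneously active
  parameterization whose depolarized steady state is unstable -- the
  starting point of the diagonal-perturbation sensitivity analysis.
* The AP-type presets (``spike``, ``plateau``, ``short-burst``,
  ``long-burst``) are stimulus-response parameterizations with a stable
  resting state near -45 mV; they differ in the slow-inactivation and
  calcium-handling time constants, the way pacemaking heterogeneity
  differs between cells.
* ``default_simplified_config`` is the reduced five-current model
  (13 state variables) with the background offset V_b calibrated so the
  equilibrated output potential V_ap rests at -44.9 mV.

All values can be overridden from a YAML/JSON configuration file.
"""

from __future__ import annotations

import copy
from typing import Any

from .myocyte import CellConfig, SimplifiedModelSpec, StimulusProtocol

__all__ = [
    "default_full_config",
    "default_simplified_config",
    "default_simplified_spec",
    "preset",
    "PRESET_NAMES",
    "build_config",
    "CLAMP_REFERENCE_CHANNELS",
]


def _gate(name, kind, v_half, slope, exponent=1, tau=1.0, **kw):
    return dict(name=name, kind=kind, v_half=v_half, slope=slope,
                exponent=exponent, tau=tau, **kw)


def _ca_gate(name, kind, ca_half, hill, tau):
    return dict(name=name, kind=kind, driver="ca", ca_half=ca_half,
                hill=hill, tau=tau)


def _cal(gbar, d_vh=-26.0, d_sl=6.5, d_tau=10.0, fca=(0.45, 4.0, 2700.0),
         f_vh=-35.0, f_sl=6.5, tf1=500.0, tf2=3000.0):
    return dict(
        name="cal", gbar=gbar, e_rev=45.0, oxy_sensitive=True,
        gates=[_gate("d", "activation", d_vh, d_sl, exponent=2, tau=d_tau),
               _ca_gate("fca", "inactivation", *fca)],
        weighted=dict(weights=[0.8, 0.2],
                      gates=[_gate("f1", "inactivation", f_vh, f_sl, tau=tf1),
                             _gate("f2", "inactivation", f_vh, f_sl, tau=tf2)]),
    )


def _cat(gbar, b=(-45.0, 7.0, 3.0), g=(-66.0, 5.5, 600.0)):
    return dict(
        name="cat", gbar=gbar, e_rev=42.0, oxy_sensitive=True,
        gates=[_gate("b", "activation", b[0], b[1], exponent=2, tau=b[2]),
               _gate("g", "inactivation", g[0], g[1], tau=g[2])],
    )


def _k1(gbar, tn, tq=6000.0):
    return dict(
        name="k1", gbar=gbar, e_rev=-80.0,
        gates=[_gate("n", "activation", -13.0, 13.0, exponent=4, tau=tn),
               _gate("q", "inactivation", -38.0, 6.0, tau=tq)],
    )


def _k2(gbar, p=(-35.0, 10.0, 30.0), inact=(-40.0, 9.0, 4000.0, 12000.0),
        weights=(0.75, 0.25), floor=False):
    """K2 stand-in: p^2 activation with two-component slow inactivation.

    With ``floor=True`` the second component is a small non-inactivating
    fraction (its gate stays open at all potentials), which removes the
    depolarized stuck state in the plateau parameterizations.
    """
    if floor:
        gates = [_gate("k1", "inactivation", inact[0], inact[1], tau=inact[2]),
                 _gate("k2", "inactivation", 120.0, 10.0, tau=inact[3])]
    else:
        gates = [_gate("k1", "inactivation", inact[0], inact[1], tau=inact[2]),
                 _gate("k2", "inactivation", inact[0], inact[1], tau=inact[3])]
    return dict(
        name="k2", gbar=gbar, e_rev=-80.0,
        gates=[_gate("p", "activation", p[0], p[1], exponent=2, tau=p[2])],
        weighted=dict(weights=list(weights), gates=gates),
    )


def _nscc(gbar, ca_gain=(0.25, 1.0, 0.6)):
    return dict(name="nscc", gbar=gbar, e_rev=-11.8,
                ca_gain=dict(ca_half=ca_gain[0], hill=ca_gain[1],
                             floor=ca_gain[2]))


def _extras(gna=0.10, gka=0.04, gkca=0.05, gclca=0.03, gh=0.008,
            gbg=0.01, apump=0.02, ancx=-0.02):
    """Minor currents of the full model (stand-ins for the source model's
    remaining channels; small conductances)."""
    return [
        dict(name="na", gbar=gna, e_rev=83.0,
             gates=[_gate("m", "activation", -20.3, 6.2, exponent=3, tau=0.45),
                    _gate("h", "inactivation", -46.2, 7.2, tau=30.0)]),
        dict(name="ka", gbar=gka, e_rev=-80.0,
             gates=[_gate("s", "activation", -28.0, 10.0, tau=15.0),
                    _gate("x", "inactivation", -68.0, 7.0, tau=500.0)]),
        dict(name="kca", gbar=gkca, e_rev=-80.0,
             gates=[_gate("xa", "activation", -20.0, 16.0, tau=60.0),
                    _gate("xab", "inactivation", -40.0, 14.0, tau=1200.0)],
             ca_gain=dict(ca_half=0.9, hill=2.0, floor=0.0)),
        dict(name="clca", gbar=gclca, e_rev=-27.0,
             gates=[_ca_gate("c", "activation", 0.7, 2.0, 150.0)]),
        dict(name="h", gbar=gh, e_rev=-20.0,
             gates=[_gate("y", "inactivation", -105.0, 8.0, tau=1000.0)]),
        dict(name="bg", gbar=gbg, e_rev=-80.0),
        dict(name="pump", form="source", amp=apump, gbar=0.0,
             inst_gates=[_gate("pump_v", "activation", -50.0, 15.0)]),
        dict(name="ncx", form="source", amp=ancx, gbar=0.0,
             ca_gain=dict(ca_half=1.0, hill=1.0, floor=0.0)),
    ]


def _cell(name, variant, channels, alpha, tau_ca, vb=0.0, v_init=-45.0):
    return {
        "name": name, "variant": variant,
        "membrane": dict(cm=1.0, vb=vb, v_init=v_init),
        "calcium": dict(alpha=alpha, tau_ms=tau_ca, rest_uM=0.1),
        "channels": channels,
        "ca_sources": ["cal", "cat"],
    }


# ---------------------------------------------------------------------------
# full model: base (spontaneously active) parameterization
#
# The base cell has an unstable depolarized steady state near -36 mV -- the
# anchor of the sensitivity analysis -- sustained by a slow calcium/NSCC
# feedback loop and a slowly de-inactivating T-type window.

_FULL_BASE = _cell(
    "full-default", "full",
    [
        _cal(0.3134, d_vh=-24.97, d_sl=5.79, d_tau=10.0,
             fca=(0.45, 4.0, 9000.0)),
        _cat(0.0573, b=(-38.01, 6.74, 7.86), g=(-48.39, 5.02, 2431.2)),
        _k1(1.1504, tn=16.78),
        _k2(0.733, p=(-33.80, 12.57, 55.37),
            inact=(-50.0, 7.0, 400.0, 1500.0)),
        _nscc(0.037, ca_gain=(0.3178, 2.93, 0.2325)),
        *_extras(gna=0.06, gka=0.015, gkca=0.012, gbg=0.0041),
    ],
    alpha=0.00015, tau_ca=7066.4,
)

# full-model AP presets (stable rest near -45 mV)

_FULL_SPIKE = _cell(
    "full-spike", "full",
    [
        _cal(1.0693, d_vh=-26.06, d_sl=5.75, d_tau=13.06,
             fca=(2.0, 4.0, 1000.0)),
        _cat(0.1596),
        _k1(1.8023, tn=21.24),
        _k2(0.8816, p=(-31.86, 7.78, 13.39)),
        _nscc(0.026),
        *_extras(),
    ],
    alpha=0.00015, tau_ca=5000.0,
)

_FULL_PLATEAU = _cell(
    "full-plateau", "full",
    [
        _cal(0.45, fca=(2.5, 4.0, 1000.0), f_vh=-42.0, tf1=2600.0, tf2=7800.0),
        _cat(0.08),
        _k1(1.3, tn=15.0),
        _k2(0.55, inact=(-50.0, 7.0, 400.0, 1500.0),
            weights=(0.97, 0.03), floor=True),
        _nscc(0.024),
        *_extras(),
    ],
    alpha=0.00015, tau_ca=5000.0,
)

_FULL_LONG_BURST = _cell(
    "full-long-burst", "full",
    [
        _cal(0.40, fca=(0.45, 4.0, 9000.0)),
        _cat(0.08),
        _k1(2.5, tn=40.0),
        _k2(0.50, inact=(-50.0, 7.0, 400.0, 1500.0)),
        _nscc(0.024),
        *_extras(),
    ],
    alpha=0.00015, tau_ca=5000.0,
)

_FULL_SHORT_BURST = _cell(
    "full-short-burst", "full",
    [
        _cal(0.40, fca=(0.45, 4.0, 6000.0)),
        _cat(0.08),
        _k1(2.5, tn=40.0, tq=3000.0),
        _k2(0.50, inact=(-50.0, 7.0, 400.0, 1500.0)),
        _nscc(0.024),
        *_extras(gkca=0.02, gclca=0.01),
    ],
    alpha=0.00015, tau_ca=5000.0,
)

# ---------------------------------------------------------------------------
# simplified (five-current, 13-variable) model
#
# V_b offsets the reported potential so the equilibrated V_ap rests at
# -44.9 mV.

_SIMPLIFIED_VB = 0.612

_SIMP_SPIKE = _cell(
    "simplified-default", "simplified",
    [
        _cal(0.45),
        _cat(0.08),
        _k1(1.0, tn=8.0),
        _k2(0.29),
        _nscc(0.012),
    ],
    alpha=0.00015, tau_ca=5000.0, vb=_SIMPLIFIED_VB,
)

_SIMP_PLATEAU = _cell(
    "simplified-plateau", "simplified",
    [
        _cal(0.45, fca=(2.5, 4.0, 1000.0), f_vh=-42.0, tf1=1350.0, tf2=4050.0),
        _cat(0.08),
        _k1(1.3, tn=25.0),
        _k2(0.55, inact=(-50.0, 7.0, 400.0, 1500.0),
            weights=(0.97, 0.03), floor=True),
        _nscc(0.012),
    ],
    alpha=0.0004, tau_ca=1500.0, vb=_SIMPLIFIED_VB,
)

_SIMP_LONG_BURST = _cell(
    "simplified-long-burst", "simplified",
    [
        _cal(0.35, fca=(0.45, 4.0, 4000.0)),
        _cat(0.08),
        _k1(2.5, tn=40.0, tq=3000.0),
        _k2(0.50, inact=(-50.0, 7.0, 400.0, 1500.0)),
        _nscc(0.012),
    ],
    alpha=0.00015, tau_ca=5000.0, vb=_SIMPLIFIED_VB,
)

_SIMP_SHORT_BURST = _cell(
    "simplified-short-burst", "simplified",
    [
        _cal(0.35, fca=(0.45, 4.0, 4000.0)),
        _cat(0.08),
        _k1(2.5, tn=40.0, tq=2000.0),
        _k2(0.50, inact=(-50.0, 7.0, 400.0, 1500.0)),
        _nscc(0.012),
    ],
    alpha=0.00015, tau_ca=5000.0, vb=_SIMPLIFIED_VB,
)

# ---------------------------------------------------------------------------
# presets: configuration + stimulus + run length

_PRESETS: dict[str, dict[str, dict[str, Any]]] = {
    "full": {
        "spike": dict(base=_FULL_SPIKE,
                      protocol=dict(onset_ms=500.0, duration_ms=50.0,
                                    amplitude=1.6),
                      duration_ms=5000.0),
        "plateau": dict(base=_FULL_PLATEAU,
                        protocol=dict(onset_ms=500.0, duration_ms=100.0,
                                      amplitude=1.0),
                        duration_ms=20000.0),
        "short-burst": dict(base=_FULL_SHORT_BURST,
                            protocol=dict(onset_ms=500.0, duration_ms=100.0,
                                          amplitude=1.0),
                            duration_ms=15000.0),
        "long-burst": dict(base=_FULL_LONG_BURST,
                           protocol=dict(onset_ms=500.0, duration_ms=200.0,
                                         amplitude=1.0),
                           duration_ms=30000.0),
        "four-spike": dict(base=_FULL_SPIKE,
                           protocol=dict(onset_ms=500.0, duration_ms=50.0,
                                         amplitude=1.6, repeats=4,
                                         interval_ms=8000.0),
                           duration_ms=38000.0),
    },
    "simplified": {
        "spike": dict(base=_SIMP_SPIKE,
                      protocol=dict(onset_ms=500.0, duration_ms=20.0,
                                    amplitude=1.2),
                      duration_ms=4000.0),
        "plateau": dict(base=_SIMP_PLATEAU,
                        protocol=dict(onset_ms=500.0, duration_ms=100.0,
                                      amplitude=1.0),
                        duration_ms=16000.0),
        "short-burst": dict(base=_SIMP_SHORT_BURST,
                            protocol=dict(onset_ms=500.0, duration_ms=100.0,
                                          amplitude=1.0),
                            duration_ms=12000.0),
        "long-burst": dict(base=_SIMP_LONG_BURST,
                           protocol=dict(onset_ms=500.0, duration_ms=100.0,
                                         amplitude=1.0),
                           duration_ms=18000.0),
    },
}

PRESET_NAMES = ("spike", "plateau", "short-burst", "long-burst")

# Channel parameterizations used to generate and fit synthetic clamp
# fixtures (shared Boltzmann constants; transient-focused time constants).
CLAMP_REFERENCE_CHANNELS = {
    "na": dict(name="na", gbar=8.0, e_rev=83.0,
               gates=[_gate("m", "activation", -20.3, 6.2, exponent=3, tau=0.45),
                      _gate("h", "inactivation", -46.2, 7.2, tau=30.0)]),
    "k1": dict(name="k1", gbar=2.0, e_rev=-80.0,
               gates=[_gate("n", "activation", -13.0, 13.0, exponent=4, tau=4.0),
                      _gate("q", "inactivation", -38.0, 6.0, tau=400.0)]),
}


def _deep_merge(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def build_config(base: dict, overrides: dict | None = None,
                 channel_overrides: dict[str, dict] | None = None) -> CellConfig:
    """Construct a :class:`CellConfig` from a parameter dictionary with
    optional deep-merged overrides (``channel_overrides`` keyed by channel
    name)."""
    d = _deep_merge(base, overrides or {})
    if channel_overrides:
        d = copy.deepcopy(d)
        d["channels"] = [
            _deep_merge(ch, channel_overrides.get(ch["name"], {}))
            for ch in d["channels"]
        ]
    return CellConfig.model_validate(d)


def default_full_config() -> CellConfig:
    """The base full cell model (spontaneously active parameterization used
    by the stability analysis)."""
    return build_config(_FULL_BASE)


def default_simplified_config() -> CellConfig:
    """The reduced five-current model (13 state variables)."""
    return build_config(_SIMP_SPIKE)


def default_simplified_spec() -> SimplifiedModelSpec:
    cfg = default_simplified_config()
    return SimplifiedModelSpec(
        channels=cfg.channels, cm=cfg.membrane.cm, vb=cfg.membrane.vb,
        calcium=cfg.calcium, oxytocin=cfg.oxytocin)


def preset(name: str, variant: str = "full") -> tuple[CellConfig, StimulusProtocol, float]:
    """Named AP-type preset: (config, stimulus protocol, run length in ms)."""
    try:
        entry = _PRESETS[variant][name]
    except KeyError:
        raise KeyError(
            f"unknown preset '{variant}/{name}'; variants: {list(_PRESETS)}, "
            f"names: {sorted(set(k for v in _PRESETS.values() for k in v))}")
    cfg = build_config(entry["base"])
    proto = StimulusProtocol.model_validate(entry["protocol"])
    return cfg, proto, float(entry["duration_ms"])
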