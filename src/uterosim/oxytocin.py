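"""Oxytocin concentration-to-conductance amplifier.

Oxytocin stimulation opens voltage-dependent calcium channels; the model
captures this as a sigmoid multiplier on the maximal conductances of the
L- and T-type calcium channels:

    gain(oxy) = a / (1 + exp(-(oxy - c))) + 1,

with fitted amplitude a = 0.37 and centre c = 0.946 (oxy in uU/mL).  The
gain lies strictly between 1 and 1 + a and increases monotonically with
concentration, so applying oxytocin never decreases a calcium conductance.
The resting-potential mechanism is untouched; any resting shift is an
emergent property of the cell model.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, Field

from .errors import InputError

__all__ = ["OxytocinSetting", "oxy_gain", "scale_calcium_conductances"]


class OxytocinSetting(BaseModel):
    """Oxytocin concentration plus the (config-overridable) sigmoid shape."""

    model_config = ConfigDict(extra="forbid")

    oxy: float = 0.0          # uU/mL
    a: float = Field(0.37, gt=0.0)
    c: float = 0.946


def oxy_gain(setting: OxytocinSetting | float, *, a: float = 0.37, c: float = 0.946) -> float:
    """Conductance multiplier for a given oxytocin concentration.

    Accepts either an :class:`OxytocinSetting` or a bare concentration (with
    optional ``a``/``c`` keywords).  Raises :class:`InputError` for negative
    concentrations.
    """
    if isinstance(setting, OxytocinSetting):
        oxy, a, c = setting.oxy, setting.a, setting.c
    else:
        oxy = float(setting)
    if oxy < 0:
        raise InputError(f"oxytocin concentration must be >= 0, got {oxy}")
    return a / (1.0 + math.exp(-(oxy - c))) + 1.0


def scale_calcium_conductances(gain: float, g_cal: float, g_cat: float) -> tuple[float, float]:
    """Apply the amplifier to the two calcium conductances element-wise."""
    if gain < 1.0:
        raise InputError(f"gain must be >= 1, got {gain}")
    return gain * g_cal, gain * g_cat
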