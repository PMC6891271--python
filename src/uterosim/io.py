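"""Configuration and result file handling.

Configs are YAML (JSON accepted -- it is a YAML subset); time is in ms,
potentials in mV, calcium in uM.  Unknown keys are rejected with the
offending path.  Trace CSVs use comma separation, '.' decimals and a
mandatory header row; every result file embeds the config hash and tool
version in ``#``-prefixed header comments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from pydantic import ValidationError

from ._version import __version__
from .clamp import ClampExperiment, ClampProtocol
from .errors import InputError
from .myocyte import CellConfig, SimulationResult

__all__ = [
    "read_config",
    "write_config",
    "write_result",
    "read_trace_csv",
    "read_clamp_csv",
    "write_clamp_csv",
    "write_json",
]

PathLike = Union[str, Path]


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def read_config(path: PathLike) -> CellConfig:
    """Load and validate a cell configuration from YAML or JSON.

    Schema violations raise :class:`InputError` listing every failing key
    path (e.g. ``channels.0.gbar``).
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InputError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a mapping")
    try:
        return CellConfig.model_validate(data)
    except ValidationError as exc:
        raise InputError(f"{path}: {_format_validation_error(exc)}") from exc


def write_config(config: CellConfig, path: PathLike) -> None:
    header = ("# uterosim cell configuration\n"
              "# units: time ms, potential mV, calcium uM\n")
    Path(path).write_text(header + yaml.safe_dump(config.model_dump(),
                                                  sort_keys=False))


def _metadata_header(meta: dict) -> str:
    lines = [f"# uterosim {__version__}"]
    for key in ("config", "variant", "config_hash", "oxy", "seed"):
        if key in meta:
            lines.append(f"# {key}={meta[key]}")
    return "\n".join(lines) + "\n"


def write_result(result: SimulationResult, path: PathLike) -> None:
    """Write a simulation trace as CSV with metadata header comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_metadata_header(result.metadata))
        result.to_frame().to_csv(fh, index=False)


def read_trace_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_clamp_csv(experiment: ClampExperiment, path: PathLike) -> None:
    data = {"time_ms": experiment.time_ms}
    for v, tr in zip(experiment.protocol.steps_mV, experiment.traces):
        data[f"step_{v:g}mV"] = tr
    with Path(path).open("w") as fh:
        fh.write(_metadata_header(experiment.metadata))
        fh.write(f"# protocol={json.dumps(experiment.protocol.model_dump())}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_clamp_csv(path: PathLike,
                   protocol: ClampProtocol | None = None) -> ClampExperiment:
    """Read externally supplied clamp traces (time_ms plus one current
    column per step).  Step potentials are parsed from column names of the
    form ``step_<V>mV`` unless a protocol is given."""
    df = read_trace_csv(path)
    if "time_ms" not in df.columns:
        raise InputError(f"{path}: missing 'time_ms' column")
    step_cols = [c for c in df.columns if c != "time_ms"]
    if not step_cols:
        raise InputError(f"{path}: no current columns found")
    time = df["time_ms"].to_numpy()
    if protocol is None:
        steps = []
        for c in step_cols:
            try:
                steps.append(float(c.removeprefix("step_").removesuffix("mV")))
            except ValueError:
                raise InputError(f"{path}: cannot parse step potential from "
                                 f"column '{c}'") from None
        dt = float(time[1] - time[0]) if len(time) > 1 else 1.0
        protocol = ClampProtocol(steps_mV=steps, dt_ms=dt,
                                 duration_ms=float(time[-1] - time[0]) or dt)
    traces = df[step_cols].to_numpy().T
    return ClampExperiment(protocol=protocol, time_ms=time, traces=traces,
                           metadata={"source": str(path)})


def write_json(obj: dict, path: PathLike, meta: dict | None = None) -> None:
    payload = dict(obj)
    payload.setdefault("_meta", {"tool": f"uterosim {__version__}",
                                 **(meta or {})})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
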