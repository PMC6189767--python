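"""Plain-text trace files: CSV channels plus a JSON metadata sidecar.

The format is deliberately instrument-agnostic (the recordings this
package emulates were never deposited in a vendor format): a comma-
delimited table with header ``time_ms,current_nA,command_mV``, period
decimal separator, no quoting, and a ``<stem>.meta.json`` sidecar holding
units, dt, seed, preset, stage timeline and ground-truth annotations for
synthetic traces. The format is versioned for future dialects.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import CurrentTrace

FORMAT_VERSION = 1
EXPECTED_COLUMNS = ("time_ms", "current_nA", "command_mV")
EXPECTED_UNITS = {"time": "ms", "current": "nA", "command": "mV"}


class TraceFormatError(ValueError):
    """Base class for trace-file format problems."""


class MalformedTraceError(TraceFormatError):
    """Missing/empty file, bad table shape, or non-numeric content."""


class UnitMismatchError(TraceFormatError):
    """Header or sidecar declares units other than ms / nA / mV."""


class NonUniformSamplingError(TraceFormatError):
    """Time stamps are not an increasing uniform grid (1 ppm tolerance)."""


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace and its sidecar; returns the sidecar path.

    Values are written with 17 significant digits, so float64 samples
    round-trip exactly.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": trace.times_ms,
            "current_nA": trace.current_na,
            "command_mV": trace.command_mv,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "units": dict(EXPECTED_UNITS),
        "dt_ms": trace.dt_ms,
        "n_samples": trace.n_samples,
        "metadata": _jsonable(trace.metadata),
        "annotations": _jsonable(trace.annotations),
    }
    sp = sidecar_path(path)
    sp.write_text(json.dumps(meta, indent=1))
    return sp


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace file, validating header, units and sampling grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as err:
        raise MalformedTraceError(f"{path}: {err}") from err
    cols = tuple(df.columns)
    if cols != EXPECTED_COLUMNS:
        stripped = tuple(c.split("_")[0] for c in cols)
        if stripped == tuple(c.split("_")[0] for c in EXPECTED_COLUMNS):
            raise UnitMismatchError(
                f"{path}: header {cols} does not carry the expected units "
                f"{EXPECTED_COLUMNS}"
            )
        raise MalformedTraceError(
            f"{path}: expected header {EXPECTED_COLUMNS}, found {cols}"
        )
    if len(df) < 2:
        raise MalformedTraceError(f"{path}: fewer than two samples")
    if not all(np.issubdtype(df[c].dtype, np.number) for c in df.columns):
        raise MalformedTraceError(f"{path}: non-numeric content")

    t = df["time_ms"].to_numpy(dtype=float)
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise MalformedTraceError(f"{path}: time stamps not strictly increasing")
    dt = float(np.mean(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * dt:
        raise NonUniformSamplingError(
            f"{path}: sampling interval varies by more than 1 ppm"
        )

    annotations: list[dict[str, Any]] = []
    metadata: dict[str, Any] = {"units": dict(EXPECTED_UNITS)}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
        units = meta.get("units", {})
        if units != EXPECTED_UNITS:
            raise UnitMismatchError(
                f"{sp}: sidecar units {units} differ from {EXPECTED_UNITS}"
            )
        annotations = list(meta.get("annotations", []))
        metadata.update(meta.get("metadata", {}))
        metadata["format_version"] = meta.get("format_version", FORMAT_VERSION)

    return CurrentTrace(
        dt_ms=dt,
        current_na=df["current_nA"].to_numpy(dtype=float),
        command_mv=df["command_mV"].to_numpy(dtype=float),
        annotations=annotations,
        metadata=metadata,
    )
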