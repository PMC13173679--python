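"""Deterministic report serialization (JSON and long-format CSV)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .dynamics import SweepResult
from .sensitivity import PRCCResult

SIG_DIGITS = 12


def _round_float(x: float) -> float:
    if not np.isfinite(x):
        return x
    return float(f"{x:.{SIG_DIGITS}g}")


def to_jsonable(obj):
    """Recursively convert result objects to JSON-ready primitives.

    Dataclass field order is preserved (deterministic ordering); all
    floating values are rounded to 12 significant digits, which makes
    serialize -> parse -> serialize byte-identical.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return {
            "index": list(map(str, obj.index)),
            "columns": list(map(str, obj.columns)),
            "values": to_jsonable(obj.to_numpy()),
        }
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating, complex, np.complexfloating)):
        if isinstance(obj, (complex, np.complexfloating)):
            return {"re": _round_float(obj.real), "im": _round_float(obj.imag)}
        return _round_float(float(obj))
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def dumps(result) -> str:
    return json.dumps(to_jsonable(result), indent=2, allow_nan=True) + "\n"


def sweep_to_frame(result: SweepResult) -> pd.DataFrame:
    """Long-format sweep table: param_value, variable, stat, value."""
    rows = []
    for mu, summary, stats in zip(result.grid, result.summaries, result.extrema):
        if summary is None:
            continue
        for var in ("p", "h", "n"):
            mn, mx, mean = stats[var]
            rows.append((float(mu), var, "min", _round_float(mn)))
            rows.append((float(mu), var, "max", _round_float(mx)))
            rows.append((float(mu), var, "mean", _round_float(mean)))
        rows.append((float(mu), "all", "kind", summary.kind))
    return pd.DataFrame(rows, columns=["param_value", "variable", "stat", "value"])


def prcc_to_frame(result: PRCCResult) -> pd.DataFrame:
    """Long-format PRCC table: parameter, output, prcc."""
    rows = [
        (param, out, _round_float(result.coefficients.loc[param, out]))
        for param in result.parameters
        for out in result.outputs
    ]
    return pd.DataFrame(rows, columns=["parameter", "output", "prcc"])


def emit_report(result, fmt: str, path) -> None:
    """Write a result as ``fmt`` ('json' or 'csv') to ``path``."""
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(dumps(result))
        return
    if fmt == "csv":
        if isinstance(result, SweepResult):
            frame = sweep_to_frame(result)
        elif isinstance(result, PRCCResult):
            frame = prcc_to_frame(result)
        elif isinstance(result, pd.DataFrame):
            frame = result
        else:
            raise ValueError(f"no CSV layout defined for {type(result).__name__}")
        frame.to_csv(path, index=False)
        return
    raise ValueError(f"unknown report format {fmt!r}")
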