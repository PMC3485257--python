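"""CSV/JSON readers and writers for input functions, TACs and fit results.

CSV dialect: optional `#`-prefixed metadata header lines of the form
``# key = value``, then a plain header + data section.  Input functions use
columns ``time_s,activity``; TACs use ``frame_start_s,frame_duration_s,
activity``.  Writers emit full-precision floats so write∘read is the
identity on values.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import FrameSchedule, InputFunction, TimeActivityCurve

__all__ = [
    "read_input_function", "write_input_function",
    "read_tac", "write_tac",
    "read_json", "write_json",
]

_IF_COLUMNS = ["time_s", "activity"]
_TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "activity"]


def _meta_lines(meta: dict) -> list[str]:
    return [f"# {k} = {json.dumps(v)}" for k, v in meta.items()]


def _parse(path) -> tuple[dict, pd.DataFrame]:
    text = Path(path).read_text()
    meta: dict = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, raw = stripped.partition("=")
                try:
                    meta[key.strip()] = json.loads(raw.strip())
                except json.JSONDecodeError:
                    meta[key.strip()] = raw.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"{path}: empty file (no header or data rows)")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body)),
                         float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV body: {exc}") from exc
    return meta, df


def _require_columns(path, df: pd.DataFrame, expected: list[str]) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: malformed header: expected columns {expected}, "
            f"got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")


def write_input_function(input_fn: InputFunction, path) -> None:
    lines = ["# fdgkin input_function v1",
             "# units = time_s:s, activity:arbitrary/mL"]
    lines += _meta_lines(input_fn.meta)
    lines.append(",".join(_IF_COLUMNS))
    for t, a in zip(input_fn.time, input_fn.activity):
        lines.append(f"{float(t)!r},{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_input_function(path) -> InputFunction:
    meta, df = _parse(path)
    _require_columns(path, df, _IF_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0.0):
        raise ValueError(f"{path}: non-monotone time grid")
    try:
        return InputFunction(time=t, activity=df["activity"].to_numpy(dtype=float),
                             meta=meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_tac(tac: TimeActivityCurve, path) -> None:
    lines = ["# fdgkin tac v1",
             "# units = frame_start_s:s, frame_duration_s:s, activity:arbitrary/mL"]
    lines += _meta_lines(tac.meta)
    lines.append(",".join(_TAC_COLUMNS))
    for s, d, a in zip(tac.schedule.start, tac.schedule.duration, tac.activity):
        lines.append(f"{float(s)!r},{float(d)!r},{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tac(path) -> TimeActivityCurve:
    meta, df = _parse(path)
    _require_columns(path, df, _TAC_COLUMNS)
    start = df["frame_start_s"].to_numpy(dtype=float)
    dur = df["frame_duration_s"].to_numpy(dtype=float)
    if np.any(dur <= 0.0):
        raise ValueError(f"{path}: negative or zero frame duration")
    gaps = start[1:] - (start[:-1] + dur[:-1])
    if np.any(gaps < -1e-9):
        raise ValueError(f"{path}: overlapping frames")
    if np.any(gaps > 1e-9):
        raise ValueError(f"{path}: gap between frames")
    try:
        schedule = FrameSchedule(start=start, duration=dur)
        return TimeActivityCurve(schedule=schedule,
                                 activity=df["activity"].to_numpy(dtype=float),
                                 meta=meta)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: unreadable JSON: {exc}") from exc
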