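"""Readers/writers for the interchange formats.

Traces and cohorts travel as RFC-4180 CSV, bout/event interval tables as
TSV with half-open ``[onset_s, offset_s)`` intervals, ground-truth
annotations as JSON.  Every table written by the pipeline carries the run
configuration hash in a ``#`` comment header so outputs are traceable to
their parameters.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import Bout, ScratchEvent
from .simulate import GroundTruth, SignalTrace

__all__ = [
    "SchemaError",
    "write_trace_csv",
    "read_trace_csv",
    "write_truth_json",
    "read_truth_json",
    "write_table",
    "read_table",
    "bouts_to_frame",
    "events_to_frame",
]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def _header(config_hash: str | None) -> str:
    return f"# scratchkit config={config_hash}\n" if config_hash else ""


def write_trace_csv(trace: SignalTrace, path, config_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        fh.write("time_s,signal\n")
        t = trace.times
        np.savetxt(fh, np.column_stack([t, trace.signal]), fmt="%.6f,%.8g", delimiter="")


def read_trace_csv(path) -> SignalTrace:
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as e:
        raise SchemaError(f"unparsable trace file: {e}") from e
    if list(df.columns) != ["time_s", "signal"]:
        raise SchemaError(f"trace must have columns time_s,signal; got {list(df.columns)}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise SchemaError("trace too short")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
        raise SchemaError("bad trace: time_s must increase uniformly")
    return SignalTrace(signal=df["signal"].to_numpy(float), sampling_rate=1.0 / dt[0])


def write_truth_json(truth: GroundTruth, path, config_hash: str | None = None) -> None:
    doc = truth.to_dict()
    if config_hash:
        doc["config"] = config_hash
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth_json(path) -> GroundTruth:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"unparsable truth file: {e}") from e
    if "events" not in doc:
        raise SchemaError("truth file lacks 'events'")
    return GroundTruth.from_dict(doc)


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [b.start_s for b in bouts],
            "offset_s": [b.end_s for b in bouts],
            "n_beats": [b.n_beats for b in bouts],
            "mean_freq_hz": [b.mean_freq_hz for b in bouts],
            "interval_cv": [b.interval_cv for b in bouts],
        }
    )


def events_to_frame(events: list[ScratchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
            "n_bouts": [e.n_bouts for e in events],
        }
    )


def write_table(df: pd.DataFrame, path, config_hash: str | None = None, sep: str = ",") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = ",", required: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as e:
        raise SchemaError(f"unparsable table: {e}") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table lacks required columns {missing}")
    return df
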