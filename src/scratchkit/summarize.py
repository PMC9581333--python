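"""Session metrics: scratch time, bout/event counts and 5-min time-courses."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Bout, ScratchEvent

__all__ = ["ScratchSummary", "summarize", "summaries_to_frame", "correlate_metrics"]

METRICS = ("scratch_time_s", "n_bouts", "n_events")


@dataclass
class ScratchSummary:
    """Per-animal, per-session totals plus binned bout counts.

    ``scratch_time_s`` is the summed duration of all bouts; a bout counts
    toward the half-open bin [k*bin_s, (k+1)*bin_s) containing its start.
    """

    animal_id: str
    scratch_time_s: float
    n_bouts: int
    n_events: int
    bin_counts: list[int]
    window_s: float = 1800.0


def summarize(
    bouts: list[Bout],
    events: list[ScratchEvent],
    window_s: float = 1800.0,
    bin_s: float = 300.0,
    animal_id: str = "",
) -> ScratchSummary:
    """Reduce a detection (or ground-truth) segmentation to session metrics."""
    n_bins_f = window_s / bin_s
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError("bad binning: window_s must be a multiple of bin_s")
    n_bins = int(round(n_bins_f))
    counts = [0] * n_bins
    time_s = 0.0
    for b in bouts:
        if b.start_s >= window_s or b.start_s < 0:
            raise ValueError("bout outside analysis window; clip first")
        counts[int(b.start_s // bin_s)] += 1
        time_s += b.duration_s
    return ScratchSummary(
        animal_id=animal_id,
        scratch_time_s=time_s,
        n_bouts=len(bouts),
        n_events=len(events),
        bin_counts=counts,
        window_s=window_s,
    )


def summaries_to_frame(summaries: list[ScratchSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "animal_id": s.animal_id,
            "scratch_time_s": s.scratch_time_s,
            "n_bouts": s.n_bouts,
            "n_events": s.n_events,
        }
        row.update({f"bin_{i + 1}": c for i, c in enumerate(s.bin_counts)})
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_metrics(summaries) -> pd.DataFrame:
    """Pearson correlation matrix of scratch time, bouts and events.

    Accepts a list of :class:`ScratchSummary` or a DataFrame carrying the
    three metric columns.  Requires at least three observations and nonzero
    variance in every metric.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries.rename(columns={"bouts": "n_bouts", "events": "n_events"})
    else:
        frame = summaries_to_frame(summaries)
    missing = [m for m in METRICS if m not in frame.columns]
    if missing:
        raise ValueError(f"missing metric columns: {missing}")
    data = frame[list(METRICS)].to_numpy(float)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 summaries")
    if np.any(np.std(data, axis=0) == 0):
        raise ValueError("degenerate metric: zero variance")
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=METRICS, columns=METRICS)
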