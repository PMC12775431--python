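"""Behavioral scores and neural-behavioral couplings.

Covers the conditioned-place-preference (CPP) score, feeding-bout
summaries, and the correlation plumbing that links windowed neural
metrics (e.g. peri-bout AUC) to behavior durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalpopError

__all__ = ["BoutTable", "cpp_score", "correlate_metric", "summarize_bouts"]


@dataclass
class BoutTable:
    """Merged bout intervals for one event label."""

    intervals: pd.DataFrame  # columns start_s, end_s, duration_s
    total_duration: float
    count: int
    label: str = ""


def cpp_score(t_paired: float, t_unpaired: float) -> float:
    """Conditioned place preference score.

    (t_paired - t_unpaired) / (t_paired + t_unpaired): +1 means all time
    in the food-paired context, -1 all time in the unpaired context.
    """
    if t_paired < 0 or t_unpaired < 0:
        raise CalpopError("occupancy times must be non-negative")
    total = t_paired + t_unpaired
    if total <= 0:
        raise CalpopError("cpp_score undefined: total occupancy time is zero")
    return (t_paired - t_unpaired) / total


def correlate_metric(
    x, y, method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlate a per-trial neural metric with a behavior metric.

    Pairs with a missing value in either vector are dropped and the
    effective n reported. Returns ``(r, two-sided p, n)``. No
    multiple-testing correction is applied; that is the caller's call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise CalpopError(f"correlation needs n >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CalpopError("correlation undefined: zero variance in an input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be pearson|spearman, got {method!r}")
    return float(res.statistic), float(res.pvalue), n


def summarize_bouts(events: pd.DataFrame, label: str) -> BoutTable:
    """Durations, count, and total time of the bouts carrying ``label``.

    Bouts need offsets; rows without one are named in the error.
    Overlapping bouts — common in real annotation files — are merged
    (interval union) with a warning rather than rejected.
    """
    sel = events[events["label"] == label]
    if sel.empty:
        return BoutTable(
            intervals=pd.DataFrame(columns=["start_s", "end_s", "duration_s"]),
            total_duration=0.0,
            count=0,
            label=label,
        )
    missing = sel.index[sel["offset_s"].isna()]
    if len(missing):
        raise CalpopError(
            f"bouts with label {label!r} missing offsets in rows {list(missing)}"
        )
    ivs = sorted(zip(sel["onset_s"].to_numpy(), sel["offset_s"].to_numpy()))
    merged = [list(ivs[0])]
    overlapped = False
    for s, e in ivs[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            overlapped = True
        else:
            merged.append([s, e])
    if overlapped:
        warnings.warn(
            f"overlapping {label!r} bouts merged ({len(ivs)} -> {len(merged)})",
            stacklevel=2,
        )
    df = pd.DataFrame(merged, columns=["start_s", "end_s"])
    df["duration_s"] = df["end_s"] - df["start_s"]
    return BoutTable(
        intervals=df,
        total_duration=float(df["duration_s"].sum()),
        count=len(df),
        label=label,
    )
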