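"""Trace normalization and peri-event extraction.

Shared by the single-cell miniscope path (z-scored ΔF/F per neuron) and
the bulk photometry path (ΔF/F of one channel). Conventions fixed here:

* ΔF/F = (F - F0)/F0 with F0 the mean baseline fluorescence; by default
  F0 is the session-wide mean per neuron, optionally a sub-window of the
  session.
* z-scoring is per neuron over the full session using the population
  (divide-by-n) standard deviation.
* Windows are half-open ``[t0, t1)`` in seconds; ``frame = floor(t * rate)``.
* Trials whose epoch would cross a session edge are dropped, never padded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import EpochTensor, TraceMatrix, WindowSpec, time_to_frame
from .errors import (
    DegenerateBaselineError,
    EmptyEpochError,
    WindowError,
)

__all__ = [
    "compute_dff",
    "zscore",
    "extract_epochs",
    "window_stat",
    "onset_latency",
]


def compute_dff(
    raw: TraceMatrix, f0_window: tuple[float, float] | None = None
) -> TraceMatrix:
    """Fractional fluorescence change (F - F0)/F0 per neuron.

    Parameters
    ----------
    raw
        Trace matrix with ``stage='raw'``.
    f0_window
        Optional ``(t0, t1)`` in session seconds over which to average the
        baseline F0. ``None`` uses the whole session (the default for
        whole-session normalization; peri-event figures may prefer a local
        pre-event window).

    Raises
    ------
    DegenerateBaselineError
        If any neuron's F0 is non-positive, naming the neuron.
    """
    if raw.stage != "raw":
        raise ValueError(f"compute_dff expects stage='raw', got {raw.stage!r}")
    if f0_window is None:
        f0 = raw.values.mean(axis=1)
    else:
        t0, t1 = f0_window
        i0 = max(time_to_frame(t0, raw.frame_rate), 0)
        i1 = min(time_to_frame(t1, raw.frame_rate), raw.n_frames)
        if i1 <= i0:
            raise WindowError(f"F0 window [{t0}, {t1}) maps to no frames")
        f0 = raw.values[:, i0:i1].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = [raw.neuron_ids[i] for i in bad[:5]]
        raise DegenerateBaselineError(
            f"non-positive baseline F0 for neuron(s) {names}"
        )
    dff = (raw.values - f0[:, None]) / f0[:, None]
    return TraceMatrix(dff, raw.frame_rate, list(raw.neuron_ids), stage="dff")


def zscore(traces: TraceMatrix) -> TraceMatrix:
    """Per-neuron session z-score: (x - mean)/SD, population SD.

    Neurons with zero session SD carry no signal and cannot be scaled;
    they are excluded from the output with a warning rather than silently
    zeroed, so downstream neuron counts stay honest.
    """
    mean = traces.values.mean(axis=1)
    sd = traces.values.std(axis=1)  # population convention (ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [nid for nid, k in zip(traces.neuron_ids, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-SD neuron(s) from z-scoring: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    if not keep.any():
        raise DegenerateBaselineError("all neurons have zero session SD")
    z = (traces.values[keep] - mean[keep, None]) / sd[keep, None]
    ids = [nid for nid, k in zip(traces.neuron_ids, keep) if k]
    return TraceMatrix(z, traces.frame_rate, ids, stage="zscored")


def extract_epochs(
    traces: TraceMatrix,
    events: pd.DataFrame,
    label: str,
    pre_s: float = 10.0,
    post_s: float = 10.0,
) -> EpochTensor:
    """Slice peri-event epochs around each onset of ``label``.

    Each epoch spans ``[-pre_s, post_s)`` around onset, i.e.
    ``round((pre_s + post_s) * frame_rate)`` frames (600 at 30 FPS with the
    10 s defaults). Trials whose epoch would extend past either session
    edge are excluded and counted in ``n_excluded``.
    """
    if traces.stage == "raw":
        raise ValueError("extract_epochs expects dff or zscored traces, got raw")
    sel = events[events["label"] == label]
    if sel.empty:
        raise EmptyEpochError(f"no events with label {label!r}")
    n_frames = int(round((pre_s + post_s) * traces.frame_rate))
    align = int(round(pre_s * traces.frame_rate))
    slabs, kept_ids = [], []
    n_excluded = 0
    for row_id, onset in zip(sel.index, sel["onset_s"].to_numpy()):
        onset_frame = time_to_frame(onset, traces.frame_rate)
        start = onset_frame - align
        stop = start + n_frames
        if start < 0 or stop > traces.n_frames:
            n_excluded += 1
            continue
        slabs.append(traces.values[:, start:stop])
        kept_ids.append(row_id)
    if not slabs:
        raise EmptyEpochError(
            f"no usable trials for {label!r}: all {n_excluded} excluded at edges"
        )
    values = np.stack(slabs, axis=1)  # neuron x trial x frame
    return EpochTensor(
        values=values,
        pre_s=pre_s,
        post_s=post_s,
        frame_rate=traces.frame_rate,
        neuron_ids=list(traces.neuron_ids),
        trial_event_ids=np.asarray(kept_ids, dtype=int),
        n_excluded=n_excluded,
        label=label,
    )


def window_stat(
    epochs: EpochTensor, window: WindowSpec, stat: str = "mean"
) -> np.ndarray:
    """Per-neuron, per-trial statistic over a peri-event window.

    ``mean`` and ``max`` reduce over the half-open frame range
    ``[t0, t1)``. ``auc`` is the trapezoidal integral of z against time
    (z·s); its frame range additionally includes the sample at ``t1``
    (clipped to the epoch) so a constant ``c`` over a 5 s window
    integrates to exactly ``5c``.
    """
    i0, i1 = epochs.window_frames(window)
    block = epochs.values[:, :, i0:i1]
    if stat == "mean":
        return block.mean(axis=2)
    if stat == "max":
        return block.max(axis=2)
    if stat == "auc":
        j1 = min(i1 + 1, epochs.n_frames)
        block = epochs.values[:, :, i0:j1]
        if block.shape[2] < 2:
            raise WindowError("auc needs at least two samples in the window")
        return np.trapezoid(block, dx=1.0 / epochs.frame_rate, axis=2)
    raise ValueError(f"unknown stat {stat!r}; expected mean|max|auc")


def onset_latency(
    values: np.ndarray,
    frame_rate: float,
    baseline: WindowSpec,
    direction: str = "above",
    origin: float = 0.0,
) -> float | None:
    """Time of the first sample beyond the baseline mean ± 2 SD.

    ``values`` is a single-channel series sampled at ``frame_rate`` whose
    first sample sits at time ``origin`` (use ``origin=-pre_s`` for a
    peri-event trace). The baseline window is taken on that same time
    axis; the scan starts at the baseline's end. Returns the crossing
    time, or ``None`` if the series never crosses.
    """
    values = np.asarray(values, dtype=float).ravel()
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    b0 = time_to_frame(baseline.t0 - origin, frame_rate)
    b1 = time_to_frame(baseline.t1 - origin, frame_rate)
    b0 = max(b0, 0)
    b1 = min(b1, values.size)
    if b1 - b0 < 2:
        raise DegenerateBaselineError("baseline window has fewer than 2 samples")
    base = values[b0:b1]
    mu, sd = base.mean(), base.std()
    if sd <= 0:
        raise DegenerateBaselineError("baseline SD is zero; threshold undefined")
    tail = values[b1:]
    if direction == "above":
        hits = np.flatnonzero(tail > mu + 2 * sd)
    else:
        hits = np.flatnonzero(tail < mu - 2 * sd)
    if hits.size == 0:
        return None
    return origin + (b1 + int(hits[0])) / frame_rate
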