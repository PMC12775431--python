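"""Core in-memory containers shared across the pipeline.

Times are stored in seconds everywhere; frame indices are derived from
seconds via ``frame = floor(t * frame_rate)`` and never stored, so the
30 FPS miniscope, 20 FPS behavior-video, and 100 Hz photometry clocks can
coexist without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import WindowError

#: stages a trace matrix can be in
STAGES = ("raw", "dff", "zscored")

_FLOOR_EPS = 1e-9


def time_to_frame(t: float, frame_rate: float) -> int:
    """Map a time in seconds to a frame index: ``floor(t * frame_rate)``.

    A tiny epsilon guards against float representation error at exact
    frame boundaries (e.g. ``5 * 30`` landing at ``149.9999...``).
    """
    return int(np.floor(t * frame_rate + _FLOOR_EPS))


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window ``[t0, t1)`` in seconds, relative to an origin.

    For peri-event use the origin is the event onset, so baseline windows
    have negative bounds (e.g. ``WindowSpec(-5, 0)``).
    """

    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1):
            raise WindowError(f"window requires t0 < t1, got [{self.t0}, {self.t1})")

    @property
    def length(self) -> float:
        return self.t1 - self.t0

    def overlaps(self, other: "WindowSpec") -> bool:
        return self.t0 < other.t1 and other.t0 < self.t1


@dataclass
class TraceMatrix:
    """Neuron x frame fluorescence matrix with its sampling clock.

    ``stage`` records which normalization has been applied: ``raw``
    fluorescence (a.u.), ``dff`` (dimensionless (F - F0)/F0), or
    ``zscored`` (per-neuron standard-deviation units over the session).
    """

    values: np.ndarray
    frame_rate: float
    neuron_ids: list[str]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D neuron x frame matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.neuron_ids = [str(i) for i in self.neuron_ids]
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.neuron_ids)} neuron ids for {self.values.shape[0]} rows"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def subset(self, neuron_ids: list[str]) -> "TraceMatrix":
        index = {nid: i for i, nid in enumerate(self.neuron_ids)}
        missing = [nid for nid in neuron_ids if nid not in index]
        if missing:
            raise KeyError(f"unknown neuron ids: {missing[:5]}")
        rows = [index[nid] for nid in neuron_ids]
        return TraceMatrix(
            self.values[rows], self.frame_rate, list(neuron_ids), self.stage
        )


@dataclass
class EpochTensor:
    """Neuron x trial x frame peri-event slab.

    ``align_index`` is the frame of event onset within each epoch
    (``round(pre_s * frame_rate)``); frame ``i`` sits at time
    ``(i - align_index) / frame_rate`` relative to onset. Trials whose
    windows would leave the session are excluded, and the exclusion count
    is carried along rather than silently dropped.
    """

    values: np.ndarray
    pre_s: float
    post_s: float
    frame_rate: float
    neuron_ids: list[str]
    trial_event_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_excluded: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("epoch tensor must be neuron x trial x frame")
        expected = int(round((self.pre_s + self.post_s) * self.frame_rate))
        if self.values.shape[2] != expected:
            raise ValueError(
                f"epoch has {self.values.shape[2]} frames, expected {expected}"
            )
        self.trial_event_ids = np.asarray(self.trial_event_ids, dtype=int)

    @property
    def align_index(self) -> int:
        return int(round(self.pre_s * self.frame_rate))

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds relative to event onset."""
        return (np.arange(self.n_frames) - self.align_index) / self.frame_rate

    def window_frames(self, window: WindowSpec) -> tuple[int, int]:
        """Frame index bounds ``[i0, i1)`` of a half-open peri-event window."""
        if window.t0 < -self.pre_s - _FLOOR_EPS or window.t1 > self.post_s + _FLOOR_EPS:
            raise WindowError(
                f"window [{window.t0}, {window.t1}) outside epoch "
                f"[-{self.pre_s}, {self.post_s}]"
            )
        i0 = self.align_index + time_to_frame(window.t0, self.frame_rate)
        i1 = self.align_index + time_to_frame(window.t1, self.frame_rate)
        i0 = max(i0, 0)
        i1 = min(i1, self.n_frames)
        if i1 <= i0:
            raise WindowError(f"window [{window.t0}, {window.t1}) maps to no frames")
        return i0, i1


EVENT_COLUMNS = ("label", "onset_s", "offset_s")


def make_event_table(
    labels, onsets, offsets=None
) -> pd.DataFrame:
    """Build an event table DataFrame (columns label, onset_s, offset_s)."""
    df = pd.DataFrame(
        {
            "label": list(labels),
            "onset_s": np.asarray(onsets, dtype=float),
            "offset_s": (
                np.full(len(list(labels)), np.nan)
                if offsets is None
                else np.asarray(offsets, dtype=float)
            ),
        }
    )
    return validate_event_table(df)


def validate_event_table(df: pd.DataFrame, duration: float | None = None) -> pd.DataFrame:
    """Validate and canonicalize an event table.

    Onsets must be non-negative (and within ``duration`` when given);
    offsets, when present, must not precede their onsets. Rows are sorted
    by onset within each label.
    """
    missing = [c for c in ("label", "onset_s") if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    df = df.copy()
    if "offset_s" not in df.columns:
        df["offset_s"] = np.nan
    df["onset_s"] = df["onset_s"].astype(float)
    df["offset_s"] = df["offset_s"].astype(float)
    if (df["onset_s"] < 0).any():
        raise ValueError("event onsets must be non-negative")
    if duration is not None and (df["onset_s"] >= duration).any():
        raise ValueError("event onset at or beyond session end")
    bad = df["offset_s"].notna() & (df["offset_s"] < df["onset_s"])
    if bad.any():
        raise ValueError(f"offset before onset in rows {list(df.index[bad])}")
    return df.sort_values(["onset_s"], kind="stable").reset_index(drop=True)
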