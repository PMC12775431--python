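"""File formats: trace matrices (CSV/HDF5), event tables (TSV), cell maps.

CSV traces: one row per neuron, first column ``neuron_id``, remaining
column headers the frame times in seconds, preceded by a single comment
line carrying the frame rate and stage. Values are written with Python's
shortest round-tripping float repr, so a CSV round trip is value-exact.
HDF5 traces use datasets ``/traces``, ``/frame_rate``, ``/neuron_ids``
plus a ``stage`` attribute and round-trip bit-exactly.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .containers import TraceMatrix, validate_event_table
from .errors import ParseError

__all__ = [
    "read_traces",
    "write_traces",
    "read_traces_csv",
    "write_traces_csv",
    "read_traces_h5",
    "write_traces_h5",
    "read_events",
    "write_events",
    "read_mapping",
    "write_mapping",
]

_HEADER_PREFIX = "# calpop-traces"


def write_traces_csv(tm: TraceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"{_HEADER_PREFIX} frame_rate={float(tm.frame_rate)!r} stage={tm.stage}\n"
        )
        # shortest-repr floats round-trip exactly through text
        fh.write("neuron_id," + ",".join(repr(float(t)) for t in tm.times) + "\n")
        for nid, row in zip(tm.neuron_ids, tm.values):
            fh.write(nid + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_traces_csv(path) -> TraceMatrix:
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty input file")
    with open(path) as fh:
        first = fh.readline().strip()
    frame_rate = None
    stage = "raw"
    skip = 0
    if first.startswith(_HEADER_PREFIX):
        skip = 1
        for token in first[len(_HEADER_PREFIX):].split():
            key, _, val = token.partition("=")
            if key == "frame_rate":
                frame_rate = float(val)
            elif key == "stage":
                stage = val
    try:
        df = pd.read_csv(path, skiprows=skip, index_col=0)
    except Exception as exc:  # malformed structure
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty:
        raise ParseError(f"{path}: no trace rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy()
        if bad.any():
            row = df.index[int(np.argmax(bad))]
            kind = "NaN" if pd.isna(df[col].to_numpy()[int(np.argmax(bad))]) else "non-numeric"
            raise ParseError(
                f"{path}: {kind} cell at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    if frame_rate is None:
        times = np.array([float(c) for c in df.columns])
        if times.size < 2:
            raise ParseError(f"{path}: cannot infer frame rate from one column")
        frame_rate = (times.size - 1) / (times[-1] - times[0])
    return TraceMatrix(values, frame_rate, [str(i) for i in df.index], stage=stage)


def write_traces_h5(tm: TraceMatrix, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=tm.values)
        fh.create_dataset("frame_rate", data=tm.frame_rate)
        fh.create_dataset(
            "neuron_ids", data=np.array(tm.neuron_ids, dtype="S")
        )
        fh.attrs["stage"] = tm.stage


def read_traces_h5(path) -> TraceMatrix:
    with h5py.File(path, "r") as fh:
        for key in ("traces", "frame_rate", "neuron_ids"):
            if key not in fh:
                raise ParseError(f"{path}: missing dataset /{key}")
        values = fh["traces"][()]
        frame_rate = float(fh["frame_rate"][()])
        ids = [b.decode() for b in fh["neuron_ids"][()]]
        stage = fh.attrs.get("stage", "raw")
    return TraceMatrix(values, frame_rate, ids, stage=str(stage))


def write_traces(tm: TraceMatrix, path) -> None:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        write_traces_h5(tm, path)
    else:
        write_traces_csv(tm, path)


def read_traces(path) -> TraceMatrix:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        return read_traces_h5(path)
    return read_traces_csv(path)


def write_events(events: pd.DataFrame, path) -> None:
    events[["label", "onset_s", "offset_s"]].to_csv(path, sep="\t", index=False)


def read_events(path, duration: float | None = None) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty input file")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    try:
        return validate_event_table(df, duration=duration)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_mapping(mapping: pd.DataFrame, path) -> None:
    mapping[["id_a", "id_b"]].to_csv(path, sep="\t", index=False)


def read_mapping(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in ("id_a", "id_b") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: mapping missing columns {missing}")
    return df
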