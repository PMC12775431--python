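"""Linear population decoding of binary behavioral conditions.

The decoder throughout is a linear maximum-margin classifier (soft-margin
SVM, C = 1.0, class-balanced weighting) on trial features built from a
neuron x trial x frame activity tensor. Features are standardized inside
each training fold only, so no information leaks from held-out trials.

Four decoding modes are provided:

* :func:`decode_cv` — stratified k-fold cross-validated accuracy (10
  folds by default) on trial features (windowed per-neuron means by
  default, or the full N x T flattening).
* :func:`shuffled_null` — the chance benchmark: the label vector is
  permuted and the identical cross-validation repeated, yielding a null
  accuracy distribution and an empirical p-value for the real accuracy.
* :func:`decode_timecourse` — accuracy as a function of time relative to
  onset, each time point using the mean activity in the following 1 s,
  5-fold cross-validated, with a shuffled-label control curve.
* :func:`projection_decoder` — a consecutive 50/50 session split: the
  hyperplane is fit on event vs pre-event-baseline frames of the first
  half, and the second half is projected onto the hyperplane normal to
  give a continuous, thresholdable event prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .containers import EpochTensor, TraceMatrix, WindowSpec, time_to_frame
from .errors import (
    AlignmentError,
    EmptyEpochError,
    LabelError,
    SplitError,
    WindowError,
)

__all__ = [
    "TrialTensor",
    "DecoderOutput",
    "NullResult",
    "TimecourseResult",
    "ProjectionResult",
    "AgreementResult",
    "build_trial_tensor",
    "decode_cv",
    "shuffled_null",
    "performance_cdf",
    "decode_timecourse",
    "projection_decoder",
    "event_agreement",
]

DEFAULT_FEATURE_WINDOW = WindowSpec(0.0, 5.0)


@dataclass
class TrialTensor:
    """N neurons x M trials x T frames activity with binary trial labels."""

    activity: np.ndarray
    labels: np.ndarray  # 1 = event A, 0 = event B
    frame_rate: float
    align_index: int
    neuron_ids: list[str]
    label_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.activity.ndim != 3:
            raise ValueError("activity must be neuron x trial x frame")
        if self.labels.size != self.activity.shape[1]:
            raise LabelError("one label per trial required")
        classes = np.unique(self.labels)
        if classes.size < 2:
            raise LabelError("both label classes must be non-empty")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_trials(self) -> int:
        return self.activity.shape[1]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[2]

    def features(
        self,
        window: WindowSpec | None = DEFAULT_FEATURE_WINDOW,
        flatten: bool = False,
    ) -> np.ndarray:
        """Per-trial feature matrix (M x features).

        Default: per-neuron mean over the window (M x N), robust at small
        trial counts. ``flatten=True`` instead unrolls the full N x T
        frame-wise activity per trial.
        """
        if flatten:
            return self.activity.transpose(1, 0, 2).reshape(self.n_trials, -1)
        if window is None:
            return self.activity.mean(axis=2).T
        i0 = self.align_index + time_to_frame(window.t0, self.frame_rate)
        i1 = self.align_index + time_to_frame(window.t1, self.frame_rate)
        i0, i1 = max(i0, 0), min(i1, self.n_frames)
        if i1 <= i0:
            raise WindowError(f"feature window [{window.t0},{window.t1}) is empty")
        return self.activity[:, :, i0:i1].mean(axis=2).T


@dataclass
class DecoderOutput:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    hyperplane_w: np.ndarray
    hyperplane_b: float
    folds_used: int
    seed: int | None
    null_accuracies: np.ndarray | None = None
    cdf: np.ndarray | None = None  # (accuracy, cumulative probability) pairs


@dataclass
class NullResult:
    null_accuracies: np.ndarray
    real_accuracy: float
    p_value: float


@dataclass
class TimecourseResult:
    times: np.ndarray
    accuracy: np.ndarray
    null_accuracy: np.ndarray  # mean shuffled-label accuracy per time point
    auc_0_10: float  # trapezoidal integral of accuracy over grid ∩ [0, 10] s
    window_len: float
    folds: int


@dataclass
class ProjectionResult:
    times: np.ndarray  # session seconds of each test-half frame
    projection: np.ndarray  # signed distance along the hyperplane normal
    threshold: float
    predicted_intervals: list[tuple[float, float]]
    train_span: tuple[float, float]
    test_span: tuple[float, float]
    hyperplane_w: np.ndarray
    hyperplane_b: float
    train_event_mean: float
    train_baseline_mean: float


@dataclass
class AgreementResult:
    frame_accuracy: float
    hit_rate: float  # fraction of actual intervals overlapped by a prediction
    iou: float  # intersection-over-union of total predicted vs actual time
    n_frames: int


def _make_svm() -> object:
    return make_pipeline(
        StandardScaler(),
        LinearSVC(C=1.0, class_weight="balanced", max_iter=20_000),
    )


def build_trial_tensor(
    epochs_a: EpochTensor,
    epochs_b: EpochTensor,
    neuron_subset: list[str],
) -> TrialTensor:
    """Stack two events' epochs into one labeled trial tensor (A=1, B=0).

    Both epoch tensors must share neuron identities and the frame grid
    (same frame rate, epoch span, and alignment); ``neuron_subset`` is
    typically the union of activated cells in the two events.
    """
    if not neuron_subset:
        raise ValueError("neuron_subset must not be empty")
    if (
        epochs_a.frame_rate != epochs_b.frame_rate
        or epochs_a.n_frames != epochs_b.n_frames
        or epochs_a.align_index != epochs_b.align_index
    ):
        raise AlignmentError("epoch tensors do not share a frame grid")
    index_a = {nid: i for i, nid in enumerate(epochs_a.neuron_ids)}
    index_b = {nid: i for i, nid in enumerate(epochs_b.neuron_ids)}
    missing = [n for n in neuron_subset if n not in index_a or n not in index_b]
    if missing:
        raise AlignmentError(
            f"neuron_subset not present in both epoch tensors: {missing[:5]}"
        )
    rows_a = [index_a[n] for n in neuron_subset]
    rows_b = [index_b[n] for n in neuron_subset]
    activity = np.concatenate(
        [epochs_a.values[rows_a], epochs_b.values[rows_b]], axis=1
    )
    labels = np.concatenate(
        [np.ones(epochs_a.n_trials, int), np.zeros(epochs_b.n_trials, int)]
    )
    return TrialTensor(
        activity=activity,
        labels=labels,
        frame_rate=epochs_a.frame_rate,
        align_index=epochs_a.align_index,
        neuron_ids=list(neuron_subset),
        label_names=(epochs_a.label or "A", epochs_b.label or "B"),
    )


def _resolve_folds(labels: np.ndarray, folds: int) -> int:
    counts = np.bincount(labels)
    counts = counts[counts > 0]
    if counts.size < 2:
        raise LabelError("decoding needs two non-empty classes")
    min_class = int(counts.min())
    if min_class < 2:
        raise LabelError(f"smallest class has {min_class} trial(s); need >= 2")
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_class} (smallest class size)",
            stacklevel=3,
        )
        return min_class
    return folds


def _cv_accuracies(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int | None
) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = _make_svm()
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return np.asarray(accs)


def decode_cv(
    tensor: TrialTensor,
    folds: int = 10,
    seed: int | None = None,
    window: WindowSpec | None = DEFAULT_FEATURE_WINDOW,
    flatten: bool = False,
) -> DecoderOutput:
    """Stratified k-fold cross-validated linear decoding accuracy.

    Accuracy per fold is the fraction of correctly predicted held-out
    labels. Folds are reduced (with a warning, minimum 2) when the
    smallest class has fewer trials than requested folds. The reported
    hyperplane comes from a final fit on all trials.
    """
    X = tensor.features(window=window, flatten=flatten)
    y = tensor.labels
    folds_used = _resolve_folds(y, folds)
    accs = _cv_accuracies(X, y, folds_used, seed)
    final = _make_svm()
    final.fit(X, y)
    svc = final.named_steps["linearsvc"]
    return DecoderOutput(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        hyperplane_w=svc.coef_.ravel().copy(),
        hyperplane_b=float(svc.intercept_[0]),
        folds_used=folds_used,
        seed=seed,
        cdf=performance_cdf(accs),
    )


def shuffled_null(
    tensor: TrialTensor,
    n_shuffles: int = 100,
    folds: int = 10,
    seed: int | None = None,
    window: WindowSpec | None = DEFAULT_FEATURE_WINDOW,
    flatten: bool = False,
) -> NullResult:
    """Shuffled-label chance benchmark for :func:`decode_cv`.

    The binary label vector is randomly permuted ``n_shuffles`` times and
    the full cross-validation repeated on each permutation. The empirical
    p-value for the real mean accuracy carries add-one smoothing:
    p = (1 + #{null >= real}) / (n_shuffles + 1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    X = tensor.features(window=window, flatten=flatten)
    y = tensor.labels
    folds_used = _resolve_folds(y, folds)
    real = _cv_accuracies(X, y, folds_used, seed).mean()
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        y_perm = rng.permutation(y)
        cv_seed = int(rng.integers(0, 2**31 - 1))
        null[k] = _cv_accuracies(X, y_perm, folds_used, cv_seed).mean()
    p = (1 + int(np.sum(null >= real))) / (n_shuffles + 1)
    return NullResult(null_accuracies=null, real_accuracy=float(real), p_value=p)


def performance_cdf(fold_accuracies) -> np.ndarray:
    """Empirical CDF of fold-level accuracies.

    Returns sorted ``(accuracy, cumulative probability)`` pairs; the final
    cumulative probability is 1.
    """
    accs = np.sort(np.asarray(fold_accuracies, dtype=float))
    if accs.size == 0:
        raise ValueError("fold_accuracies must be non-empty")
    values, counts = np.unique(accs, return_counts=True)
    cum = np.cumsum(counts) / accs.size
    return np.column_stack([values, cum])


def decode_timecourse(
    epochs_a: EpochTensor,
    epochs_b: EpochTensor,
    neuron_subset: list[str],
    window_len: float = 1.0,
    folds: int = 5,
    time_grid: np.ndarray | None = None,
    seed: int | None = None,
    n_null: int = 5,
) -> TimecourseResult:
    """Decoding accuracy as a function of time relative to onset.

    At each grid time ``t`` the features are per-neuron mean activity over
    ``[t, t + window_len)`` and the decoder is cross-validated with
    ``folds`` folds. The control curve averages ``n_null`` shuffled-label
    runs per time point. ``auc_0_10`` integrates the accuracy curve over
    the portion of [0, 10] s the grid covers.
    """
    tensor = build_trial_tensor(epochs_a, epochs_b, neuron_subset)
    if time_grid is None:
        time_grid = np.arange(-10.0, 9.0 + 1e-9, 0.5)
    time_grid = np.asarray(time_grid, dtype=float)
    lo, hi = -epochs_a.pre_s, epochs_a.post_s
    if time_grid.min() < lo - 1e-9 or time_grid.max() + window_len > hi + 1e-9:
        raise WindowError(
            f"time grid with {window_len}s windows exceeds epoch span [{lo},{hi}]"
        )
    rng = np.random.default_rng(seed)
    y = tensor.labels
    folds_used = _resolve_folds(y, folds)
    acc = np.empty(time_grid.size)
    null = np.empty(time_grid.size)
    for j, t in enumerate(time_grid):
        X = tensor.features(window=WindowSpec(t, t + window_len))
        cv_seed = int(rng.integers(0, 2**31 - 1))
        acc[j] = _cv_accuracies(X, y, folds_used, cv_seed).mean()
        null_accs = []
        for _ in range(n_null):
            y_perm = rng.permutation(y)
            null_accs.append(
                _cv_accuracies(
                    X, y_perm, folds_used, int(rng.integers(0, 2**31 - 1))
                ).mean()
            )
        null[j] = float(np.mean(null_accs)) if null_accs else np.nan
    mask = (time_grid >= 0.0) & (time_grid <= 10.0)
    auc = float(np.trapezoid(acc[mask], time_grid[mask])) if mask.sum() >= 2 else np.nan
    return TimecourseResult(
        times=time_grid,
        accuracy=acc,
        null_accuracy=null,
        auc_0_10=auc,
        window_len=window_len,
        folds=folds_used,
    )


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def projection_decoder(
    traces: TraceMatrix,
    events: pd.DataFrame,
    label: str,
    neuron_subset: list[str],
    baseline_pre_s: float = 5.0,
    threshold: float | None = None,
    min_duration: float = 0.5,
    split_frac: float = 0.5,
    seed: int | None = None,
) -> ProjectionResult:
    """Consecutive-split projection decoder with event-interval prediction.

    The session is split into two consecutive segments at ``split_frac``.
    A classifier is trained on the first segment using frames inside the
    labeled event intervals as positives and frames from the
    ``baseline_pre_s``-second window before each onset as negatives. Every
    frame of the second segment is then projected onto the hyperplane
    normal (signed distance); runs of projection above ``threshold`` are
    merged into predicted event intervals, and intervals shorter than
    ``min_duration`` are dropped. The sign convention puts the event class
    on the positive side.

    ``threshold=None`` (default) uses the midpoint between the mean
    projections of the two training classes. Out-of-sample projections
    regress toward zero relative to the hinge-loss margins seen in
    training, so the raw hyperplane (threshold 0) over-predicts events on
    held-out data; the class midpoint is robust to that shift. Pass an
    explicit value to threshold at the hyperplane itself or anywhere else.
    """
    if not neuron_subset:
        raise ValueError("neuron_subset must not be empty")
    if traces.stage == "raw":
        raise ValueError("projection_decoder expects dff or zscored traces")
    if not 0 < split_frac < 1:
        raise ValueError("split_frac must be in (0, 1)")
    sub = traces.subset(neuron_subset)
    split_frame = int(np.floor(sub.n_frames * split_frac))
    split_time = split_frame / sub.frame_rate
    sel = events[events["label"] == label]
    if sel.empty:
        raise EmptyEpochError(f"no events with label {label!r}")
    offsets = sel["offset_s"].to_numpy()
    onsets = sel["onset_s"].to_numpy()
    if np.isnan(offsets).any():
        raise ValueError("projection decoder needs events with offsets")
    train_mask_evt = offsets <= split_time
    test_mask_evt = onsets >= split_time
    if not train_mask_evt.any() or not test_mask_evt.any():
        raise SplitError(
            f"a session half contains no {label!r} events; "
            f"adjust split_frac (currently {split_frac})"
        )

    fr = sub.frame_rate
    pos = np.zeros(split_frame, dtype=bool)
    neg = np.zeros(split_frame, dtype=bool)
    for onset, offset in zip(onsets[train_mask_evt], offsets[train_mask_evt]):
        i0 = max(time_to_frame(onset, fr), 0)
        i1 = min(time_to_frame(offset, fr), split_frame)
        pos[i0:i1] = True
        b0 = max(time_to_frame(onset - baseline_pre_s, fr), 0)
        neg[b0:i0] = True
    neg &= ~pos
    if pos.sum() < 2 or neg.sum() < 2:
        raise SplitError("too few training frames in the first session half")
    X_train = np.concatenate(
        [sub.values[:, :split_frame][:, pos].T, sub.values[:, :split_frame][:, neg].T]
    )
    y_train = np.concatenate([np.ones(int(pos.sum()), int), np.zeros(int(neg.sum()), int)])
    clf = _make_svm()
    clf.fit(X_train, y_train)
    svc = clf.named_steps["linearsvc"]

    train_scores = clf.decision_function(X_train)
    train_event_mean = float(train_scores[y_train == 1].mean())
    train_baseline_mean = float(train_scores[y_train == 0].mean())
    if threshold is None:
        threshold = 0.5 * (train_event_mean + train_baseline_mean)

    X_test = sub.values[:, split_frame:].T
    projection = clf.decision_function(X_test)
    times = (split_frame + np.arange(projection.size)) / fr

    above = projection > threshold
    intervals: list[tuple[float, float]] = []
    if above.any():
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        for s, e in zip(starts, ends):
            t0, t1 = times[s], times[e] + 1.0 / fr
            if t1 - t0 >= min_duration:
                intervals.append((float(t0), float(t1)))
    return ProjectionResult(
        times=times,
        projection=projection,
        threshold=threshold,
        predicted_intervals=_merge_intervals(intervals),
        train_span=(0.0, split_time),
        test_span=(split_time, sub.n_frames / fr),
        hyperplane_w=svc.coef_.ravel().copy(),
        hyperplane_b=float(svc.intercept_[0]),
        train_event_mean=train_event_mean,
        train_baseline_mean=train_baseline_mean,
    )


def event_agreement(
    predicted_intervals: list[tuple[float, float]],
    actual_intervals: list[tuple[float, float]],
    frame_rate: float,
    span: tuple[float, float] | None = None,
) -> AgreementResult:
    """Agreement between predicted and observed event intervals.

    * ``frame_accuracy``: fraction of frames in ``span`` where the binary
      predicted/actual occupancy agrees.
    * ``hit_rate``: fraction of actual intervals overlapped by at least
      one predicted interval (NaN, with a warning, if there are none).
    * ``iou``: total intersection time over total union time, computed on
      the merged interval sets in continuous time.
    """
    pred = _merge_intervals([tuple(map(float, iv)) for iv in predicted_intervals])
    act = _merge_intervals([tuple(map(float, iv)) for iv in actual_intervals])
    if span is None:
        all_iv = pred + act
        if not all_iv:
            raise ValueError("no intervals and no span given")
        span = (min(s for s, _ in all_iv), max(e for _, e in all_iv))

    def _intersection(a, b):
        total = 0.0
        for s1, e1 in a:
            for s2, e2 in b:
                total += max(0.0, min(e1, e2) - max(s1, s2))
        return total

    inter = _intersection(pred, act)
    len_pred = sum(e - s for s, e in pred)
    len_act = sum(e - s for s, e in act)
    union = len_pred + len_act - inter
    iou = inter / union if union > 0 else (1.0 if not pred and not act else 0.0)

    n_frames = max(int(round((span[1] - span[0]) * frame_rate)), 1)
    grid = span[0] + (np.arange(n_frames) + 0.5) / frame_rate

    def _occupancy(ivs):
        occ = np.zeros(n_frames, dtype=bool)
        for s, e in ivs:
            occ |= (grid >= s) & (grid < e)
        return occ

    frame_accuracy = float(np.mean(_occupancy(pred) == _occupancy(act)))
    if not act:
        warnings.warn("no actual intervals: hit rate undefined", stacklevel=2)
        hit_rate = float("nan")
    else:
        hit_rate = float(
            np.mean([_intersection([iv], pred) > 0 for iv in act])
        )
    return AgreementResult(
        frame_accuracy=frame_accuracy, hit_rate=hit_rate, iou=iou, n_frames=n_frames
    )
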