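"""Event-responsive neuron detection and classification.

A neuron counts as event-activated when two conditions hold jointly:

1. a within-trial permutation test rejects the null that its baseline and
   event windows are exchangeable (one-sided, activation direction), and
2. its average z-scored response in the event window exceeds a magnitude
   threshold (0.2 z by default).

Selectivity between two events is quantified by the selectivity response
index SRI = (A - B)/(A + B) over the mean event-window responses A and B
of the same registered neurons, with fixed ±0.2 cut-offs. Pre-cells and
post-cells around feeding-bout onsets reuse the same permutation
machinery with shifted windows and a max statistic.

Permutation scheme: the observed statistic contrasts the event-window and
baseline-window statistics within each trial, so the null is built by
exchanging exactly those two window labels within each trial (an
independent fair coin per trial). With M trials the full null has 2^M
states; ``exact=True`` enumerates them all, otherwise ``n_perm`` random
draws are used with the add-one p-value smoothing
p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochTensor, WindowSpec
from .errors import InsufficientDataError, RegistrationError, WindowError
from .signals import window_stat

__all__ = [
    "ActivationResult",
    "SelectivityResult",
    "PhaseResult",
    "detect_activated",
    "compute_sri",
    "classify_selectivity",
    "identify_phase_cells",
    "join_registered",
    "PRE_CELL_WINDOWS",
    "POST_CELL_WINDOWS",
]

#: (baseline, event) windows for phenotyping cells around feeding-bout onset
PRE_CELL_WINDOWS = (WindowSpec(-10.0, -5.0), WindowSpec(-5.0, 0.0))
POST_CELL_WINDOWS = (WindowSpec(-5.0, 0.0), WindowSpec(0.0, 5.0))

SRI_EPS = 1e-6


@dataclass
class ActivationResult:
    """Per-neuron permutation-test outcome for one event type."""

    neuron_ids: list[str]
    p_value: np.ndarray
    response: np.ndarray  # trial-mean event-window statistic (z units)
    baseline: np.ndarray  # trial-mean baseline-window statistic (z units)
    activated: np.ndarray  # p < alpha AND response > z_threshold
    params: dict = field(default_factory=dict)

    @property
    def activated_ids(self) -> list[str]:
        return [nid for nid, a in zip(self.neuron_ids, self.activated) if a]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "p_value": self.p_value,
                "response": self.response,
                "baseline": self.baseline,
                "activated": self.activated,
            }
        )


@dataclass
class SelectivityResult:
    """SRI values and categories for neurons registered across two events."""

    neuron_ids: list[str]
    A: np.ndarray
    B: np.ndarray
    sri: np.ndarray  # NaN where undefined
    category: np.ndarray  # A_selective | B_selective | shared | undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "A": self.A,
                "B": self.B,
                "sri": self.sri,
                "category": self.category,
            }
        )


@dataclass
class PhaseResult:
    """Pre-/post-cell phenotype per neuron around feeding-bout onsets."""

    neuron_ids: list[str]
    phase: np.ndarray  # 'pre' | 'post' | 'neither'
    max_response: np.ndarray  # winning event-window max (z)
    pre: ActivationResult
    post: ActivationResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_ids,
                "phase": self.phase,
                "max_response": self.max_response,
                "p_pre": self.pre.p_value,
                "p_post": self.post.p_value,
            }
        )


def _window_trial_stats(
    epochs: EpochTensor, window: WindowSpec, statistic: str
) -> np.ndarray:
    if statistic not in ("mean", "max"):
        raise ValueError(f"statistic must be 'mean' or 'max', got {statistic!r}")
    return window_stat(epochs, window, stat=statistic)


def detect_activated(
    epochs: EpochTensor,
    baseline: WindowSpec = WindowSpec(-5.0, 0.0),
    event: WindowSpec = WindowSpec(0.0, 5.0),
    n_perm: int = 1000,
    alpha: float = 0.05,
    z_threshold: float = 0.2,
    statistic: str = "mean",
    seed: int | None = None,
    exact: bool = False,
) -> ActivationResult:
    """Permutation test of event-window vs baseline-window activity.

    The observed statistic per neuron is the trial mean of the per-trial
    event-window statistic minus the baseline-window statistic. The null
    exchanges the two window labels independently within each trial.

    With ``exact=True`` all 2^M label assignments are enumerated and
    p = #{null >= observed}/2^M (the identity assignment guarantees
    p >= 2^-M); trials are capped at 20 in this mode. Otherwise ``n_perm``
    random assignments are drawn and p carries add-one smoothing, so
    p in [1/(n_perm+1), 1].
    """
    if baseline.overlaps(event):
        raise WindowError(
            f"baseline [{baseline.t0},{baseline.t1}) overlaps "
            f"event [{event.t0},{event.t1})"
        )
    if epochs.n_trials < 2:
        raise InsufficientDataError(
            f"permutation test needs >= 2 trials, got {epochs.n_trials}"
        )
    wb = _window_trial_stats(epochs, baseline, statistic)  # (N, M)
    we = _window_trial_stats(epochs, event, statistic)
    diff = we - wb
    obs = diff.mean(axis=1)
    m = epochs.n_trials

    if exact:
        if m > 20:
            raise InsufficientDataError(
                f"exact enumeration limited to 20 trials, got {m}"
            )
        n_states = 2**m
        # sign +1 keeps the trial's labels, -1 swaps baseline/event
        bits = (np.arange(n_states)[:, None] >> np.arange(m)[None, :]) & 1
        signs = 1.0 - 2.0 * bits  # (2^m, m)
        null = (signs[:, None, :] * diff[None, :, :]).mean(axis=2)  # (2^m, N)
        p = (null >= obs[None, :]).sum(axis=0) / n_states
        n_perm_used = n_states
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, m)) * 2.0 - 1.0
        null = (signs[:, None, :] * diff[None, :, :]).mean(axis=2)
        p = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
        n_perm_used = n_perm

    response = we.mean(axis=1)
    activated = (p < alpha) & (response > z_threshold)
    return ActivationResult(
        neuron_ids=list(epochs.neuron_ids),
        p_value=p,
        response=response,
        baseline=wb.mean(axis=1),
        activated=activated,
        params={
            "baseline": (baseline.t0, baseline.t1),
            "event": (event.t0, event.t1),
            "n_perm": n_perm_used,
            "alpha": alpha,
            "z_threshold": z_threshold,
            "statistic": statistic,
            "exact": exact,
            "scheme": "within-trial baseline/event window-label exchange",
            "seed": seed,
            "label": epochs.label,
        },
    )


def compute_sri(
    A: np.ndarray,
    B: np.ndarray,
    neuron_ids: list[str] | None = None,
    threshold: float = 0.2,
) -> SelectivityResult:
    """Selectivity response index (A - B)/(A + B) with ±threshold cut-offs.

    A and B are the mean event-window responses of the *same* registered
    neurons in the two events. The index presumes non-negative responses;
    where ``A + B`` is non-positive or within ``1e-6`` of zero the ratio
    loses its [-1, 1] interpretation and the SRI is left undefined (NaN,
    category 'undefined').
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise RegistrationError(
            f"A and B cover different neuron sets: {A.shape} vs {B.shape}"
        )
    if neuron_ids is None:
        neuron_ids = [f"n{i}" for i in range(A.size)]
    elif len(neuron_ids) != A.size:
        raise RegistrationError("neuron_ids length does not match responses")
    denom = A + B
    defined = (denom > 0) & (np.abs(denom) > SRI_EPS)
    sri = np.full(A.shape, np.nan)
    sri[defined] = (A[defined] - B[defined]) / denom[defined]
    category = classify_selectivity(sri, threshold=threshold)
    return SelectivityResult(
        neuron_ids=list(neuron_ids), A=A, B=B, sri=sri, category=category
    )


def classify_selectivity(sri: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Map SRI values to categories with fixed cut-offs.

    SRI > threshold -> selective for event A; SRI < -threshold -> selective
    for event B; in between -> activated in both ('shared'); NaN ->
    'undefined'.
    """
    sri = np.asarray(sri, dtype=float)
    cat = np.full(sri.shape, "undefined", dtype=object)
    defined = np.isfinite(sri)
    cat[defined & (sri > threshold)] = "A_selective"
    cat[defined & (sri < -threshold)] = "B_selective"
    cat[defined & (sri >= -threshold) & (sri <= threshold)] = "shared"
    return cat


def identify_phase_cells(
    epochs: EpochTensor,
    n_perm: int = 1000,
    alpha: float = 0.05,
    z_threshold: float = 0.2,
    seed: int | None = None,
) -> PhaseResult:
    """Classify neurons as pre-cells, post-cells, or neither.

    Pre-cells: baseline [-10, -5) vs event [-5, 0) before bout onset;
    post-cells: baseline [-5, 0) vs event [0, 5). Both tests use the
    maximum z in each window as the per-trial statistic and the same
    permutation machinery as :func:`detect_activated`. The two tests run
    independently; a neuron passing both is assigned the phase with the
    larger event-window max, ties going to 'pre'.
    """
    if epochs.pre_s < 10.0 or epochs.post_s < 5.0:
        raise WindowError(
            f"phase analysis needs epochs spanning [-10, +5] s, got "
            f"[-{epochs.pre_s}, {epochs.post_s}]"
        )
    pre_res = detect_activated(
        epochs,
        baseline=PRE_CELL_WINDOWS[0],
        event=PRE_CELL_WINDOWS[1],
        n_perm=n_perm,
        alpha=alpha,
        z_threshold=z_threshold,
        statistic="max",
        seed=seed,
    )
    post_res = detect_activated(
        epochs,
        baseline=POST_CELL_WINDOWS[0],
        event=POST_CELL_WINDOWS[1],
        n_perm=n_perm,
        alpha=alpha,
        z_threshold=z_threshold,
        statistic="max",
        seed=None if seed is None else seed + 1,
    )
    phase = np.full(epochs.n_neurons, "neither", dtype=object)
    max_response = np.zeros(epochs.n_neurons)
    for i in range(epochs.n_neurons):
        is_pre, is_post = pre_res.activated[i], post_res.activated[i]
        if is_pre and is_post:
            # disjoint grouping: the larger window max wins, tie -> pre
            if post_res.response[i] > pre_res.response[i]:
                phase[i], max_response[i] = "post", post_res.response[i]
            else:
                phase[i], max_response[i] = "pre", pre_res.response[i]
        elif is_pre:
            phase[i], max_response[i] = "pre", pre_res.response[i]
        elif is_post:
            phase[i], max_response[i] = "post", post_res.response[i]
        else:
            max_response[i] = max(pre_res.response[i], post_res.response[i])
    return PhaseResult(
        neuron_ids=list(epochs.neuron_ids),
        phase=phase,
        max_response=max_response,
        pre=pre_res,
        post=post_res,
    )


def join_registered(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    mapping: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join per-neuron results across two sessions on a cell map.

    ``mapping`` has columns ``id_a``/``id_b`` giving the cross-session
    correspondence produced upstream (e.g. by spatial-footprint
    registration); it must be injective both ways. ``frame_a`` and
    ``frame_b`` are per-neuron tables with a ``neuron_id`` column. Returns
    the matched records (columns suffixed ``_a``/``_b``) plus the lists of
    unmatched neuron ids on each side.
    """
    for col in ("id_a", "id_b"):
        if col not in mapping.columns:
            raise RegistrationError(f"mapping is missing column {col!r}")
        dup = mapping[col][mapping[col].duplicated()]
        if not dup.empty:
            raise RegistrationError(
                f"duplicate ids in mapping column {col!r}: {sorted(set(dup))[:5]}"
            )
    a = frame_a.copy()
    b = frame_b.copy()
    if "neuron_id" not in a.columns or "neuron_id" not in b.columns:
        raise RegistrationError("result frames need a 'neuron_id' column")
    a["neuron_id"] = a["neuron_id"].astype(str)
    b["neuron_id"] = b["neuron_id"].astype(str)
    mapping = mapping.astype({"id_a": str, "id_b": str})
    merged = mapping.merge(
        a.add_suffix("_a"), left_on="id_a", right_on="neuron_id_a", how="inner"
    ).merge(b.add_suffix("_b"), left_on="id_b", right_on="neuron_id_b", how="inner")
    merged = merged.drop(columns=["neuron_id_a", "neuron_id_b"])
    matched_a = set(merged["id_a"])
    matched_b = set(merged["id_b"])
    unmatched_a = [nid for nid in a["neuron_id"] if nid not in matched_a]
    unmatched_b = [nid for nid in b["neuron_id"] if nid not in matched_b]
    return merged.reset_index(drop=True), unmatched_a, unmatched_b
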