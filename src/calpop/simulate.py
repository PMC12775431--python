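"""Synthetic session generator with known ground truth.

Emulates the data this pipeline is built to consume: 30 FPS miniscope
trace matrices of a few hundred neurons with designated event-responsive
subpopulations, 100 Hz bulk photometry channels, behavioral event
schedules (chamber entries, feeding bouts), and conditioned-place-
preference occupancy/intake tables.

Trace model
-----------
Each neuron's raw trace is

    F(t) = F0 + drift(t) + kernel * spikes(t) + Gaussian noise

where spikes is a per-frame Bernoulli train (baseline rate 0.01/frame)
and the kernel is a difference of exponentials
``exp(-t/decay_tau) - exp(-t/rise_tau)`` normalized to unit peak
(rise 0.2 s, decay 1.5 s — GCaMP6s-like). Neurons belonging to an
ensemble get an additional elevated-rate spike train inside the ensemble's
response window after each matching event; its per-spike amplitude is
calibrated so the expected steady-state event-window mean equals
``response_amplitude`` times the neuron's background SD, i.e. the nominal
amplitude is expressed in (approximate) z units of the final z-scored
trace. Non-responsive neurons carry identical background statistics with
no event-locked term.

All randomness flows from the single session seed through
``numpy.random.SeedSequence.spawn``: one child stream drives the event
schedule and each neuron owns its own child, so adding neurons to a
config leaves earlier neurons' traces bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import TraceMatrix, make_event_table
from .errors import ConfigError

__all__ = [
    "EnsembleSpec",
    "ScheduleSpec",
    "KernelSpec",
    "SessionConfig",
    "GroundTruth",
    "calcium_kernel",
    "generate_session",
    "generate_photometry",
    "generate_behavior",
]


@dataclass
class EnsembleSpec:
    """One event-responsive subpopulation."""

    label: str
    fraction: float  # probability that a neuron belongs to this ensemble
    amplitude: float  # target event-window mean, in background-SD (z) units
    window: tuple[float, float] = (0.0, 5.0)  # response window rel. to onset (s)
    jitter_sd: float = 0.0  # per-trial onset jitter (s)


@dataclass
class ScheduleSpec:
    """One behavioral event type to place on the session timeline."""

    label: str
    n_trials: int
    min_spacing: float = 25.0  # s between any two onsets (all labels pooled)
    duration: float = 5.0  # bout length (s); offset = onset + duration


@dataclass
class KernelSpec:
    rise_tau: float = 0.2  # s
    decay_tau: float = 1.5  # s


@dataclass
class SessionConfig:
    n_neurons: int = 200
    frame_rate: float = 30.0  # Hz (miniscope default; use 100 for photometry)
    duration: float = 900.0  # s
    seed: int = 0
    ensembles: list[EnsembleSpec] = field(default_factory=list)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    noise_sd: float = 0.2  # fluorescence a.u.
    drift_amplitude: float = 0.5  # a.u.; default 5% of baseline_f0
    baseline_f0: float = 10.0  # a.u.
    event_schedule: list[ScheduleSpec] = field(default_factory=list)
    baseline_rate: float = 0.01  # background spikes per frame
    event_rate: float = 0.3  # elevated spike probability inside response window
    transient_amplitude: float = 1.0  # a.u. per background spike
    edge_margin: float = 10.0  # keep onsets this far from session edges (s)

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.baseline_f0 <= 0:
            raise ConfigError("baseline_f0 must be positive")
        if self.kernel.rise_tau <= 0 or self.kernel.decay_tau <= 0:
            raise ConfigError("kernel taus must be positive")
        if self.kernel.rise_tau >= self.kernel.decay_tau:
            raise ConfigError("kernel rise_tau must be smaller than decay_tau")
        if not 0 <= self.baseline_rate <= 1 or not 0 < self.event_rate <= 1:
            raise ConfigError("baseline_rate/event_rate must be probabilities")
        labels = {s.label for s in self.event_schedule}
        for ens in self.ensembles:
            if not 0 <= ens.fraction <= 1:
                raise ConfigError(
                    f"ensembles[{ens.label!r}].fraction must be in [0, 1]"
                )
            if ens.label not in labels:
                raise ConfigError(
                    f"ensembles[{ens.label!r}] has no matching event_schedule entry"
                )
            if ens.jitter_sd < 0:
                raise ConfigError(f"ensembles[{ens.label!r}].jitter_sd must be >= 0")
        for sched in self.event_schedule:
            if sched.n_trials < 1:
                raise ConfigError(f"event_schedule[{sched.label!r}].n_trials >= 1")
            if sched.min_spacing <= 0 or sched.duration <= 0:
                raise ConfigError(
                    f"event_schedule[{sched.label!r}] spacing/duration must be > 0"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        d["ensembles"] = [EnsembleSpec(**e) if isinstance(e, dict) else e
                          for e in d.get("ensembles", [])]
        d["event_schedule"] = [ScheduleSpec(**s) if isinstance(s, dict) else s
                               for s in d.get("event_schedule", [])]
        k = d.get("kernel", KernelSpec())
        d["kernel"] = KernelSpec(**k) if isinstance(k, dict) else k
        # tuples survive YAML as lists
        for e in d["ensembles"]:
            e.window = tuple(e.window)
        return cls(**d)


@dataclass
class GroundTruth:
    """Which neurons respond to which events, for scoring downstream stages."""

    responsive_map: dict[str, list[str]]  # neuron id -> sorted event labels
    amplitudes: dict[str, dict[str, float]]  # neuron id -> {label: amplitude}
    seed: int

    def responsive_to(self, label: str) -> set[str]:
        return {
            nid for nid, labels in self.responsive_map.items() if label in labels
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def calcium_kernel(kernel: KernelSpec, frame_rate: float) -> np.ndarray:
    """Difference-of-exponentials transient, sampled at frame_rate, unit peak."""
    t_end = kernel.decay_tau * 8  # tail below ~3e-4 of peak
    t = np.arange(0, t_end, 1.0 / frame_rate)
    k = np.exp(-t / kernel.decay_tau) - np.exp(-t / kernel.rise_tau)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("kernel collapsed; check rise_tau < decay_tau")
    return k / peak


def _sample_schedule(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Reject-sample event onsets so every pair respects min_spacing.

    Spacing is enforced across all labels pooled (epochs of different
    events never overlap by construction). Hard failure after 10,000
    rejected draws, which indicates an over-packed schedule.
    """
    spacing = max((s.min_spacing for s in config.event_schedule), default=0.0)
    lo = config.edge_margin
    onsets: list[float] = []
    labels: list[str] = []
    durations: list[float] = []
    attempts = 0
    for sched in config.event_schedule:
        hi = config.duration - config.edge_margin - sched.duration
        if hi <= lo:
            raise ConfigError(
                f"event_schedule[{sched.label!r}]: session too short for margins"
            )
        for _ in range(sched.n_trials):
            while True:
                candidate = rng.uniform(lo, hi)
                if all(abs(candidate - o) >= spacing for o in onsets):
                    break
                attempts += 1
                if attempts > 10_000:
                    raise ConfigError(
                        "event_schedule: could not place onsets under "
                        "min_spacing after 10,000 attempts"
                    )
            onsets.append(candidate)
            labels.append(sched.label)
            durations.append(sched.duration)
    offsets = [o + d for o, d in zip(onsets, durations)]
    return make_event_table(labels, onsets, offsets)


def generate_session(
    config: SessionConfig,
) -> tuple[TraceMatrix, pd.DataFrame, GroundTruth]:
    """Generate one miniscope-like session: raw traces, events, ground truth.

    Deterministic given ``config.seed``: two calls with the same config
    produce bit-identical outputs.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_neurons)
    schedule_rng = np.random.default_rng(children[0])
    events = _sample_schedule(config, schedule_rng)

    n_frames = int(round(config.duration * config.frame_rate))
    kern = calcium_kernel(config.kernel, config.frame_rate)
    kernel_sum = kern.sum()
    onsets_by_label = {
        label: grp["onset_s"].to_numpy()
        for label, grp in events.groupby("label")
    }

    impulses = np.zeros((config.n_neurons, n_frames))
    noise = np.empty((config.n_neurons, n_frames))
    drift = np.empty((config.n_neurons, n_frames))
    responsive_map: dict[str, list[str]] = {}
    amplitudes: dict[str, dict[str, float]] = {}
    neuron_ids = [f"n{i:03d}" for i in range(config.n_neurons)]
    t = np.arange(n_frames) / config.frame_rate

    for i, nid in enumerate(neuron_ids):
        rng = np.random.default_rng(children[1 + i])
        # 1) ensemble membership (fixed draw order keeps streams stable)
        member = [rng.random() < ens.fraction for ens in config.ensembles]
        # 2) background spikes, drift, noise
        impulses[i] = (
            rng.random(n_frames) < config.baseline_rate
        ) * config.transient_amplitude
        phase = rng.uniform(0, 2 * np.pi)
        walk = np.cumsum(rng.normal(0.0, 1.0, n_frames))
        walk *= config.drift_amplitude / (2.0 * np.sqrt(n_frames))
        drift[i] = (
            config.drift_amplitude * np.sin(2 * np.pi * 3 * t / config.duration + phase)
            + walk
        )
        noise[i] = rng.normal(0.0, config.noise_sd, n_frames)
        # background SD used as the z-unit reference for event amplitudes
        background = impulses[i].copy()
        sigma_ref = float(
            np.std(
                sps.fftconvolve(background, kern)[:n_frames] + drift[i] + noise[i]
            )
        )
        sigma_ref = max(sigma_ref, 1e-12)
        # 3) event-locked elevated-rate spiking for member neurons
        labels_hit: list[str] = []
        for ens, is_member in zip(config.ensembles, member):
            if not is_member:
                continue
            spike_amp = (
                ens.amplitude * sigma_ref / (config.event_rate * kernel_sum)
            )
            for onset in onsets_by_label.get(ens.label, ()):
                jitter = rng.normal(0.0, ens.jitter_sd) if ens.jitter_sd > 0 else 0.0
                w0 = int(np.floor((onset + jitter + ens.window[0]) * config.frame_rate))
                w1 = int(np.floor((onset + jitter + ens.window[1]) * config.frame_rate))
                w0, w1 = max(w0, 0), min(w1, n_frames)
                if w1 <= w0:
                    continue
                train = rng.random(w1 - w0) < config.event_rate
                impulses[i, w0:w1] += train * spike_amp
            if ens.amplitude != 0:
                # amplitude-0 members contribute nothing and are not
                # counted as ground-truth responsive
                labels_hit.append(ens.label)
        if labels_hit:
            responsive_map[nid] = sorted(labels_hit)
            amplitudes[nid] = {
                ens.label: ens.amplitude
                for ens, m in zip(config.ensembles, member)
                if m and ens.amplitude != 0
            }

    traces = sps.fftconvolve(impulses, kern[None, :], axes=1)[:, :n_frames]
    traces += config.baseline_f0 + drift + noise
    tm = TraceMatrix(traces, config.frame_rate, neuron_ids, stage="raw")
    gt = GroundTruth(
        responsive_map=responsive_map, amplitudes=amplitudes, seed=config.seed
    )
    return tm, events, gt


def generate_photometry(
    config: SessionConfig,
    polarity: int = -1,
    onset_lag: float = 0.86,
    amplitude: float | None = None,
) -> tuple[TraceMatrix, pd.DataFrame]:
    """Generate a single-channel bulk photometry session.

    The channel carries baseline + drift + noise plus one deterministic
    kernel-shaped deflection per scheduled event, of the given polarity,
    beginning ``onset_lag`` seconds after each onset. The defaults emulate
    an extracellular-ATP-sensor signal, which dips ~0.86 s after
    feeding-bout onset; calcium-like positive signals use ``polarity=+1``
    and a lag of zero. By default the deflection amplitude comes from the
    first ensemble spec, in background-SD units (1.0 if none is given);
    passing ``amplitude`` sets it in absolute fluorescence units instead —
    useful for noiseless signals, whose background SD is zero.
    """
    config.validate()
    if polarity not in (+1, -1):
        raise ConfigError("polarity must be +1 or -1")
    if onset_lag < 0:
        raise ConfigError("onset_lag must be >= 0")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2)
    schedule_rng = np.random.default_rng(children[0])
    events = _sample_schedule(config, schedule_rng)

    n_frames = int(round(config.duration * config.frame_rate))
    rng = np.random.default_rng(children[1])
    t = np.arange(n_frames) / config.frame_rate
    noise = rng.normal(0.0, config.noise_sd, n_frames)
    phase = rng.uniform(0, 2 * np.pi)
    walk = np.cumsum(rng.normal(0.0, 1.0, n_frames))
    walk *= config.drift_amplitude / (2.0 * np.sqrt(n_frames))
    drift = (
        config.drift_amplitude * np.sin(2 * np.pi * 3 * t / config.duration + phase)
        + walk
    )
    if amplitude is None:
        sigma_ref = max(float(np.std(noise + drift)), 1e-12)
        amplitude = (
            config.ensembles[0].amplitude if config.ensembles else 1.0
        ) * sigma_ref

    kern = calcium_kernel(config.kernel, config.frame_rate)
    deflection = np.zeros(n_frames)
    for onset in events["onset_s"].to_numpy():
        start = int(np.floor((onset + onset_lag) * config.frame_rate))
        if start >= n_frames:
            continue
        stop = min(start + kern.size, n_frames)
        deflection[start:stop] += kern[: stop - start]
    values = config.baseline_f0 + drift + noise + polarity * amplitude * deflection
    tm = TraceMatrix(
        values[None, :], config.frame_rate, ["photometry"], stage="raw"
    )
    return tm, events


def generate_behavior(
    n_mice: int,
    paired_bias: float = 0.7,
    intake_mean: tuple[float, float] = (2.0, 1.0),
    intake_sd: tuple[float, float] = (0.3, 0.3),
    total_time: float = 1200.0,
    occupancy_sd: float = 0.1,
    n_bouts: int = 8,
    bout_duration_mean: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a place-preference behavior table plus feeding bouts.

    Per mouse, the occupancy fraction of the paired context is drawn as
    ``clip(Normal(paired_bias, occupancy_sd), 0, 1)`` of ``total_time``
    (zero ``occupancy_sd`` makes the fraction exactly ``paired_bias``),
    and HFD intake per context is Normal with the given means/SDs,
    truncated at zero. Bout intervals are exponential-gap, exponential-
    duration. Deterministic given ``seed``.

    Returns ``(mice, bouts)``: one row per mouse with ``t_paired``,
    ``t_unpaired`` and intakes, and a long table of bout intervals.
    """
    if not 0 <= paired_bias <= 1:
        raise ConfigError("paired_bias must be in [0, 1]")
    if n_mice < 1:
        raise ConfigError("n_mice must be >= 1")
    if occupancy_sd < 0:
        raise ConfigError("occupancy_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    bout_rows = []
    for m in range(n_mice):
        frac = paired_bias
        if occupancy_sd > 0:
            frac = float(np.clip(rng.normal(paired_bias, occupancy_sd), 0.0, 1.0))
        t_paired = frac * total_time
        t_unpaired = (1.0 - frac) * total_time
        intake_p = max(float(rng.normal(intake_mean[0], intake_sd[0])), 0.0)
        intake_u = max(float(rng.normal(intake_mean[1], intake_sd[1])), 0.0)
        rows.append(
            {
                "mouse_id": f"m{m:02d}",
                "t_paired": t_paired,
                "t_unpaired": t_unpaired,
                "intake_paired_g": intake_p,
                "intake_unpaired_g": intake_u,
            }
        )
        t_cursor = float(rng.exponential(30.0))
        for _ in range(n_bouts):
            dur = float(rng.exponential(bout_duration_mean)) + 1.0
            bout_rows.append(
                {"mouse_id": f"m{m:02d}", "start_s": t_cursor, "end_s": t_cursor + dur}
            )
            t_cursor += dur + float(rng.exponential(30.0)) + 5.0
    return pd.DataFrame(rows), pd.DataFrame(bout_rows)
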