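# Methods

This note documents the statistical procedures calpop implements, the
conventions it fixes where the underlying analysis tradition leaves
choices open, and what its synthetic benchmarks do and do not show.

## Signal model and normalization

Traces enter as a neuron × frame matrix of raw fluorescence (arbitrary
units) at a known frame rate. Times are seconds everywhere; frame
indices are derived as `floor(t * frame_rate)` and never stored, which
keeps 30 FPS miniscope, 20 FPS behavior-video, and 100 Hz photometry
clocks consistent. All analysis windows are half-open `[t0, t1)` so
adjacent windows never double-count a shared boundary frame.

**ΔF/F** is (F − F₀)/F₀ per neuron. The baseline F₀ is the session-wide
mean by default; a sub-window of the session can be supplied when a
local baseline is preferable (e.g. photometry with slow drift). Neurons
with non-positive F₀ are an error, not silently clamped. ΔF/F is
invariant to rescaling the raw signal, which makes downstream results
independent of detector gain.

**z-scoring** is per neuron over the full session with the population
(divide-by-n) SD. Per-epoch z-scoring is deliberately not done: the
session-level scale is what makes a "0.2 z" activation threshold
comparable across neurons and sessions. Zero-SD neurons cannot be scaled
and are excluded with a warning so counts stay honest.

**Epochs** span `pre_s` before to `post_s` after each onset (defaults
10 s / 10 s: 600 frames at 30 FPS). Trials that would cross a session
edge are dropped — never padded — and the exclusion count is carried in
the result and the pipeline manifest.

**Windowed statistics** are `mean`, `max`, or `auc` per neuron and
trial. AUC is the trapezoidal integral of z against time (z·s); its
frame range includes the sample at `t1` (clipped to the epoch) so a
constant c over a 5 s window integrates to exactly 5c.

**Onset latency** is the time of the first post-baseline sample beyond
the baseline mean ± 2 SD, in the requested direction; `None` when never
crossed, and an error when the baseline SD is exactly zero (the
threshold is then undefined). Callers should note the rule's character:
with a white-noise baseline, each scanned sample crosses 2 SD with
probability ≈ 0.023, so the rule is meaningful only on signals whose
pre-onset segment is smooth at the scale of the baseline noise, or when
the scan starts close to the expected deflection.

## Event-activated neurons

A neuron is **event-activated** when two conditions hold jointly:

1. a one-sided permutation test rejects exchangeability of its baseline
   window [−5, 0) s and event window [0, 5) s at α = 0.05, and
2. its mean z-scored event-window response exceeds 0.2.

The test statistic is the trial mean of (event-window statistic −
baseline-window statistic). Because the statistic contrasts exactly two
windows within each trial, the null exchanges exactly those two window
labels within each trial — an independent fair coin per trial. Monte
Carlo mode draws `n_perm = 1000` assignments and reports the add-one
smoothed p = (1 + #{null ≥ observed})/(n_perm + 1), bounded below by
1/(n_perm + 1). Exact mode enumerates all 2^M assignments (M ≤ 20) and
reports p = #{null ≥ observed}/2^M; the identity assignment guarantees
p ≥ 2^−M. Every result records the scheme, windows, and seed.

The magnitude clause makes the rule conjunctive: a tiny but highly
consistent response is significant yet not "activated". Consequently the
null-session flag rate of the full rule sits far *below* α — that is
its purpose. Type-I calibration is therefore assessed on the p-clause
alone (threshold 0), where the flag rate on amplitude-zero synthetic
sessions is statistically consistent with α (measured 0.044 over 4000
neuron-tests, binomial p = 0.07 against 0.05). The test is mildly
conservative because a causal calcium transient straddling the
window boundary breaks exact time-reversal symmetry between windows.

**Selectivity (SRI).** For neurons registered across two events with
mean responses A and B over the same [0, 5) window, SRI = (A − B)/(A + B):
greater than 0.2 → selective for A, less than −0.2 → selective for B,
between → activated in both. The ratio presumes non-negative responses;
when A + B ≤ 10⁻⁶ the index loses its [−1, 1] interpretation and is
reported undefined (NaN) and excluded from category counts. Cross-session
correspondence tables (from footprint registration, performed upstream)
are inner-joined with both-ways injectivity enforced and unmatched
neurons listed.

**Pre-cells / post-cells.** The same permutation machinery with
phase-specific windows — pre: baseline [−10, −5) vs event [−5, 0);
post: baseline [−5, 0) vs event [0, 5) — and the per-trial window
*maximum* as statistic, matching the "max z > 0.2" magnitude rule. The
two tests run independently; a neuron passing both is assigned the phase
with the larger event-window max, ties to pre, so the groups are
disjoint.

## Population decoding

The decoder everywhere is a linear maximum-margin classifier (soft
margin, C = 1.0, class-balanced weights) with feature standardization
fit inside each training fold only — no statistics leak from held-out
trials. Features default to per-neuron mean activity over [0, 5) s
(robust at small trial counts); the full N × T flattening is available
by flag.

- **Cross-validation**: stratified k-fold (default 10), seed-fixed fold
  assignment; folds are reduced with a warning (minimum 2) when the
  smaller class is smaller than k. Accuracy is the fraction of correctly
  predicted held-out labels; the per-fold empirical CDF is reported.
- **Shuffled null**: the label vector is permuted `n_shuffles` times
  (default 100) and the identical CV repeated, giving a null accuracy
  distribution and p = (1 + #{null ≥ real})/(n_shuffles + 1).
- **Time course**: at each grid time t (default −10 to +9 s, step 0.5),
  features are each neuron's mean over [t, t + 1 s), 5-fold CV, with a
  shuffled-label control curve; the accuracy curve's trapezoidal AUC
  over the covered part of [0, 10] s summarizes post-onset decodability.
- **Projection decoder**: the session is split into two consecutive
  halves; the classifier is trained on first-half frames inside event
  intervals (positives) vs frames from the 5 s before each onset
  (negatives), and every second-half frame is projected onto the
  hyperplane normal. Runs above threshold become predicted event
  intervals after dropping those shorter than 0.5 s (suppresses
  single-frame flicker). The positive side is the event class by
  construction. The default threshold is the midpoint of the two
  training classes' mean projections rather than the hyperplane itself:
  hinge-loss training pushes training points beyond ±1 margin, and
  held-out projections regress toward zero relative to those margins, so
  thresholding at 0 systematically over-predicts events out of sample
  (observed: held-out non-event frames median ≈ −0.6 against a training
  baseline mean ≈ −3.3). Any explicit threshold, including 0 and +inf,
  can be passed.
- **Agreement**: predicted vs observed intervals are compared by
  frame-wise accuracy over a common span, per-event hit rate, and
  intersection-over-union computed on merged intervals in continuous
  time.

Decoding accuracy is invariant to any common affine rescaling of the
features (standardization absorbs it), and chance behavior is unbiased:
with labels drawn i.i.d., mean CV accuracy sits at 0.5 within Monte
Carlo error. Permutation (without replacement) shuffling instead has a
small known pessimistic bias from train/test label anti-correlation,
which is why the chance-calibration checks draw labels i.i.d. while the
shuffled-null procedure follows the permutation convention.

## Behavioral scores

CPP score = (t_paired − t_unpaired)/(t_paired + t_unpaired) ∈ [−1, 1],
antisymmetric under swapping contexts, undefined for zero total time.
Bout tables require offsets; overlapping bouts are merged (union) with a
warning, since real annotation files contain overlaps. Correlations
(Pearson or Spearman) drop incomplete pairs, report (r, p, n), require
n ≥ 3 and nonzero variance, and apply no multiple-testing correction —
that is the caller's responsibility.

## Synthetic sessions

The generator emulates the data the pipeline consumes, not the raw
videos: 30 FPS trace matrices (or 100 Hz single-channel photometry),
event schedules, and CPP occupancy/intake tables.

Each neuron's raw trace is F₀ + drift + kernel∗spikes + Gaussian noise.
The kernel is exp(−t/1.5 s) − exp(−t/0.2 s), unit peak — GCaMP6s-like
rise and decay. Background spiking is Bernoulli at 0.01/frame with 1.0
a.u. transients; drift is a 3-cycle sinusoid plus a random walk, 5% of
the 10 a.u. baseline by default, which exercises ΔF/F robustness; noise
SD is 0.2 a.u. Ensemble members get an elevated-rate (0.3/frame) spike
train inside the response window after each matching event, with
per-spike amplitude calibrated so the expected steady-state window mean
equals the nominal amplitude times the neuron's *background* SD. Nominal
amplitudes are therefore approximate z units: the signal itself inflates
the session SD, so a nominal 2.0 z ensemble realizes ≈ 1.0–1.4 z after
z-scoring — far above the 0.2 z rule, which is what the recovery
benchmarks rely on.

Event schedules reject-sample onsets under a global minimum spacing of
25 s (wider than the 20 s epoch span, so epochs never truncate or
overlap) with session-edge margins, failing hard after 10,000 rejected
draws. All randomness flows from the single session seed through
spawned child streams — one for the schedule, one per neuron — so
identical seeds give bit-identical sessions and adding neurons leaves
earlier neurons' traces unchanged.

Photometry sessions carry one deterministic kernel-shaped deflection per
event, of chosen polarity, beginning a configurable lag after onset
(defaults: negative polarity, 0.86 s — an extracellular-ATP-sensor-like
dip after feeding-bout onset). Amplitude is specified in background-SD
units via the ensemble spec, or absolutely for noiseless signals whose
background SD is zero. Behavior tables draw each mouse's paired-context
occupancy fraction as clip(Normal(bias, sd), 0, 1) — zero sd yields the
deterministic boundary cases, bias 0.5 a zero-mean CPP distribution.

What the synthetic benchmarks show: that each stage recovers the ground
truth its generator encodes, at calibrated error rates, under realistic
transient kinetics, drift, and noise. What they do not show: performance
under correlated population noise, overlapping cell footprints or
crosstalk from imperfect source extraction, behavioral label noise,
non-stationary responses, or session-to-session registration errors —
all properties of recorded data that the generator deliberately omits.

## Problem sizes and numerical choices

The validation suite runs null calibration on twenty 200-neuron,
20-trial, amplitude-zero sessions; recovery and selectivity on
200-neuron sessions with 15% responsive ensembles; decoding on ~40-trial
tensors with 50 shuffle repeats; and the projection decoder on
100-neuron high-SNR sessions — sizes chosen to put Monte Carlo error
well inside the asserted tolerances. Exact permutation enumeration is
capped at 20 trials (2^20 states). Window-boundary arithmetic carries a
10⁻⁹ s epsilon against float representation error at exact frame
boundaries. CSV trace files are written with shortest-repr floats (exact
text round trip) plus a single header comment carrying frame rate and
stage; HDF5 round trips are bit-exact. Pipeline manifests record every
parameter, seed, version, config hash, and exclusion count.
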