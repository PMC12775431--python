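# calpop

Peri-event population analysis for single-cell calcium imaging and fiber
photometry, built around the analysis chain used in cue-conditioned
feeding experiments: which prefrontal neurons respond when a mouse enters
a food-paired context or starts a feeding bout, how selective those
neurons are between two behaviors, and how well the population activity
predicts behavior.

It is aimed at labs that already run source extraction (e.g. CNMF-E) and
want a tested, scriptable implementation of everything downstream of the
extracted trace matrix.

## What it computes

Given a neuron × frame trace matrix and a table of behavioral event
onsets:

- **Normalization** — ΔF/F = (F − F₀)/F₀ with F₀ the mean baseline
  fluorescence, then per-neuron session z-scoring (population SD), so all
  downstream statistics are in standard-deviation units.
- **Peri-event epochs** — 10 s before to 10 s after each onset (600
  frames at 30 FPS; 2000 at 100 Hz photometry), with edge trials dropped
  and counted.
- **Event-activated neurons** — a neuron is activated when a within-trial
  permutation test of its event window [0, 5) s against its baseline
  window [−5, 0) s rejects at α = 0.05 *and* its mean z-scored response
  exceeds 0.2. An exact enumeration mode reproduces the full 2^M
  permutation null.
- **Selectivity** — SRI = (A − B)/(A + B) over mean responses to two
  events; SRI > 0.2 → selective for A, < −0.2 → selective for B,
  in between → activated in both.
- **Pre-/post-cells** — the same permutation machinery with windows
  [−10, −5) vs [−5, 0) and [−5, 0) vs [0, 5) around feeding-bout onsets
  and a max-z statistic, separating anticipatory from consummatory cells.
- **Population decoding** — a linear maximum-margin classifier (SVM,
  C = 1, class-balanced, fold-internal standardization) on an
  N × M × T trial tensor: 10-fold cross-validated accuracy with per-fold
  CDF, shuffled-label nulls, peri-onset decoding time courses (1-s
  windows, 5-fold), and a consecutive 50/50-split projection decoder that
  turns held-out activity into predicted event intervals.
- **Photometry & behavior** — onset latency as the first sample beyond
  the baseline mean ± 2 SD, feeding-bout summaries, CPP score
  (t_paired − t_unpaired)/(t_paired + t_unpaired), and Pearson/Spearman
  coupling of windowed neural metrics to behavior durations.
- **Synthetic sessions** — a generator with known ground truth
  (difference-of-exponentials calcium kernel, Bernoulli spiking, drift,
  noise, event schedules, designated responsive ensembles) so every stage
  is testable without recorded data.

## Worked example

```python
import calpop

cfg = calpop.SessionConfig(
    n_neurons=120, duration=1200.0, seed=42,
    ensembles=[calpop.EnsembleSpec("entry", 0.15, 2.0),
               calpop.EnsembleSpec("intake", 0.15, 2.0)],
    event_schedule=[calpop.ScheduleSpec("entry", 15, 25.0, 5.0),
                    calpop.ScheduleSpec("intake", 15, 25.0, 5.0)],
)
traces, events, truth = calpop.generate_session(cfg)
z = calpop.zscore(calpop.compute_dff(traces))
ep_entry = calpop.extract_epochs(z, events, "entry")
ep_intake = calpop.extract_epochs(z, events, "intake")
res_e = calpop.detect_activated(ep_entry, seed=1)
res_i = calpop.detect_activated(ep_intake, seed=2)
sri = calpop.compute_sri(res_e.response, res_i.response,
                         neuron_ids=res_e.neuron_ids)
union = sorted(set(res_e.activated_ids) | set(res_i.activated_ids))
tensor = calpop.build_trial_tensor(ep_entry, ep_intake, union)
dec = calpop.decode_cv(tensor, folds=10, seed=3)
null = calpop.shuffled_null(tensor, n_shuffles=100, folds=10, seed=4)
```

Output:

```
epoch: 600 frames, onset at frame 300
activated: 18/120 (entry), 19/120 (intake)
selectivity among activated: {'B_selective': 17, 'A_selective': 17, 'shared': 1, 'undefined': 1}
decoder: mean accuracy 1.000, shuffled mean 0.480, p = 0.0099
```

Reading it: two simulated ensembles (~18 neurons each) respond to chamber
entry and to feeding bouts; the detector recovers both, the SRI splits
them cleanly into entry-selective and intake-selective groups with almost
no shared cells, and the activated population decodes which behavior a
trial came from perfectly, while label shuffling stays at chance
(p = 1/101, the smallest value 100 shuffles can give).

The same stages are scriptable from the shell:

```bash
calpop simulate --config session.yaml --out session/
calpop detect --traces session/traces.h5 --events session/events.tsv \
              --label intake --out activated.tsv
calpop run --config pipeline.yaml --out results/
```

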