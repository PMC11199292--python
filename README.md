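# microtrait

Resting-state EEG **microstate stability** analysis and its association with
questionnaire traits, built for individual-differences ("neural trait")
research: from raw multichannel EEG to per-subject stability metrics, and
from those metrics to moderated trait regressions.

The scalp potential field of resting EEG does not drift continuously: it
stays quasi-stable in one topographic configuration for ~40–120 ms, then
switches abruptly to another. These configurations — *microstates*, with
four canonical classes A–D — are recovered by clustering the potential maps
at peaks of global field power (GFP, the spatial SD across electrodes).
People differ reliably in how *stable* their microstates are (long durations
/ few occurrences vs. short durations / many occurrences), and this package
implements the full chain used to test whether that stability relates to a
trait such as aggression, separately for men and women.

## What it computes

**Segmentation** (per subject): GFP-peak maps → polarity-invariant
atomize–agglomerate hierarchical clustering (AAHC) into K = 4 maps →
grand-mean clustering across subjects → assignment to the canonical A–D
order → back-fitting every sample → per-class metrics:

- *duration* (ms): mean length of a class's uninterrupted runs,
- *occurrence* (1/s): how often a class's runs begin,
- *coverage*: fraction of time occupied,
- *GEV*: GFP-weighted variance explained,
  GEV = Σₜ (GFPₜ · corr(vₜ, map_{L(t)}))² / Σₜ GFPₜ².

**Trait statistics** (per cohort): one-way random-effects ICC and a
fixed-vs-random-intercept likelihood-ratio test for the consistency of the
metrics across classes; standardized regression of the trait on mean
duration / mean occurrence; and "model 1" moderation,

y = b₀ + b₁·x + b₂·g + b₃·(x·g),

with y, x z-scored, gender g coded 0/1, simple slopes reported per gender.
The trait is the 12-item short-form Aggression Questionnaire (four subscales
× three items, 1–6 Likert, scored as plain means).

**Synthetic ground truth**: a generator renders 64-channel, 512 Hz
eyes-closed EEG whose topography at each instant is one of four planted maps
driven by an amplitude-modulated 10 Hz carrier (so polarity flips within a
state), with gamma-distributed run lengths (population mean 80 ms), plus
cohort tables in which aggression depends on duration with planted
per-gender slopes. Every stage of the pipeline is tested against this
ground truth.

## Worked example

```python
import microtrait as mt
from microtrait.preprocess import preprocess_recording

montage = mt.make_montage(64)                      # packaged 10/10 cap
sim = mt.simulate_recording(montage, record_seconds=120.0, snr=5.0, seed=7)
epochs = preprocess_recording(sim.recording, montage)
seg = mt.MicrostateSegmentation(epochs, templates=mt.canonical_maps(montage)).fit()
print(seg.summary())
```

```
Microstate segmentation
  states: A, B, C, D   epochs: 60   GEV: 0.975
  state  duration_ms  occurrence_hz  coverage     gev
      A         78.2           3.13     0.253   0.235
      B         76.8           3.08     0.251   0.234
      C         79.7           3.03     0.244   0.261
      D         79.5           3.11     0.252   0.256
  mean duration 78.6 ms, mean occurrence 3.09/s
```

The four classes each cover ~25 % of the recording, the recovered mean
duration (78.6 ms) matches the planted 80 ms law, and the four maps explain
97.5 % of the GFP-weighted variance of this noiseless-by-construction
synthetic subject.

On the trait side, with a planted slope of −0.47 in men and −0.14 in women
(N = 101; 43 men, 58 women):

```python
from microtrait.synth import CohortSimConfig, simulate_trait_table, trait_analysis_table
from microtrait.traitstats import TraitModerationModel

table = trait_analysis_table(simulate_trait_table(CohortSimConfig(seed=7, n_subjects=101))[0])
print(TraitModerationModel.from_dataframe(table).fit().summary())
```

```
aq_total ~ mean_duration_ms (moderated by gender)
  pooled:      beta = -0.401, p = 3.22e-05, R2 = 0.161, n = 101
      female:  beta = -0.179, p = 0.178 (n = 58)
        male:  beta = -0.645, p = 2.96e-06 (n = 43)
  interaction: b = -0.589, t(97) = -3.29, p = 0.00139, 95% CI [-0.944, -0.234], R2 = 0.246, dR2 = 0.084
```

A single N = 101 draw is noisy (here the male slope lands at −0.645); over
replicates the estimates are unbiased for the planted values — the test
suite and the acceptance script verify this.

The one-command demo runs everything (simulation → preprocessing →
segmentation → grand mean → trait grid):

```bash
microtrait demo --seed 1 --out results/demo
```

## Layout

- `microtrait.synth` — ground-truth EEG and cohort generators
- `microtrait.preprocess` — filtering, interpolation, epoching, artifact
  screening, average reference
- `microtrait.microstates` — GFP peaks, AAHC, grand mean, back-fitting,
  stability metrics (`MicrostateSegmentation` → results object)
- `microtrait.traitstats` — AQ scoring, ICC, model comparison, regression,
  moderation (`TraitModerationModel` → results object)
- `microtrait.io`, `microtrait.pipeline`, `microtrait.cli` — BrainVision/EDF
  I/O, orchestration, and the `microtrait` command-line tool

See `docs/methods.md` for the modelling assumptions and numerical choices.
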