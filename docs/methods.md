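# Methods

This note documents the models, conventions and numerical choices behind
`microtrait`, and what the synthetic ground truth does and does not
establish about real recordings.

## The microstate model

Resting EEG is treated as a piecewise-constant sequence of topographies:
at every sample the scalp field is one of K = 4 zero-mean maps (classes
A–D), scaled by a time-varying activation of arbitrary sign. Everything
downstream respects two symmetries of that model:

- **Polarity invariance.** A dipolar generator oscillates, so a map and its
  negation are the same microstate. Spatial similarity is therefore the
  absolute Pearson correlation across channels (equivalently |u·v| for
  zero-mean unit maps), cluster centroids are principal directions rather
  than plain means, and GEV terms are squared.
- **Scale invariance.** Stability metrics depend on which map fits best,
  never on overall amplitude; multiplying the data by any positive constant
  leaves labels and metrics unchanged (the suite asserts this bitwise).

**GFP** is the population (divide-by-C) spatial standard deviation; the
choice of population vs. sample SD is a global scale and affects nothing
downstream. GFP peaks are strict-left / non-strict-right local maxima
(`g[i-1] < g[i] >= g[i+1]`), found within each epoch independently.

**AAHC.** Clustering starts from singleton clusters of the GFP-peak maps
(weighted by their GFP) and repeatedly dissolves the cluster whose removal
costs least GEV, reassigning each orphaned map to the cluster whose centroid
it best matches in absolute correlation. A cluster's GEV contribution and
centroid are the top eigenvalue/eigenvector of its weighted scatter matrix
Σ w²uuᵀ, which makes contribution, centroid and polarity invariance
mutually consistent and lets the implementation update incrementally
(64×64 eigendecompositions per step). *Known limitation:* the procedure is
greedy. On instances whose true structure contains near-singleton clusters,
the minimum-contribution criterion dissolves exactly those clusters first
and cannot recover them; equality with exhaustive max-GEV partitioning
holds in the method's operating regime (clusters of comparable occupancy,
moderate topographic noise) and is asserted there, not for adversarial
inputs. Rank-deficient inputs (all maps identical up to sign) yield fewer
effective clusters with a warning rather than fabricated maps.

**Ordering.** Subject and grand-mean maps are labeled A–D by exhaustive
search over the 4! permutations maximizing summed absolute correlation with
template maps (ties → lexicographically smallest permutation). The packaged
templates are four idealized dipolar fields on the montage sphere: two
mirrored frontal–posterior diagonals (A, B), an anterior–posterior gradient
(C), and a fronto-central focal field (D); their pairwise |corr| on the
64-channel cap is ≤ 0.5.

**Back-fitting.** GFP peaks take the best-matching class; every other
sample inherits the label of its nearest peak within the epoch (midpoint
rule, ties to the earlier peak). No temporal smoothing and no minimum
segment length are imposed. An epoch without any interior GFP peak falls
back to per-sample best fit and is flagged.

**Metrics.** A run is a maximal same-label span within one 2-s epoch; runs
never merge across epochs because epochs are discontinuous after artifact
rejection. By default, runs touching an epoch edge are excluded from
duration averages (they are right/left-censored), and occurrences count
runs starting strictly inside an epoch. The alternative policy (all runs)
is available via `exclude_truncated=False` and is the one under which the
accounting identity Σₖ durationₖ·occurrenceₖ = 1000·Σₖ coverageₖ holds
exactly. Mean duration and mean occurrence are unweighted means over the
four classes (a class that never occurs is excluded from the duration mean
and flagged). GEV uses all samples, GFP-squared-weighted.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass at 1.5–20 Hz
plus a 2 Hz-wide IIR notch at 60 Hz; the narrow notch gets extended reflect
padding because its impulse response outlasts scipy's default. Bad channels
are interpolated from their 4 nearest neighbours (great-circle distance on
the montage sphere); the automatic criterion flags flatlines (SD < 1e-6 µV)
and channels whose log-variance exceeds the median by > 8 robust MADs —
one-sided, because genuinely quiet channels near the zero line of a dipolar
topography are healthy. Eyes-closed spans are cut into non-overlapping 2-s
epochs (remainders dropped); any epoch containing a sample beyond ±100 µV
is rejected whole; finally the common average reference is applied
(idempotently). Independent-component ocular cleaning is a human-in-the-loop
step and is deliberately not implemented; externally cleaned data can be
fed in directly.

## Synthetic ground truth

The generator emulates the study conditions the package is designed for:
64-channel (10/10 cap), 512 Hz, eyes-closed recordings; four planted maps;
semi-Markov state sequence with gamma run lengths (discretized to ≥ 1
sample; population mean 80 ms — the centre of the typical 40–120 ms range —
between-subject SD 15 ms); a 10 Hz amplitude-modulated sinusoidal carrier
(alpha band, eyes closed) whose sign flips within each state; spatially
white Gaussian noise scaled to an exact signal-to-noise RMS ratio (default
5); cohorts of N = 101 with 58 women / 43 men.

State **transitions align to carrier zero crossings** by default — the
moments of minimal field power, which is where topographic switches are
observed in real data. This makes the nearest-peak back-fitting rule exact
up to the (physically label-free) zero-amplitude boundary samples, at the
cost of quantizing run lengths to half-carrier periods (~50 ms at 10 Hz);
recovery tests therefore compare against the *realized* run lengths, and
`snap_to_carrier=False` gives unquantized sequences for law-level tests.

Trait side: aggression is planted as y = β_g·z(duration) + ε with
gender-specific β (defaults −0.47 men / −0.14 women) and residual SD
√(1−β²), so the planted β *is* the within-gender standardized slope. The
latent score is mapped affinely to the 1–6 AQ range (mean 3.5, SD 0.8,
rare tails clipped) and expanded into 12 integer items whose mean matches
the target within 1/24. In table-only cohorts the per-class duration jitter
SD defaults to (between-subject SD)/√3, planting a type-consistency ICC of
0.75; per-class occurrences follow the semi-Markov identity
occurrence = coverage·1000/duration with coverage 1/4.

What the synthetic data does **not** contain: ocular/muscle artifacts
beyond injected amplitude spikes, 1/f background, channel-correlated noise
(available as an option but off by default in tests), non-stationary state
prevalence, or imperfectly dipolar maps. Passing tests therefore establish
the correctness of the algorithms under the stated model, not the
robustness of microstate estimates to real-world artifact structure; GEV
on synthetic subjects (~97 %) is accordingly higher than the ~75 % typical
of real recordings.

## Statistics

- **ICC**: one-way random-effects consistency form, σ²ᵦ/(σ²ᵦ+σ²w), with
  variance components from a REML random-intercept fit (statsmodels
  MixedLM); negative estimates truncate at the boundary. Invariant to
  affine rescaling of the metric.
- **Model comparison**: OLS with class as a categorical fixed effect vs.
  the same model plus a subject random intercept, both by ML; LRT referred
  to χ²(1) — conservative at the variance boundary (the 50:50 χ²₀/χ²₁
  mixture is available via `boundary_mixture=True`).
- **Regression**: OLS on z-scored (ddof = 1) variables, so β equals the
  Pearson correlation and R² = β² exactly.
- **Moderation**: y and x z-scored over the whole sample *before* forming
  the interaction; the two-level moderator coded 0/1 with levels in sorted
  order. Reported: interaction coefficient with t (df = n−4), two-sided p,
  95 % CI, R², ΔR² vs. the no-interaction model, and within-gender
  standardized simple slopes (the raw-scale interaction coefficient is also
  emitted, as the standardized-vs-raw convention differs across software).
  A subgroup with a constant outcome yields NaN simple slopes rather than
  aborting the grid.
- **Multiple testing**: none — every cell of the outcome × predictor grid
  is a two-sided test at α = 0.05, stated in the output metadata.
- Missing or out-of-range AQ items raise; subjects are excluded by the
  caller, never imputed.

## Problem sizes and tolerances

Monte-Carlo checks use sizes chosen to make their tolerances comfortable:
slope-recovery bias (< 0.03) over 1000 replicates of N = 101; moderation
type-I error in [0.03, 0.07] over 2000 null replicates; mixed-model null
calibration over 300 replicates (bound 0.06, the χ²(1) reference being
conservative); ICC recovery ±0.1 at N = 100; map recovery ≥ 0.95 and
duration recovery ±15 % on cohorts of five 120-s subjects at SNR 5. The
acceptance script averages slope estimates over 200 replicate cohorts and
ICCs over 25. Numerical ties: AAHC atomization and reassignment take the
first index; map sorting takes the lexicographically smallest permutation;
eigenvector signs are fixed by making the largest-magnitude component
positive. All randomness flows from explicit integer seeds through
numpy Generators; cohort subjects use spawned child seeds so any subject
can be re-rendered in isolation.
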