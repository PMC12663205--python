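# Methods

`dualeeg` implements a complete window-level EEG classification pipeline
for two-group (schizophrenia vs healthy control) studies: preprocessing,
dual feature extraction, a two-branch CNN–BiLSTM classifier with
baselines, wrapper feature selection, and stratified cross-validated
evaluation — together with a synthetic cohort generator so that the whole
chain is testable without clinical data.

## Pipeline model

A recording is a `channels × samples` array at sampling rate `fs`
(default 500 Hz) over the 31-electrode 10-20 montage (FP1 … O2; a 32nd
ground channel, when present in a file, is dropped by name before
analysis). The processing chain is:

1. **Filtering.** Zero-phase 4th-order Butterworth band-pass (default
   0.5–45 Hz) applied forward–backward to the continuous recording, with
   an optional IIR notch (Q = 30) for power-line noise. Defaults are
   chosen for a 500 Hz signal whose acquisition chain already band-limits
   to ≈0.16–30 Hz and notches 45–55 Hz; every edge is configurable.
   Filtering precedes segmentation so window edges see no transients.
2. **Segmentation.** Non-overlapping 25-s windows, half-open sample
   ranges `[k·T_w, (k+1)·T_w)` with `T_w = round(fs · 25)` (12,500 at
   500 Hz); the trailing remainder is discarded. A 600-s recording yields
   24 windows; 0-based window indices.
3. **Artifact rejection.** A window is rejected iff any channel's
   absolute amplitude exceeds `threshold × SD` (default 8 SD) of that
   channel over the subject's whole recording. This is an automatic
   amplitude-threshold screen for gross excursions, not a substitute for
   ICA-based ocular/muscle artifact correction; it catches the spike-like
   contamination the simulator can inject and nothing subtler.
4. **Normalization.** Per-channel, per-window z-scoring with the
   population (1/N) standard deviation, matching the 1/T_w variance
   definition used by the features. Zero-variance channels map to
   all-zeros with a warning (shapes must stay fixed for the network
   inputs). Normalization is idempotent.

## Features

**Temporal (per channel):** variance `(1/T_w)Σ(x−μ)²`; absolute energy
`Σ|x|²`; an autoregressive summary — AR(p) fitted by Yule–Walker (p = 2
by default) and collapsed to the first coefficient φ₁, since the feature
grid allots one column to "auto-regression" and φ₁ is the dominant
spectral-shape summary (the order and the choice of scalar are
configurable); Shannon entropy of a K-bin equal-width amplitude histogram
(K = 64) in bits — fixed-width binning replaces a "unique values"
probability rule that degenerates to log₂N on continuous data; Hjorth
mobility `sqrt(Var(Δx)/Var(x))` with the length-(N−1) forward difference.
Default matrix: 31 channels × {variance, energy, AR, mobility} = 31×4.

Note an interaction: on z-scored windows variance ≈ 1 and energy ≈ T_w
identically, so these two columns carry no between-group information
post-normalization. They are still computed as configured (the grid is
the contract); callers who want amplitude-sensitive features can extract
them from pre-normalization windows.

**Functional (per unordered channel pair, canonical lexicographic order;
465 pairs for 31 channels):** Pearson correlation; magnitude-squared
coherence `|S_ij|²/(S_ii·S_jj)` from Welch spectra (2-s Hann segments,
50 % overlap) averaged over 1–30 Hz to a scalar — the band matches the
acquisition band-pass and is configurable; phase locking value
`|mean exp(iΔφ)|`; and the phase lag index. Instantaneous phase is the
argument of the analytic signal (Hilbert transform) of the full 25-s
window, without sub-band decomposition. Default matrix:
{PLI, PLV, Pearson} = 465×3.

**PLI variants.** Three forms are provided:
`standard = |mean sign(sin Δφ)|` (the literature definition, in [0,1]);
`wpli = |mean sin Δφ| / mean |sin Δφ|` (weighted PLI, in [0,1]); and
`printed = |mean sign(sin Δφ)| / mean |sin Δφ|`, a ratio form that shares
wPLI's denominator but keeps the signed-count numerator. The printed form
exceeds 1 for constant small nonzero lags (numerator 1, denominator
|sin Δφ| < 1), so it is not a bounded synchronization index; it is
nevertheless the default because it is the formula this package's feature
set is specified by, with the other two a one-flag switch. All variants
return 0 when the denominator vanishes (zero-lag locking), and all are
symmetric in the pair.

## Classifiers

The **hybrid** network takes the two matrices per window:

* functional branch: input `(pairs × F_f × 1)` → Conv(8, 3×3, same) → BN
  → ReLU → Conv(16, 3×3, same) → BN → ReLU → flatten (no pooling);
* temporal branch: channels as the 31-step sequence of F_t-vectors →
  BiLSTM(100) → BN (per feature) → ReLU → BiLSTM(50, final states);
* concatenation → fully connected 64 + ReLU → 2-way softmax.

Training: Adam, lr 1e-3 halved every 20 epochs, mini-batch 32, up to 70
epochs, early stopping on a stratified 10 % validation split with
patience 10 (best weights restored). The head width (64), the validation
split and the step-decay schedule are this package's choices where only
"Schedule"/"Early stopping" is specified upstream. The branches accept
any consistent `(pairs × F_f, channels × F_t)` shapes, not just 465×3 /
31×4.

All network layers (conv/BN/ReLU/dropout/LSTM/dense, Adam,
softmax-cross-entropy) are implemented directly on numpy with
hand-derived backpropagation; every layer's backward pass is verified
against central-difference numeric gradients in the test suite. Training
is exactly reproducible from `(spec, data, seed)`.

Baselines: KNN (k = 25, city-block, brute-force search, no
standardization) and an RBF-kernel SVM with standardization, automatic
kernel scale and 0.05 outlier fraction — realized as ν-SVM with ν = 0.05,
reading the outlier fraction as the ν bound on margin errors — via
scikit-learn; and a plain CNN (3 conv blocks of 8/16/32 3×3 filters, BN,
ReLU, dropout 0.3, Adam 1e-3, up to 64 epochs) on a single matrix input.
KNN scores are neighbor vote fractions; SVM scores a logistic map of the
decision margin; schizophrenia is the positive class everywhere.

## Feature-combination search

A wrapper search over the 4-functional × 5-temporal pools: (1) score each
single functional feature with all temporal features; (2) greedily grow
the functional subset from the best single, keeping a step only if the
primary metric (accuracy; ties by AUC, then smaller subsets) does not
decrease; (3) under the chosen functional subset, greedily grow temporal
subsets from each single start. Every combination is evaluated at most
once (subsets are canonicalized), evaluator failures are recorded and
skipped, and an exhaustive mode scores all (2⁴−1)(2⁵−1) = 465 subset
pairs. Greedy search can miss optima that are not on its growth path;
that is inherent to the procedure, and the exhaustive flag exists for
small pools.

## Evaluation

Stratified k-fold cross-validation (default k = 5) at the window level,
with an optional subject-level mode (all windows of a subject in one
fold). Window-level splitting is the default evaluation unit, but note it
lets a model see other windows of a test subject during training;
subject-level results are the honest generalization estimate, and both
are exposed. Confusion counts at threshold 0.5; accuracy, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), with empty-denominator metrics
reported as undefined (None), never 0. ROC sweeps all distinct score
thresholds (ties grouped) and AUC is trapezoidal; it equals the
normalized Mann–Whitney U, which the tests verify against a brute-force
pairwise count.

## Synthetic cohorts

The generator emulates the *structure* of a two-group task-EEG study —
31 channels, 500 Hz, 25-s windows, 26/25 subjects — with controllable
group effects. Each subject's signal is

```
x_c(t) = A · ( w · Σ_k s_k(t − c·τ) + n_pink,c(t) + n_white,c(t) )
```

where the `s_k` are K = 3 shared unit-variance narrow-band sources at
6, 10 and 20 Hz (band-passed white noise, ±7.5 % relative bandwidth, so
phase drifts realistically while staying shared), mixed into channel `c`
with coupling weight `w ∈ [0,1]` and a channel-proportional circular lag
`c·τ` (τ = 5 ms by default — nonzero so that PLI, blind to zero-lag
coupling, sees the effect); the noise is 80 % pink (1/f^β, β = 1, built
by frequency-domain shaping) plus 20 % white, scaled so full-strength
oscillatory power over noise power equals `snr` (default 1); `A` is the
amplitude multiplier. Coupling moves PLV/PLI/coherence/Pearson; `A`
moves variance/energy and provably nothing else (same-seed signals are
exactly proportional).

Study conditions: the **strong** effect sets coupling 0.7 (SZ) vs 0.3
(HC) and amplitude 1.2 vs 1.0 — a clearly separable cohort; the **null**
condition uses identical parameters for both groups — a chance-level
control. Everything is deterministic given the cohort seed (subject
seeds are SeedSequence-derived).

What the simulator does *not* model: volume conduction and a common
reference (which inflate zero-lag synchrony in real EEG), ocular/muscle
artifacts beyond optional amplitude spikes, event-locked structure,
non-stationarity across blocks, and inter-subject variability beyond the
random source phases. Passing recovery tests therefore demonstrates that
the pipeline's machinery is correct and sensitive to the effects it
claims to measure — not that comparable accuracy would be reached on
clinical recordings.

## Problem sizes and numerics

The parameter-recovery runs use 150-s recordings (6 windows per subject;
306 windows over the 51-subject strong cohort, 120 over a 20-subject null
cohort) — the package's chosen desk-scale configuration; all counts are
configurable up to the full 600-s design. Tolerances: z-scoring to 1e-9
on means/SDs; brute-force feature agreement to 1e-10; amplitude
invariance exact up to float rounding (1e-12) for phase/correlation
features and 1e-9 for coherence; AUC–U agreement to 1e-12. Degenerate
inputs (constant channels) map to zeros/0-values with warnings rather
than exceptions wherever a shape contract must survive; genuinely
unusable configurations (invalid bands, empty pools, single-class
training sets, mixed EDF sampling rates) raise with the offending field
named.

## Known limitations

* The printed-ratio PLI is unbounded above; cross-study comparability
  requires the `standard` or `wpli` variant.
* Window-level CV leaks subject identity; use `subject_level=True` for
  generalization claims.
* The EDF writer covers the plain 16-bit EDF subset used here (1-s
  records, one sampling rate, µV units) — not EDF+ annotations.
* The numpy network trains on one CPU; it is sized for feature-matrix
  inputs (hundreds of rows), not raw-EEG end-to-end learning.
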