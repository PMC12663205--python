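# dualeeg

EEG-based schizophrenia-vs-control classification from **dual feature
matrices**: per-window temporal features (one row per channel) and
functional-connectivity features (one row per channel pair) feed a
two-branch CNN–BiLSTM network, evaluated with stratified k-fold
cross-validation against KNN/SVM/CNN baselines. A built-in two-group EEG
simulator makes the entire pipeline runnable and testable without any
clinical data.

Intended users: researchers in EEG-based psychiatric classification who
want a reproducible, fully inspectable reference pipeline — from raw
multichannel signals to cross-validated metrics — with every formula
implemented exactly as written and verified against brute-force oracles.

## The method

A recording (31 channels of the 10-20 montage, 500 Hz) is band-pass
filtered (zero-phase Butterworth), cut into non-overlapping 25-s windows
(`T_w = 12,500` samples), screened for amplitude artifacts, and z-scored
per channel per window, `X_w^norm = (X_w − μ_w)/σ_w`.

From each window two matrices are extracted:

* **temporal, 31 × 4** — per channel: variance `(1/T_w)Σ(x−μ)²`,
  absolute energy `Σ|x|²`, Yule–Walker AR coefficient φ₁, Hjorth
  mobility `√(Var(Δx)/Var(x))` (Shannon entropy of the binned amplitude
  distribution is also available);
* **functional, 465 × 3** — per channel pair: phase lag index (PLI),
  phase locking value `PLV = (1/T_w)|Σ_t e^{i(φ_i−φ_j)}|`, and Pearson
  correlation (band-averaged magnitude-squared coherence
  `|S_ij|²/(S_ii S_jj)` is also available). Phase is the angle of the
  analytic (Hilbert) signal.

The classifier runs the functional matrix through a small CNN
(conv 8 → conv 16, 3×3, batch-norm, ReLU, flatten) and the temporal
matrix through a stacked bidirectional LSTM (100 → 50 units, channels as
the sequence axis), concatenates both embeddings, and finishes with a
64-unit dense layer and a 2-way softmax. Training uses Adam (1e-3, step
decay), mini-batches of 32, and early stopping. The networks are
implemented directly on numpy with hand-derived, gradient-checked
backpropagation. A greedy wrapper search selects feature combinations
from the 4 functional × 5 temporal pools (465 possible subset pairs).

## Worked example

```python
import dualeeg as dg

cfg = dg.CohortConfig(n_subjects_per_group=(6, 6), n_channels=8,
                      fs=250.0, duration_seconds=100.0, seed=42)
params_sz, params_hc = dg.strong_effect()   # coupling 0.7 vs 0.3
cohort = dg.generate_cohort(params_sz, params_hc, cfg)

dataset = dg.build_dataset(cohort)
print(f"{len(dataset)} windows, temporal {dataset.temporal_array().shape[1:]},"
      f" functional {dataset.functional_array().shape[1:]}")

report = dg.cross_validate(dg.ModelSpec(kind="hybrid", seed=0),
                           dataset, k=5, seed=0)
m = report.summary()
print(f"accuracy {m['accuracy']:.3f}  sensitivity {m['sensitivity']:.3f}  "
      f"specificity {m['specificity']:.3f}  AUC {m['auc']:.3f}")
print(f"pooled confusion: TP={report.pooled_counts.tp} "
      f"FP={report.pooled_counts.fp} TN={report.pooled_counts.tn} "
      f"FN={report.pooled_counts.fn}")
```

Output:

```
48 windows, temporal (8, 4), functional (28, 3)
accuracy 0.900  sensitivity 0.800  specificity 1.000  AUC 1.000
pooled confusion: TP=19 FP=0 TN=24 FN=5
```

Twelve simulated subjects (six per group) yield 48 windows; on this
small, strongly coupled cohort the hybrid classifier recovers the group
difference almost perfectly — fold-mean accuracy 0.90, pooled AUC 1.0,
with the five errors all missed schizophrenia windows. `sensitivity` is
the schizophrenia detection rate and `specificity` the healthy
recognition rate (schizophrenia is the positive class).

The same pipeline is available from the shell:

```bash
dualeeg simulate --seed 1 --out cohort/          # EDF files + manifest
dualeeg extract  --cohort cohort/ --out features/
dualeeg evaluate --features features/ --out report/
dualeeg search   --features features/ --out search/
```

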