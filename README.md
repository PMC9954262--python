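# vmdp300

Single-trial classification of P300 vs non-P300 EEG epochs by **variational
mode decomposition (VMD)**, a 30-feature battery, SMOTE class balancing and
cross-validated machine-learning classifiers — aimed at oddball-paradigm
brain–computer interfaces for users whose P300 is attenuated (< 2.5 µV) and
late (> 400 ms), as in autism-spectrum recordings.

## Who this is for

EEG/BCI researchers who want a reproducible, fully scriptable implementation
of the VMD-based P300 detection pipeline: each 1-second channel-epoch
(250 samples at 250 Hz) is decomposed into M = 5 band-limited AM-FM modes,
each mode is summarised by 30 time/frequency features, the 1:7
target/non-target imbalance is corrected by SMOTE, and bagged trees, a
fine-Gaussian-kernel SVM and a wide shallow neural network are compared
mode-by-mode under stratified 10-fold cross-validation with the full
confusion-matrix battery (accuracy, sensitivity, specificity, precision,
F1, NPV, ROC AUC).

A bundled synthetic oddball-ERP generator reproduces the multisession
block/run/event bookkeeping of public P300 benchmarks (7 sessions ×
(20 calibration + 50 online) blocks × 8 objects, one pseudorandom target per
block → 1/8 target probability; 3,920 block-averaged epochs and a
31,360 × 250 channel-epoch matrix per subject), so every stage runs and is
tested without downloading any data.

## The core decomposition

VMD splits x(t) into modes s_m(t) with center frequencies ω_m by minimising
the summed analytic-spectrum bandwidth subject to reconstruction,

    min Σ_m ‖∂_t[(δ(t) + j/πt) * s_m(t)] e^{−jω_m t}‖₂²   s.t.  Σ_m s_m = x,

solved by ADMM in the spectral domain: a Wiener-filter mode update
ŝ_m ← (x̂ − Σ_{i≠m} ŝ_i + λ̂/2)/(1 + 2α(ω − ω_m)²), a power-weighted
center-frequency update, and dual ascent λ̂ ← λ̂ + τ(x̂ − Σ ŝ_m), iterated to
relative tolerance ε. Defaults α = 1000, τ = 0.01, ε = 0.005, M = 5; modes
are returned in descending-frequency order, so mode 5 is the low-frequency
component where the P300 lives. See `docs/methods.md` for every numerical
convention.

## Worked example

```python
from vmdp300 import (SimConfig, VMDConfig, SmoteConfig, simulate_epochset,
                     channel_normalize, flatten, smote_balance,
                     default_specs, evaluate_pipeline)
from vmdp300.pipeline import mode_feature_tables

# one reduced synthetic subject: 1 session, 15 blocks, 120 averaged epochs
cfg = SimConfig(n_sessions=1, calib_blocks=5, online_blocks=10, seed=1)
flat = flatten(channel_normalize(simulate_epochset(cfg)))
print(flat.rows.shape)                    # (960, 250)

tables = mode_feature_tables(flat.rows, flat.row_labels, VMDConfig(), fs=250.0)
balanced = {m: smote_balance(t, SmoteConfig(seed=1)) for m, t in tables.items()}
print(balanced[5].values.shape)           # (1680, 30)

report = evaluate_pipeline(balanced, default_specs(1), k=10, seed=1)
print(report.best_mode, report.best_family)
print(report.cell(5, "svm")[["accuracy", "f1", "auc"]])
```

Output:

```
(960, 250)
(1680, 30)
5 svm
accuracy    94.821429
f1          94.959277
auc         98.431122
```

Interpretation: 120 block-averaged epochs over 8 channels give 960 rows;
SMOTE doubles the 840-row majority to a balanced 1,680 × 30 table; the best
(mode, classifier) cell is the lowest-frequency mode with the Gaussian-kernel
SVM — the low-frequency mode carries the P300 — at ~95 % cross-validated
accuracy on this synthetic subject. (Scores on the bundled generator are
optimistic in absolute terms because, following the reproduced protocol,
SMOTE and normalisation run before fold splitting; see `docs/methods.md`.)

The same chain is available from a shell:

```sh
vmdp300 run-all --sessions 1 --seed 1 --out run/
vmdp300 simulate --subjects 1 --sessions 1 --seed 7 --out sim/
vmdp300 decompose --alpha 1000 --tau 0.01 --tol 0.005 --modes 5 \
        --in flat.csv --out modes/
```

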