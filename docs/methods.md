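# Methods

## Problem

Detecting the P300 event-related potential on a per-stimulus basis is the
core of an oddball-paradigm brain–computer interface. In autism-spectrum
recordings the component is attenuated (below ~2.5 µV) and late (after
~400 ms), so single-trial detection needs both a signal representation that
isolates the low-frequency band where the P300 lives and a classifier robust
to heavy class imbalance (one target among eight stimulus objects).

This package implements that pipeline: adaptive decomposition of every
channel-epoch into five band-limited modes, a 30-feature battery per mode,
SMOTE class balancing, and a three-family classifier comparison under
stratified 10-fold cross-validation — together with a synthetic oddball-EEG
generator so the whole chain runs and is tested without any external
recordings.

## Variational mode decomposition

Each 250-sample channel-epoch x(t) is decomposed into M = 5 AM-FM modes
s_m(t) with center frequencies ω_m by minimising the summed bandwidth of the
modes' analytic spectra subject to soft reconstruction. The augmented
Lagrangian is solved by ADMM entirely in the spectral domain on the positive
half-axis:

- mode update (Wiener form):
  ŝ_m ← (x̂ − Σ_{i<m} ŝ_i^{new} − Σ_{i>m} ŝ_i^{old} + λ̂/2) / (1 + 2α(ω − ω_m)²)
- center-frequency update: ω_m ← ∫ω|ŝ_m|²dω / ∫|ŝ_m|²dω
- dual ascent: λ̂ ← λ̂ + τ(x̂ − Σ ŝ_m)

iterated until Σ_m ‖ŝ_m^{n+1} − ŝ_m^n‖²/‖ŝ_m^n‖² < ε. The stopping rule is
evaluated on the half-axis spectra; by Parseval this equals the time-domain
ratio up to a common weighting that cancels mode-wise, and it keeps the loop
free of inverse transforms.

Defaults: α = 1000 (bandwidth penalty), τ = 0.01 (dual step), ε = 0.005,
M = 5, max 500 iterations. Numerical choices:

- **Boundary**: the signal is mirror-extended by half its length on each
  side before the FFT and cropped after inversion, suppressing edge ringing;
  `boundary="none"` disables it.
- **ω initialisation**: evenly spaced on (0, 0.5] cycles/sample by default;
  `zeros` and seeded `random` policies available. With the default policy the
  solver is fully deterministic.
- **Mode ordering**: output sorted by descending center frequency, so mode 5
  is always the lowest-frequency component. With 2–30 Hz EEG input the five
  centers settle near 22, 13, 8, 5 and 3 Hz — roughly the classical beta,
  low-beta, alpha, theta and delta bands — without any band constraint.
- **Degenerate modes**: a mode whose spectrum collapses to zero keeps its
  previous ω (logged); zero-norm modes are excluded from the convergence sum.
- Non-convergence within the iteration cap returns the partial result with a
  `VMDConvergenceWarning`, never silently.

`vmd_decompose_matrix` batches the same arithmetic across rows (chunked at
4096 rows) and matches the scalar path to floating-point accuracy; rows exit
the iteration individually when they meet the tolerance.

## Preprocessing

50 Hz zero-phase IIR notch (quality factor 30) and 2–30 Hz zero-phase
4th-order Butterworth band-pass, applied forward–backward; epochs are the
half-open [0, 1000) ms window from stimulus onset (250 samples at 250 Hz,
the 200 ms pre-stimulus baseline dropped); events sharing a stimulus object
within a block are averaged sample-wise; channels are z-scored with moments
pooled over all epochs and samples of the channel. The 3-D epoch array is
flattened epoch-major/channel-minor into a rows × 250 matrix — the fixed row
order matters because SMOTE and CV folds act on row identity. Normalisation
is deliberately computed over the full concatenated data (train and test
together), matching the pipeline order this package reproduces; the
train/test leakage this implies is a property of that protocol, not an
accident (see Limitations).

## Feature battery

Thirty descriptors per mode signal, in a fixed canonical order. The list
intentionally contains two skewness columns and two Shannon-type entropies;
the battery is defined by its column list, not by mathematical independence.
Conventions chosen here: amplitude-histogram entropies use 16 equal-width
bins over [min, max]; Rényi and Tsallis orders are q = 2; `entropy` is the
amplitude-histogram Shannon entropy while `shannon_entropy` is the entropy of
the normalised Welch spectral power distribution, keeping the two columns
distinct; kurtosis is Pearson (non-excess) and skewness the biased
Fisher–Pearson moment coefficient; log-energy entropy guards the logarithm
with 1e-12; Welch PSDs use 128-sample Hann segments at 50 % overlap; band
powers integrate the PSD over delta (1–3), theta (4–7), alpha (8–12), beta
(13–30) and gamma (30–100, truncated at Nyquist) Hz. Zero-variance signals
define the normalised differences, Hjorth mobility/complexity, histogram
entropies and the log-root-sum-of-sequential-variation as 0 so every vector
stays finite. The gamma band is near-zero after the 2–30 Hz band-pass and is
retained for list fidelity only.

Kruskal–Wallis H (rank-based, tie-corrected, χ² p-value) is computed per
feature column as a screening report; no feature is dropped by it.

## SMOTE balancing

With one target in eight objects the flattened table is 7:1 imbalanced.
Synthetic minority rows are x + u·(x_nn − x), u ~ U(0,1), with x_nn one of
the k = 5 nearest minority neighbours by Euclidean distance on the raw
feature values (features enter SMOTE exactly as extracted). Neighbour ties
break by row index, so a seeded run is bit-reproducible. Balancing is
applied to the whole table before fold splitting — again the reproduced
protocol's order; interpolated rows therefore share information across CV
folds, which inflates absolute cross-validated scores (see Limitations).

## Classifiers and evaluation

- **EBT** — 30 bagged decision trees (bootstrap size = training size, Gini
  splits, split cap defaulting to n_train − 1, i.e. unrestricted), scored by
  averaged leaf probabilities (vote fraction for pure leaves).
- **SVM (fine Gaussian)** — K(a,b) = exp(−‖a−b‖²/(2ρ²)) with ρ = 1.4, box
  constraint 1, standardised inputs; decision values as scores. The kernel
  scale enters sklearn as gamma = 1/(2ρ²) following this kernel form.
- **ANN** — one hidden layer of 100 ReLU units (a "wide" net: more hidden
  units than inputs), sigmoid output, no regularisation, Adam with an
  iteration cap of 1000, standardised inputs. The one-vs-one multiclass
  setting sometimes quoted with such configurations is vacuous for two
  classes and is ignored.

Folds are stratified by class (necessary after SMOTE for stable fold
composition), k = 10, shuffled with the run seed. Per fold the full
confusion battery is reported: accuracy, sensitivity, specificity,
precision, F1, NPV (all %), plus trapezoidal ROC AUC (equal to the
Mann–Whitney pairwise statistic). Undefined metrics (zero denominator)
are NaN, never 0. The best (mode, classifier) cell is chosen by mean
accuracy, ties broken by mean AUC then lower mode index. EBT and SVM cells
are seed-deterministic; the ANN is stochastic in its weight initialisation
and mini-batching and is controlled by the same seed.

## Synthetic data generator

The generator emulates the structure of multisession oddball P300
recordings from an 8-channel parietal/central montage: per subject,
7 sessions × (20 calibration + 50 online) blocks × 8 objects; calibration
blocks have 10 runs, online blocks draw 3–10 runs per block; each run
flashes every object once, and one pseudorandom object per block is the
target (exact 1/8 target event probability). Block averaging therefore
yields 3,920 averaged epochs per subject and a 31,360 × 250 flat matrix.

Each event is 1.2 s (−200…1000 ms). Background noise is band-limited
(2–30 Hz) 1/f-amplitude noise scaled to an exact RMS, plus an alpha-band
(8–12 Hz) sinusoid of random frequency and phase per event and channel.
Target events add a half-cosine (Hann) bump of default amplitude 2.0 µV,
latency 450 ms and width 300 ms — inside the attenuated/late range reported
for ASD — scaled per channel by a parietal-maximal topography (Pz = 1.0,
CPz = 0.8, POz = 0.7, C3/C4 = 0.3, …). Over 95 % of the template's energy
lies below 8 Hz, so after decomposition the class-separating energy
concentrates in the lowest-frequency mode by construction.

Noise defaults (pink RMS 1.0 µV, alpha amplitude 0.5 µV) were fixed once so
that single-row class separability is moderate — well away from both chance
and ceiling — making the pipeline's comparative properties (mode ranking,
permutation-null margins) non-degenerate. They model the *effective*
post-averaging SNR of a cooperative recording rather than raw scalp-EEG
amplitudes; absolute accuracy numbers on this generator are not predictions
for any real dataset.

What the generator does **not** model: overlapping 200 ms inter-stimulus
streams (events are independent segments; block averaging makes this
adequate for testing), eye/muscle artifacts, volume-conduction lead fields,
inter-subject variability, non-stationarity across sessions. Passing tests
therefore demonstrate correctness of the pipeline's computations and the
qualitative low-frequency-mode finding, not clinical performance.

## Problem sizes used in tests and the acceptance script

Structural counts are computed at the full per-subject scale (3,920 epochs,
31,360 × 250, balanced 54,880 × 30). The cross-validated (mode × classifier)
grid is computed on reduced subjects of 1 session × 15 blocks (120 averaged
epochs, 960 rows, 1,680 after balancing) — chosen as the smallest scale at
which the mode ranking is stable across seeds — with three independent
subjects (seeds) for the headline property.

## Known limitations

- SMOTE before fold splitting and whole-data normalisation both leak
  information across CV folds; absolute scores are optimistic. The library
  exposes the stages separately, so a leakage-safe variant (normalise and
  balance within training folds only) is a few lines for the user; the
  bundled protocol reproduces the published order deliberately.
- The decomposition is run unconstrained with M = 5 and descending-frequency
  ordering; modes are not forced onto the canonical EEG bands, they settle
  there for band-passed EEG-like input.
- The duplicate feature columns (two skewness entries; first difference =
  mean curve length under these conventions) are kept by design; tree and
  kernel methods are insensitive to duplicated columns, and the 30-column
  contract stays intact.
- Per-row VMD treats each channel-epoch independently; no joint
  multichannel decomposition is attempted.
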