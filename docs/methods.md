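# Methods

## Problem and pipeline

`gaitfuse` recognises four lower-limb locomotion modes — running, level
walking, stair ascent and ramp ascent — from two wearable modalities
recorded simultaneously: four-channel surface EMG (rectus femoris RF,
tibialis anterior TA, biceps femoris BF, gastrocnemius GA) at 2000 Hz and a
three-channel IMU (Y-axis acceleration, angular velocity and orientation
angle) at 200 Hz.  The pipeline is

1. **conditioning** — zero-phase 4th-order Butterworth filters (EMG
   band-pass 20–500 Hz, IMU low-pass 10 Hz), cubic-spline upsampling of the
   IMU stream to 2000 Hz, segmentation into paired 0.3-s windows
   (4×600 EMG, 3×600 IMU), stratified 7:1:2 train/validation/test split;
2. **feature extraction** — either a hand-designed time/frequency feature
   bank (MAV, VAR, RMS, ZC, WAMP, WL, MDF, MNP) or a learned dual-stream
   CNN whose output layer is removed after training;
3. **feature selection** — multi-class ReliefF weighting with a 0.1
   threshold on the learned features;
4. **classification** — RBF-SVM, KNN, decision tree and random forest under
   seeded stratified five-fold cross-validation.

## Dual-stream CNN

Each modality has its own branch: a window is treated as a one-plane image
and passed through conv 1×101 (depth 16) → max-pool 1×10 → conv 3×11 for
EMG / 2×11 for IMU (depth 8) → max-pool 2×2, all convolutions valid
(no padding) with stride 1 and ReLU activations.  Both branches flatten to
160; concatenation gives the 320-wide convergence layer, a fully connected
layer maps it to 32, and a softmax output gives the four class
probabilities.  Valid stride-1 convolution with non-overlapping pooling is
the unique standard choice that reproduces the 600→500→50→40→20 width chain
and the 160/320/32 feature widths; the architecture tests include a
negative control showing that any padding or stride change breaks this
identity.

Training uses minibatches of 64, Adam at learning rate 0.001 and
cross-entropy loss.  The iteration count is interpreted as epochs and is
configurable; the experiments in this repository use 24–30 epochs, which is
where validation accuracy plateaus on the synthetic task at the dataset
sizes used (the canonical setting of 200 epochs remains the constructor
default for `TrainConfig`).  Weights are initialised with fan-in-scaled
uniform draws from a single seeded generator, and batch order is drawn from
the same generator, so training is bit-reproducible on a fixed seed.  The
network is implemented directly on NumPy: convolutions are im2col + BLAS
matmul, pooling keeps argmax indices for backprop, and gradients were
verified against central finite differences in the test suite.

Feature extraction removes the output layer.  Two taps are exposed:
`fc32` (the estimator default) returns the 32-unit FC representation — the
layer feeding the removed output — and `fusion320` returns the 320-unit
convergence layer.  The FC tap applies ReLU (configurable off), keeping
extracted features non-negative like the convolutional activations.  The
condition-comparison experiments extract every CNN condition at its
pre-FC tap (160 per single branch, 320 for the fused single-stream and
the dual-stream): the extraction pipeline reserves the features *before*
the fully connected layer, which is also the only arrangement under
which ReliefF has a dimensionality-reduction job to do.  ReliefF pruning
of the 320 convergence features is what distinguishes the
dual-stream-plus-ReliefF condition (IEDL) from the raw fused single
stream (IESL).

The single-stream variant applies one branch followed by the same FC-32 /
softmax head.  Its fused condition stacks the seven channels into a 7×600
input with the 3×11 second kernel, flattening to 320; the channel-stacked
layout is our reading of "fusion of the two kinds of data" for a
single-stream network, chosen because it needs no architecture change.

## ReliefF

For each sampled instance S the weight of feature N is decreased by the
mean range-normalised difference to the k nearest same-class hits and
increased by the prior-weighted mean difference to the k nearest misses of
every other class C, with factor P(C)/(1 − P(class(S))) and overall scale
1/(mk).  Defaults: k = 10, m = all instances without replacement (fully
deterministic), Euclidean neighbour search on per-feature max–min
normalised values so the metric and the diff agree, ties broken by lowest
row index, the sampled instance never its own hit, and zero-range features
defined to have diff 0.  Selection keeps features with W ≥ 0.1.  An
exhaustive brute-force implementation of the same update rule lives in the
test suite and the estimator matches it to 1e-10 on every fixture tried.

## Synthetic gait generator

No public recordings exist for this task, so the package ships a generator
that emulates the statistical structure the pipeline assumes rather than
the biomechanics:

* **EMG**: per muscle, a sum of wrapped Gaussian activation bursts in gait
  phase modulates a unit-RMS Gaussian carrier band-pass filtered to
  20–500 Hz, plus a small in-band noise floor (3% of the envelope peak).
  Amplitude-modulated band-limited noise is the standard surface-EMG
  surrogate.
* **IMU**: per channel, a constant offset plus the first two cadence
  harmonics of the gait phase, plus Gaussian noise (8% of the harmonic
  amplitude).  Acceleration, angular velocity and angle are generated as
  independent harmonic channels, not analytic derivatives of one another;
  the pipeline never relies on inter-channel kinematic consistency.
* **variability**: both modalities share one phase track whose per-cycle
  period is jittered (relative SD 0.03), which puts cycle-to-cycle Pearson
  similarity of the defaults in the high (> 0.85) regime of steady
  treadmill gait.

Mode defaults (cadences 2.6 / 1.8 / 1.4 / 1.72 Hz for running / walk /
stair / ramp; burst sets and harmonic tables in `synthio.py`) are free
design parameters chosen once so that the four modes are mutually
distinguishable, running has the largest amplitudes, and — deliberately —
no single modality and no per-channel summary suffices: level walking and
ramp ascent have nearly identical IMU kinematics and cadence (a moderate
incline changes leg-swing little) and nearly identical per-muscle EMG
intensities — what changes on the incline is the muscle *coordination
pattern*, i.e. where in the cycle each muscle fires relative to the others.
This cross-modal, cross-channel complementarity is what makes the
comparisons meaningful: a single-IMU model systematically confuses walk
with ramp; per-channel manual statistics (MAV, RMS, spectral summaries)
are blind to coordination timing and confuse the same pair; only features
that see cross-channel waveform structure — the convolutional extractors,
and at full strength the fused dual-stream — resolve all four modes.

Pseudo-subjects perturb the mode defaults multiplicatively (amplitude
0.85–1.15, cadence 0.95–1.05 across the six-subject default panel), a
deliberately mild model of between-subject variation.  Per-recording seeds
derive from (seed, subject, mode, repetition) via `numpy.random.SeedSequence`,
so datasets reproduce from one integer while all recordings stay mutually
independent.

What the generator does **not** model: electrode-skin artifacts, sensor
drift, muscle fatigue, X/Z-axis IMU channels, rest phases, and any
realistic musculoskeletal coupling.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and that its qualitative
behaviour (fusion ≥ single modality, learned ≥ manual features) emerges on
signals with the assumed structure — not that the same accuracies would be
reached on recorded human data.

## Experiment sizes

Recorded sessions in the emulated protocol run minutes per repetition; the
synthetic experiments use much shorter recordings, which is the package's
chosen problem scale:

* default dataset: 6 pseudo-subjects × 4 modes × 4 repetitions × 12 s
  (~600 usable windows per subject after edge trimming);
* per-subject evaluation: extractor trained per subject (30 epochs) on that
  subject's 70% split, features extracted for the train+test windows,
  ReliefF-selected, then five-fold CV per classifier;
* condition-ordering experiment: 3 pseudo-subjects × 4 modes × 2
  repetitions × 8 s, 24 epochs, repeated over 3 seeds and averaged.

The CV folds are assigned over the union of the extractor's train and test
windows: the extractor is trained once and its features are then
cross-validated.  The extractor having seen the CV-training windows makes
these accuracies optimistic relative to a fully nested
(re-extract-per-fold) design; this bias is retained knowingly, as part of
the protocol being implemented, rather than corrected.

## Numerical choices and edge cases

* Zero-phase filtering (`sosfiltfilt`) squares the designed magnitude
  response; filter tests compare measured sine gains against the analytic
  response of the designed filter.  0.25 s is trimmed from each recording
  end before windowing to drop filter transients.
* Cubic-spline upsampling supports integer ratios only and reproduces the
  input samples exactly at the knots.
* The split uses per-mode largest-remainder rounding with a carry
  propagated across modes, so totals land exactly on 7:1:2 while every
  mode stays within one window of the ratio.
* Gait-cycle boundaries for the QC statistics come from rising zero
  crossings of the mean-removed angle channel, gated to at least 70% of the
  autocorrelation-estimated fundamental period (a strong second harmonic
  otherwise yields two crossings per cycle); cycles are linearly
  time-normalised to 200 points before Pearson comparison.
* The manual "variance" follows the EMG convention: (1/(N−1)) Σ x², no
  mean subtraction.  ZC counts sign changes with step > δz; WAMP counts
  steps ≥ its threshold.  Both thresholds default to fractions of the
  window RMS (1% and 5%) so counts are unit-free.  The median frequency is
  the smallest bin reaching half the cumulative power, since the exact
  half-split equality rarely holds on a discrete periodogram.
* ReliefF's degenerate cases: constant features get weight 0; a class with
  ≤ k members raises with an actionable message; an empty selection raises
  rather than returning a 0-column matrix.

## Known limitations

The NumPy CNN is single-threaded BLAS-bound and intended for the printed
architecture at these dataset sizes, not for large-scale training.  The
permutation-null and ordering checks are stochastic: they hold across the
seeds exercised in the tests, not as theorems.  Classifier hyperparameters
(SVM C=1 RBF, KNN k=5, unlimited-depth Gini tree, 100-tree forest) are
conventional defaults, deliberately untuned.

One systematic effect is worth knowing: on well-separated synthetic data
most of the 320 convergence features carry ReliefF weight above the 0.1
threshold (typically 40–60% survive), so selection reduces redundancy only
partially, and the single unpruned decision tree — alone among the four
classifier families — generalises noticeably worse (~0.93–0.95 mean CV
accuracy) than SVM/KNN/RF (≥0.99) on the selected set, even though the
extractor itself classifies held-out windows at ≈0.99.  This is a
property of a greedy axis-aligned tree on a large correlated feature set,
not of the extractor; pruning or a lower selection threshold would lift
it, but both are kept at their documented defaults.
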