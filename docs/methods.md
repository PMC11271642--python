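# Methods

This note documents the models, parameters, and numerical choices behind
`lrpdetect`, and what the synthetic-data results do and do not show.

## Synthetic study model

The generator emulates a self-paced reaching study: 8 subjects × 2 tasks
(unilateral right-arm, bilateral) × 3 measurement sets × 40 trials.  Each
trial is a rest period drawn uniformly from [5, 7] s (hands on the
mechanical switches), the true movement onset, a reach, a button press,
and the return.  Recordings are continuous 64-channel EEG at 500 Hz
(extended 10-20 actiCap layout, FCz reference not a data channel) with a
6 s lead-in so every trial has the 5 s of pre-onset history the window
grid needs.

**LRP model.**  A unit ramp rising linearly over the last
`lrp_duration` = 1 s before the onset (half-cosine available via
`ramp_shape`), decaying back to zero over 0.3 s, scaled to
`lrp_amplitude` = −6 µV and injected through a fixed spatial pattern:
peak 1.0 at C1, 0.8 at C3, decreasing over the surrounding
fronto-central/centro-parietal left-hemisphere channels, small midline
weights.  Unilateral (right-arm) trials use only the left-hemisphere +
midline pattern; bilateral trials mirror it onto the right hemisphere, so
C1 and C2 carry equal weight by construction.  −6 µV on 10 µV noise is a
deliberately clear readiness potential; real single-subject amplitudes
vary widely, so absolute balanced accuracies on synthetic data
characterize the pipeline, not any recorded population.

**Noise model.**  Gaussian noise, power ∝ 1/f (exponent 1, flat available
via `white_noise`), equicorrelated across channels (ρ = 0.2 via a shared
component), normalized to `noise_sd` = 10 µV per channel.  Generated in
single precision: the elementwise and FFT work on ~500 s recordings is
memory-bound and noise does not need 53-bit mantissas.  FFT lengths are
padded to the next fast length to avoid Bluestein-path slowdowns.

**Kinematics.**  Reaches follow a minimum-jerk displacement profile to
(0, 300, 250) mm — 30 cm forward, 25 cm up, ‖·‖ ≈ 390.5 mm — over 0.8 s,
with 0.2 mm SD marker jitter at rest.  The hand switch releases
`switch_delay` = 15 ms after the true onset.  This value is load-bearing:
the distance × normalized-velocity product of a smooth reach stays below
the 0.6 mm onset threshold for roughly the first tenth of the reach
(~80 ms at 0.8 s duration), so the backward threshold search terminates
at the switch-release sample and the onset estimate inherits the
mechanical delay as its error.  15 ms is a realistic microswitch release
latency and keeps the estimator within the ±20 ms recovery band; a
larger delay degrades the estimate one-for-one.

**Invalid trials.**  A configurable fraction of trials (default 0) draws
a rest period below the 5 s minimum and is flagged invalid and excluded
from labeling and evaluation.  The default is zero so that the default
study pools the design's full 960 epochs per task; tests exercising the
exclusion logic set the fraction explicitly.

## Onset estimation

Positions are re-zeroed by the mean over the first second of the trial;
distance is the Euclidean norm of the re-zeroed 3-D position; velocity is
the one-sample forward difference of distance (first sample 0), low-pass
filtered at 4 Hz (Butterworth, 4th order) and normalized to the trial
maximum, so the product distance × velocity carries mm.  The filter is
applied zero-phase (forward-backward) by default to avoid shifting the
onset; causal filtering is available via `zero_phase=False`.  The
backward search runs sample-wise on the 500 Hz grid from the switch
release; trials where no sample falls below threshold are excluded rather
than assigned the trial start, mirroring the invalid-trial philosophy.
For bilateral trials the left-hand trace is used, matching the intended
application where the unimpaired arm labels the data.

Scaling all positions by a constant moves the threshold crossing slightly
(the product is not scale-free); on synthetic reaches the estimate moves
by at most a few samples per doubling.

## Montages

Montage memberships are configuration, not contract: the shipped custom
sets (4/8/16/21/32 channels) are nested supersets of {C1, C3, FC1, CP1}
growing concentrically over the left hemisphere and midline, and the
standard sets (16/21/32) are classic extended 10-20 constellations (the
32-channel standard set is the first block of the 64-channel layout).
All lists can be overridden via YAML (`load_montage_definitions`); the
enforced invariants are nesting, C1 membership, and the absence of
right-hemisphere (even-indexed) labels in custom montages.

## Window-to-feature transform

Windows are standardized per window and channel with the window's own
mean and SD — the statistics an online system has at hand — with
zero-variance channels mapped to zeros.  Decimation to 20 Hz and the
0.1–4 Hz bandpass are fused into one exact frequency-domain operation:
the real-FFT bins of the 1 s window at 1–4 Hz are retained (DC removed)
and inverse-transformed at 20 samples.  An earlier implementation used an
8th-order Chebyshev-I anti-aliasing decimator followed by a 20-point FFT
bandpass; its filter edge transients leaked ~5% of an out-of-band tone's
power into the kept bins, violating the intended ≥ 20 dB stopband, so the
exact spectral route replaced it.  Since the passband (≤ 4 Hz) lies far
below the 10 Hz target Nyquist, band selection itself anti-aliases.

**xDAWN.**  Training instances are labeled windows rather than a
continuous record with event markers, so the filters solve the
epoch-based two-class generalized eigenproblem: maximize evoked-response
energy wᵀ(ĒĒᵀ/T)w of the LRP-class average Ē against the pooled
per-window signal energy, keeping the top 4 eigenvectors by eigenvalue.
The pooled covariance is ridge-regularized by 1e-8 · trace/dim to guard
rank deficiency.  Eigenvalues are verified against an independent dense
eigensolver (max gap ~1e-16 on toy problems).

Features are the last 4 samples (0.2 s) of each pseudo-channel, flattened
channel-major (pseudo-channel 1's samples first), z-scored with
training-set statistics (zero-SD features mapped with SD := 1 and
flagged).

## Classifier

L1-regularized linear SVM (scikit-learn `LinearSVC`, primal
squared-hinge) with class weights 1:2 (NoLRP:LRP).  The complexity grid
"7 equal-spaced values in 10⁻⁶–10⁰" is read as log-equispaced integer
exponents −6…0, the only reading that yields 7 natural values across six
decades.  Selection uses stratified 5-fold cross-validation scored by
balanced accuracy — consistent with the evaluation metric — with ties
resolved toward the smaller C (stronger regularization).  Platt's sigmoid
P(LRP|s) = 1/(1 + exp(a·s + b)) is fitted on the training set's decision
values by maximum likelihood with Platt's smoothed targets (BFGS); an
internal-calibration variant was considered and left out since the
training sets here are large relative to the 2-parameter fit.  The
decision threshold is strictly p > 0.5, so p = 0.5 exactly is NoLRP.

## Evaluation

Ground-truth labels per window come from change-point relabeling: scan
the predicted labels backward from window [-1, 0] s through [-2, -1] s;
the first run of three consecutive NoLRP predictions wholly inside this
interval places the change point immediately after (later than) the run;
without such a run the whole interval is LRP.  Fixed boundary labels
(pre-interval → NoLRP, [-1, 0] s → LRP) are applied last.  Two readings
were genuinely open and are fixed as follows: boundary-window
*predictions* do participate in the 3-run scan (their *truth* is
overridden only afterwards), and balanced accuracy is pooled over all
windows of all test trials of a fold rather than averaged per trial.  The
implementation is verified exhaustively against a brute-force oracle over
all 2²¹ in-range prediction patterns.

A chance-level control needs care here: because relabeling derives truth
from predictions, scoring a random prediction sequence against truths
relabeled *from that same sequence* is biased above chance (≈ 0.57
pooled).  The meaningful control — random predictions scored against
truths fixed beforehand from an independent sequence — has expectation
exactly 0.5 and is what the tests and acceptance script compute.

Leave-one-set-out validation yields 24 folds (8 subjects × 3 splits) per
condition; condition C trains on two bilateral sets and tests on the
held-out unilateral set.  All fitted artifacts (xDAWN, normalizer, SVM,
Platt) are tagged with their training-fold identity and derive from
training data only.

## ERP analysis

For readiness-potential visualization the continuous recording is
band-passed 0.1–4 Hz with a zero-phase 4th-order Butterworth — an IIR
filter is the natural choice on a continuous signal, unlike the
per-window FFT filter of the classification path — then epoched
[-1.5, 0] s around onsets and baseline-corrected on [-1.5, -1] s.
Artifact screening is an optional peak-to-peak rejection; the generator
produces no blinks, so it defaults to off and no independent-component
analysis is implemented.

## Problem sizes and what passing means

The full default study (16 subject-task cells, ~480 s of 64-channel EEG
each) generates in about a minute and supports the end-to-end checks:
onset recovery within ±20 ms on ≥ 95% of 1920 labeled trials, 24 folds
per condition, 960 pooled epochs per task, condition A mean BA > 0.8 with
the transfer gap |BA_A − BA_C| < 0.005 at custom-32 (seeds 1, 2, 7 give
BA_A 0.807–0.820).  Stochastic unit checks run at reduced sizes chosen so
the tested effect exceeds its sampling noise by a comfortable margin,
e.g. template recovery by trial averaging uses 6000 trials because the
10 µV 1/f noise leaves a 10/√n µV standard error that must fall ~3σ below
the 0.6 µV tolerance band, and grand-average symmetry checks use 120
epochs per task.

Passing on synthetic data shows the pipeline is correct and internally
consistent, not that the detector reaches any particular accuracy on
recorded EEG: the generator's LRP is stationary across trials and
subjects, its noise has no artifacts (blinks, EMG leakage, electrode
drift), its spatial pattern is exactly lateralized and compact — which is
also why shrinking the montage from 32 to 4 channels costs almost no
performance here — and movement kinematics are noiseless minimum-jerk
reaches.  Real transfer performance depends on inter-subject and
inter-task variability the generator deliberately does not model.

## Known limitations

- No EMG, EOG/blink, or head-model forward simulation; no ICA.
- The exact channel identities of the reduced montages are approximations
  (editable via YAML); tests pin invariants, not memberships.
- The EEG on-disk format is mne's FIF container rather than a clinical
  exchange format; events, motion, ground truth, and reports are TSV/JSON.
- Single-trial onset estimates inherit the mechanical switch delay as a
  systematic bias; with the default 15 ms delay this is below the 2 ms
  sample period × 10.
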