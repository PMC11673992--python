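# Methods

## Problem and pipeline

`emocsp` classifies short EEG epochs into three emotional states
(positive, negative, neutral) evoked by a music-listening protocol.  The
chain is:

1. **Session model.** 19-channel, 250 Hz recordings in which ten
   one-minute music tracks (five positive, five negative) alternate with
   eight 15 s silent pauses (the neutral condition); ≈720 s per subject.
2. **Preprocessing.** 50 Hz notch, zero-phase FIR band-pass 0.5–45 Hz
   (order 800), optional ICA artifact rejection, removal of the first and
   last 10 s of each music track, concatenation of the remaining signal
   per class (200 s per music class, 120 s neutral), and rectangular
   windowing into 3 s epochs with 70 % overlap (219 windows per music
   class per subject).  The neutral class has less data, so its overlap
   is raised until its window count matches the music classes.
3. **Multi-class CSP.**  Per-trial centering, per-class scatter matrices
   `R_i = Σ_j X_j^T X_j`, composite `R = Σ_i R_i`, whitening
   `W = Λ^{-1/2} U_0^T` from `R = U_0 Λ U_0^T`, whitened class
   covariances `S_i = W R_i W^T` (which sum to the identity), per-class
   eigendecompositions, and filters built from extreme eigenvectors.
4. **Deep ensemble.**  Three identical convolutional autoencoders
   (conv 3×3×16 → pool → conv 2×2×8 → pool, mirrored decoder, all
   'same' padding; bottleneck (188, 5, 8) for a 750 × 19 epoch) trained
   on reconstruction MSE with Adam for 10 epochs; bottlenecks are
   flattened (7 520 per branch), concatenated (22 560) and fed to a
   128-ReLU + 3-softmax head trained with the branches frozen (stacking).
5. **Baseline.**  32 hand-crafted features per epoch (19 channel
   variances, 3 autocorrelation summaries, 10 DWT statistics), a
   per-feature Kruskal–Wallis screen at α = 0.05, and a majority vote of
   a linear SVM, 5-NN and a 35-unit MLP, each fitted on an independent
   bootstrap resample.

## Synthetic data model

Real recordings of this protocol are not redistributable, so the package
ships a generator that plants exactly the structure the pipeline
exploits:

    x(t) = A s(t) + pink(t) + white(t)

with a random square mixing matrix `A` (condition number bounded, ≤30 by
default), band-limited Gaussian sources (FIR-filtered white noise), and
channel-wise 1/f plus white sensor noise (σ = 0.5 and 0.2 relative to a
unit-variance source channel).  Class structure enters through the
source variances: each class owns one dominant source at 4× the unit
background variance — the positive source in the alpha band (8–13 Hz),
negative in beta (13–30 Hz), neutral in theta (4–8 Hz) with a 0.8×
overall amplitude so pauses are quieter.  The 4:1 ratio makes the
planted CSP problem solvable but not trivial.  Sources are Gaussian
processes rather than AR models because the pipeline only consumes
second-order structure.

The cohort generator draws screening-questionnaire rows (BDI, 9-point
SAM valence/arousal means, control-question and motion flags) spanning
the retain/exclude regimes; the documented rules (exclude BDI > 21,
failed control, motion noise, positive induction requiring valence and
arousal ≥ 6, negative induction requiring valence < 3) retain exactly 7
of the 16 reference-table subjects.  The "above 6 = high" SAM rule is
implemented as ≥ 6 because the reference table retains a subject with
means of exactly 6.0.

What the generator does **not** emulate: volume conduction from a
biophysical head model, ocular/muscle artifact waveforms, inter-subject
anatomical variability (a mixing-matrix jitter parameter exists but
defaults to 0 and claims no fidelity to any real cohort), and
non-stationarity within a session.  Passing tests therefore show that
the pipeline recovers planted second-order spatial structure — not that
it would reach the same numbers on real EEG.

## Numerical and design choices

- **Window counting.**  Step = round(L·(1−overlap)); trailing partial
  windows are discarded, so 200 s at 250 Hz with 3 s / 70 % gives
  exactly 219 windows.  This is the only convention consistent with the
  protocol's printed counts.  The balancing overlap is solved as the
  smallest fraction whose count reaches the target.  (The protocol's
  printed neutral count of 208 windows at 86 % overlap is not
  reproducible from 120 s under any step convention we tried; both the
  stated fraction and the solved one are exposed.)
- **Centering.**  Common-average reference and temporal mean removal are
  both applied (each can be disabled); covariance estimation needs the
  temporal centering, and CAR removes at most one spatial dimension,
  which the whitening rank logic tolerates.
- **Covariance scaling.**  Scatter matrices are summed, not averaged,
  and not trace-normalized by default (a `trace_norm` flag provides the
  standard CSP normalization); the scaling cancels in the whitening.
- **Eigen conventions.**  Eigenvalues sorted descending with stable
  ties; each eigenvector's largest-magnitude entry is made positive, so
  fits are reproducible bit-for-bit.  `rank_tol` = 1e−10 relative to the
  largest eigenvalue.
- **Filter-bank modes.**  `per_class` implements the literal 2m-filter
  banks.  `composite` (default) preserves the channel count: each
  class's largest-eigenvalue filters are stacked with a ⌈C/K⌉/⌊C/K⌋
  split (19 = 7+6+6 for three classes), because the downstream network
  expects T×C input planes.  The number of components m is a free
  parameter (default 3); nothing in the protocol fixes it.
- **Branch diversity.**  The three autoencoders are identical networks
  trained on identical data; the only free variable is the
  initialisation seed, which is what distinguishes the branches.
- **Input scaling.**  Epochs are min–max scaled with the minimum and
  maximum of the training tensor (matching the sigmoid output layer);
  per-epoch scaling is available behind a flag.  Scaling parameters are
  never taken from validation or test data.
- **Head regularization.**  The stacked feature dimension (22 560)
  dwarfs any realistic epoch count, so the softmax head is L2-penalized
  (weight decay 1e−2) and trained for 30 Adam epochs at lr 1e−3, batch
  32.  Without the penalty the head interpolates the training set with
  near-zero margin and generalizes at chance-plus; with it, held-out
  accuracy matches an L2 logistic probe on the same features.  Branch
  training stays at 10 epochs.
- **Split.**  70/15/15 with floor rounding (2 922 epochs → 2 045/438/439).
  Default granularity is `block`: each (subject, class) run of
  consecutive windows is cut into contiguous train/val/test chunks, so
  overlapping windows never straddle the split.  `window` granularity
  (plain shuffling) reproduces the conventional protocol and is
  optimistic when windows overlap 70–86 %.
- **Noise sweep.**  Noise at a prescribed SNR is added to held-out
  epochs only; the model is not retrained (a train-with-noise mode
  exists behind a flag).  SNR grid: −4, 0, 1, 10, 20 dB.  Because the
  corruption conceptually enters the raw recording before the 0.5–45 Hz
  chain, the sweep can band-limit the injected noise to the passband
  (`band=`); full-band white noise probes inputs the preprocessing can
  never produce (measured, the two differ little here).  On the planted
  cohort a model that never saw noise holds its accuracy at +20 dB and
  collapses to the chance floor by +10 dB: the whitening `Λ^{-1/2}`
  amplifies spatially weak directions (shrinkage covariance estimators
  are out of scope), so additive noise in those directions overwhelms
  the projections.  Evaluation-time-only corruption therefore cannot
  reproduce headline robustness numbers at negative SNRs; graceful
  degradation at strongly negative SNR would require the
  train-with-noise path.
- **Metrics.**  Accuracy, macro precision/recall/F1 and Cohen's kappa
  (multi-class confusion matrix), all in percent.  Macro averaging is
  the assumption of record; classes are balanced by construction so
  macro ≈ micro.  ROC is one-vs-rest with trapezoidal AUC.
- **Baseline conventions.**  Wavelet db4 at level 4 for 750-sample
  epochs (unstated in the protocol; config-exposed).  "Entropy of
  autocorrelation" is the Shannon entropy of the per-channel |acf| over
  lags 1..T/2 normalized to a distribution, averaged across channels.
  DWT statistics are computed on the pooled coefficients per channel and
  then averaged across channels.  The MLP uses one hidden layer of 35
  units (reading "35 hidden layers" as a unit count; 35 layers is
  implausible at this scale).  Bootstrap resamples are training-set
  sized with replacement; three-way vote ties go to the SVM.  The
  reference chain feeds raw feature vectors to the learners, so no
  feature standardization is applied by default; a `standardize` flag
  adds a per-learner scaler, and on the planted cohort that variant
  saturates the task (the 19 channel variances alone become linearly
  separable), overtaking the deep ensemble — the deep-above-baseline
  ordering holds for the unscaled reference procedure, and should be
  read as a property of that procedure rather than of hand-crafted
  features in general.
- **Neural network backend.**  The autoencoders and head are implemented
  in NumPy with Numba-compiled convolution kernels (float32, stride-1
  'same' convolution, 2×2 ceiling-division pooling, nearest-neighbour
  up-sampling with crop-to-target, Adam).  A stride-1 'same' transpose
  convolution is algebraically a plain convolution, which is how the
  decoder blocks are realised.  Gradient correctness is covered by
  finite-difference tests.

## Problem sizes used in tests and the acceptance script

The end-to-end checks run the full pipeline at a reduced problem size
chosen for desk-scale runs: 7 retained subjects, one 45 s track per
music class per subject (5 s head/tail trims) plus two 15 s pauses,
giving 252 balanced epochs per class (756 total, 525 train / 105 val /
126 test under the block split).  Spatial-filter algebra is checked on
100 random SPD problems and planted-recovery on 20 reseeded 6-channel
cohorts; the Kruskal–Wallis type-I rate on 1 000 null features.

## Known limitations

- Determinism across machines is best-effort: results are bit-stable for
  a fixed seed on one machine, but BLAS/Numba differences can move
  trained-model metrics in the last decimals.
- The composite filter bank duplicates rows if the covariance rank falls
  below the channel count minus one; inputs that are rank-deficient
  beyond CAR raise instead.
- The ICA artifact stage automates a traditionally visual step with
  kurtosis/variance thresholds (z > 3, ratio > 3); it is off by default
  and not validated against human raters.
- EDF round-trips are 16-bit quantized; the npz container is the
  lossless interchange format.
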