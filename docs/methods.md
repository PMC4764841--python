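# Methods

## Signal model of the synthetic generator

A session is an `n_sensors x n_samples` matrix at 1000 Hz (200-Hz low-pass
metadata), beginning with a 50-s task-free head segment from which all
baseline statistics are later estimated.  Four components are summed:

1. **Movement-related cortical field.**  Each execution cue adds
   `a_m * g_m * w(t - t_cue)`, where `m` is the movement type.  The
   temporal template `w` is a raised cosine rising from −1000 ms before the
   cue to a peak at +300 ms and decaying to zero by +1000 ms; the published
   figures show this shape but no formula, and the raised cosine is the
   smoothest two-parameter choice.  The spatial pattern `g_m` is a small
   Gaussian dipole patch (radius 2 cm) on a toy cortical surface, projected
   through the single-sphere lead field and scaled so its largest absolute
   parietal-sensor value is 1; the configured amplitude `a_m` is therefore
   the peak sensor deflection in data units.  The two movement types differ
   in both amplitude (grasp 0.45, open 0.36) and patch centre (about 10°
   apart on the left posterior cortex), because type decoding exploits
   spatiotemporal differences, not amplitude alone.
2. **Oscillations with ERD.**  Alpha (8–13 Hz) and beta (13–30 Hz)
   band-limited Gaussian noise per sensor (SD 0.55 and 0.40), multiplied by
   an envelope that drops to `sqrt(1 - depth)` during the movement epoch
   (0–1000 ms after each cue; depths 0.45 and 0.35), so the band-power
   ratio movement/baseline equals `1 - depth` exactly.  Both bands are
   carved out of one white-noise draw by disjoint spectral masks; disjoint
   supports of a Gaussian process are independent.
3. **1/f background** (exponent 1, SD 0.45 per sensor), synthesized by
   spectral shaping with the DC bin removed.
4. **White sensor noise** (SD 1.0).

Amplitude and noise defaults were set so that desk-scale open-loop decoding
lands where the published patient cohort lies: movement type ~70–85%
(cohort mean 68.1%), intention ~95%+ (93.8%), intention strictly above
type, and first-onset detections clustered a few hundred ms before the
peak-accuracy time.  They are configuration, not assertions about patient
SNR.

The closed-loop generator injects one MRCF burst of the instructed type per
instruction (probability 0.95, modelling lapses), beginning 500 ms (plus
100-ms Gaussian jitter) after the instruction change; the schedule records
the equivalent cue time of each burst as scoring ground truth.

The toy anatomy (mesh and hence patch topographies) is seeded by a separate
subject-level `anatomy_seed`, deliberately independent of the session seed:
repeated sessions of one subject share their dipole geometry, which is what
lets a decoder trained on an open-loop session transfer to a closed-loop
stream.

**What the generator does not emulate:** correlated brain noise and
artifacts (cardiac, ocular), head movement, realistic conductor geometry,
sensor gradiometry, or the amplitude non-stationarities of real sessions.
Passing tests therefore demonstrate the correctness and statistical sanity
of the pipeline, not patient-level performance.

## Features

A feature labelled `t` covers the half-open window `[t - 500 ms, t)` —
causal labelling, so the real-time path never touches future samples.  SMF:
per-channel window mean, z-scored with the mean/SD of the first 50 s,
restricted to the 84 parietal sensors.  Band powers: one-sided DFT power of
the baseline-mean-detrended window summed over `[f_lo, f_hi)` (no taper by
default; a Hann option exists), z-scored against the distribution of
500-ms-window powers over the 50-s baseline (hop 100 ms) — the symmetric
treatment with the SMF.  Channels with zero baseline SD raise rather than
produce infinities.

## Decoding

Nested cross-validation (outer 10 folds, inner 5 by default; both
stratified and seeded): the inner loop scores every (window, gamma, cost)
triple and the outer test trials are scored once with the winner.  Ties
break deterministically toward smaller cost, then smaller gamma, then the
earlier window.  Inputs are standardized per fold with training statistics.
The default grids are the conventional powers-of-two SVM grids
(gamma 2^-15..2^3, cost 2^-5..2^15, log-2 step 2); `small_spec()` is the
documented quick-run configuration (5 gammas x 3 costs, 5x3 folds) used by
the test suite and the acceptance script.  Its gamma grid extends down to
2^-13 because the concatenated intention task has 11 x 84 = 924 features
and a useful RBF gamma scales like 1/n_features.

The intention task concatenates the 11 rest windows (covering −2500..−1000
ms before the cue) and the 11 peri-movement windows (−500..+1000 ms); folds
split by trial so a trial's rest and intention examples never straddle a
split.

Known caveat: with blocked trial order (4 same-type cues per block) and
slow 1/f noise, same-block trials share noise, which inflates within-session
type accuracy relative to cross-session transfer.  This is a real property
of blocked designs, left in deliberately; the null (label-shuffled) checks
are unaffected because shuffling breaks the block structure.

## Onset detection

Confidence models are trained on individual 500-ms SMF windows: rest
windows labelled 0, intention windows labelled 1.  `c_svm` is a sigmoid
(Platt) calibrated RBF-SVM probability — calibration on internal CV, the
same construction as LIBSVM's probability estimates; `c_gpr` is the
posterior mean of a Gaussian-process regression onto the 0/1 boxcar target
(fixed RBF kernel, median-heuristic length scale, no hyperparameter
optimization).  Training windows are subsampled to at most 600 (SVM) and
400 (GP) examples, seeded, to bound the calibration and Cholesky costs.

An onset fires when **both** confidences strictly exceed their thresholds
(ties do not trigger) and at least 1.5 s has passed since the last
*accepted* onset (half-open lockout: exactly 1.5 s later is allowed;
suppressed candidates do not restart it).

Thresholds come from the smallest quantile level (one level applied to both
pooled streams, 201-point grid) whose rest-segment false-detection rate is
at or below the target (default 1 per minute).  The rest streams are
predicted **out-of-fold** (3-way split of the training trials): in-sample
rest confidences are optimistically quiet and would yield thresholds that
fire immediately on unseen data.

The offline timing evaluation follows the real-time algorithm under
ten-fold cross-validation.  Time zero of the histogram is the window at
which type-classification accuracy peaks on the training trials (fixed
mid-grid hyperparameters, tie toward the earlier window); each test trial
is scanned from −2000 to +1000 ms around it in 200-ms steps and the first
detection enters the 16-bin histogram, with a not-detected (N.D.) bin
completing the 100%.  The ±500-ms capture fraction is reported both among
all trials and among detected trials, since either denominator is
defensible.  Under label-shuffled training a run with zero detections
counts as KS p = 1 (no evidence against uniformity).

## Closed loop

Every 200 ms the latest causal SMF (z-scored against the stream's own first
50 s) updates both confidences; batch prediction is used for speed but is
numerically identical to the stepwise loop.  At an onset the movement type
is inferred by a separate RBF-SVM trained on all intention-epoch windows of
the open-loop session (labels = trial type; hyperparameters from a
trial-level 3-fold CV), and the two-state hand transitions 150 ms later
(hand-control delay).  Logged onset times are corrected by −70 ms (the
processing delay) before scoring.  The delay model's components
(acquisition 0.02, processing 70, feature window 500, hand control 150,
projection 110 ms) sum to ~830 ms.

Scoring sections are half-open `[start, end)`, bounded by every instruction
change **and** every hand-state change (the published per-subject section
counts exceed the 22 instructions, which forces this subdivision); a
section is same-state when the instruction matches the hand posture at its
start.  TP/FP/FN/TN count sections with/without a corrected-time onset.
An onset exactly on a boundary belongs to the later section.  When a
detection flips the hand mid-instruction, the flip itself opens the new
section — the only reading the section arithmetic supports.

Movement-type accuracy at detection is intrinsically hard in this model:
the detector fires at a fixed confidence level, which equalizes SMF
amplitude across types at detection time, leaving only the spatial-pattern
difference.  Synthetic closed-loop accuracies scatter from chance to ~70%,
matching the spread of the published per-subject values.

## Exact statistics

`fisher_exact_one_tailed` is the upper hypergeometric tail
`P(X >= a | margins)` — positive association — evaluated through the
log-gamma survival function, accurate to better than 1e-9 against exact
integer enumeration for every margin-compatible table with N ≤ 60 (test
suite).  Accuracy is `100 (a + d) / N` to one decimal.  Note on printed
precision: one published p (0.046) is the half-up rounding of the exact
tail 0.045455; comparisons therefore allow one unit in the last printed
place.

## Source imaging

The toy cortex is a rippled sphere (radius 0.07 m inside a 0.09-m
conductor; six seeded sinusoidal modes, relative amplitude 0.12) with
analytic surface normals; the ripple gives dipoles generic non-radial
orientations, since purely radial dipoles are silent in a spherical
conductor.  The forward model is the closed-form spherical-conductor
solution projected on the radial magnetometer orientations.

The inverse is a depth-weighted, Tikhonov-regularized minimum norm:
`W = R L' (L R L' + lam * mu * C)^-1` with source covariance
`R = diag(||l_j||^-1)` (exponent 0.5, balancing the superficial bias of
unweighted minimum norm against over-correction at depth), noise covariance
`C` estimated from the −1500..−500 ms pre-cue baseline of every trial, and
`mu = tr(LRL')/tr(C)` making `lam` dimensionless (default 0.01; `lam = 0`
raises a conditioning error when the Gram matrix is ill-conditioned).  The
hierarchical-Bayes hyperparameters `m0 = 100`, `gamma0 = 10` of the full
variational method are carried in `InverseConfig` as provenance only: the
downstream quantities need only a linear filter.

The eSCP of a trial is its per-vertex mean current over 0–500 ms, z-scored
per vertex against the across-trial distribution of baseline-window means.
The group map is a per-vertex one-way ANOVA across movement types, masked
at unadjusted p < 0.05 (an FDR option exists, off by default).  The null
calibration of that mask is checked on sessions with randomized (per-cue)
type order: with blocked order the slow noise correlates same-label trials
and genuinely inflates F — an artifact of blocked designs, not of the map.

## Problem sizes and tolerances

The test suite and acceptance script run full-size open-loop sessions
(80 trials, ~490 s) but reduced counts elsewhere, as the package's standard
quick-run sizes: a 9-session cohort for the onset histogram, 10 seeds for
the paired intention-vs-type comparison, 20 label shuffles for the null
band, 300-vertex meshes and 20 dipole recoveries for source imaging, and
4–6 null sessions for the mask-rate check.  The null mask-rate band
([2.5%, 8.5%] pooled) is wider than the iid binomial band because the
minimum-norm filter spatially correlates neighbouring vertices.  Numerical
ties in model selection always break deterministically (documented above),
and every stochastic step takes an explicit seed.
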