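# Methods

## Problem and pipeline

Huntington's disease (HD) produces chorea (abrupt, irregular involuntary
movements) and dystonia (sustained abnormal postures) in the upper limbs.
Clinician rating of these impairments — here the modified upper-limb motor
score (mULMS), the sum of five 0–4 UHDRS sub-items (left/right upper-limb
dystonia, trunk chorea, left/right upper-limb chorea; range 0–20) — is
coarse and rater-dependent. `hdmotion` implements an automated
alternative: three tri-axial accelerometers (one per wrist, one on the
sternum; 100 Hz, ±8 g) record a standardized token-transfer task performed
at three difficulty levels (baseline simple, baseline complex, dual task),
and the signals are reduced to features that feed (a) an HD-vs-control
classifier ensemble and (b) a continuous Movement Impairment Score (MIS)
regressed against the mULMS.

The pipeline is: per-sensor feature extraction (234 values per
participant-task) → equal-width discretization and greedy joint mutual
information (JMIM) ranking → per-task RBF-SVM classifiers fused by
majority vote → linear SVR of mULMS on the five most informative
baseline-simple features.

## Feature set (234 values)

Each of the three sensors contributes 39 time-domain and 39
frequency-domain values; names are fixed in a registry
(`<sensor>.<axis|pair>.<feature>`) so tables are column-stable.

Time domain, per axis (raw, unfiltered signal): mean and SD; seven
recurrence-quantification measures — recurrence rate (RR), determinism
(DET), mean/max diagonal line length, diagonal line-length entropy
(natural log), laminarity (LAM), trapping time (TT) — on the thresholded
distance matrix of the delay-embedded trajectory; the largest Lyapunov
exponent (LE, Rosenstein estimator, reported in nats/s); sample entropy;
and normalized permutation entropy.  Per sensor, the three inter-axis
Pearson correlations complete the 39.

Frequency domain, per axis: the time signal is low-passed (zero-phase
Butterworth, order 4, 20 Hz cutoff) and transformed with a rectangular
2 s / 50 % overlap STFT (0.5 Hz bins).  Features are mean per-window
signal power ("spectral energy"), mean Shannon entropy of the non-DC
power distribution ("component entropy"), and the mean magnitudes of STFT
components 1–5 (0.5–2.5 Hz; DC excluded — the gravity offset carries no
movement information).  Six wavelet features come from a five-level
Daubechies-2 decomposition of the *raw* signal (symmetric padding): the
sums of absolute detail coefficients at levels 1–5 plus the level-5
approximation sum.  The low-pass exists only to stabilise the STFT
features; the wavelet branch keeps the high-frequency jerk content.

### Numerical conventions

* RQA parameters (unstated in the clinical protocol, field-standard
  defaults, all config-exposed): embedding dimension m = 3, delay
  τ = 10 samples (0.1 s), radius ε = 0.2·SD (fixed radius, per axis),
  minimum line lengths l_min = v_min = 2, Theiler window = τ.  DET uses
  the Webber/Zbilut denominator (all diagonal-line points); vertical-line
  statistics run over full matrix columns.  Measures with no qualifying
  lines are 0; a zero-variance signal degenerates to an all-ones matrix
  (RR = 1) with a warning.
* LE: nearest neighbours constrained to temporal separation above the
  mean period (dominant FFT peak); divergence slope fitted over steps
  0–30 by least squares.  Verified against the logistic-map limit ln 2
  and the near-zero periodic limit.
* Sample entropy: m = 2, r = 0.2·SD, Chebyshev distance, self-matches
  excluded; if no templates match, the defined fallback −ln(1/n_pairs)
  is returned with a warning.
* Permutation entropy: order 4, delay 1, ties ranked by order of
  appearance, normalized by ln(4!).  Order 4 remains resolvable at the
  shortest admissible signals (400 samples).
* Component entropy of white noise converges to ln B − (1 − γ), not ln B:
  raw periodogram bins are exponentially distributed.  The flat-spectrum
  limit ln B holds deterministically and is tested as such.
* Constant axes yield correlation 0 (with a warning) rather than NaN; the
  234 outputs are always finite.

The O(n²) kernels (recurrence line statistics, sample-entropy template
counting, nearest-neighbour divergence) are JIT-compiled; pure-NumPy
matrix paths are kept and the test suite asserts bit-level agreement
between the two routes, plus agreement with brute-force pure-Python
oracles.

## Selection, classification, regression

Features are equal-width discretized into 5 bins (small-sample regime;
the bin count is exposed in configuration).  JMIM ranks greedily: first
the feature maximising I(f; C), then repeatedly the candidate maximising
min over selected s of I((f, s); C), with ties broken by registry order.
Mutual information is the plug-in estimator in bits.  Ranking, feature
count tuning and hyperparameter search all run inside each training fold
(leak-free); a whole-cohort ranking mode exists for the MIS predictor
choice.

Per task, an RBF-SVM is trained on z-scored top-n features;
n ∈ {5, 10, 20, 40} and (C, γ) ∈ {1, 10, 100} × scale·{0.1, 1, 10} are
chosen by inner cross-validation (smallest n on ties).  Votes fuse by
majority; a participant with only the baseline simple recording is
classified by that vote alone, and a two-vote split resolves to HD —
missing an early-manifest patient is costlier than a false alarm.
Evaluation is stratified participant-level 5-fold CV; both pooled and
fold-averaged metrics are reported because the two aggregations differ
slightly for unbalanced folds.

The MIS is a linear ε-insensitive SVR (C = 1, ε = 0.1 on standardized
targets) of mULMS on the top-5 baseline-simple features, fitted on HD
participants only (controls carry mULMS 0 by convention and would anchor
the regression artificially).  Evaluation is leave-one-out; reported
metrics are Pearson r, r², adjusted r² (p = 5), MAE and MAE as a
percentage of the maximum observed score.  The MIS is left on the raw
regression scale (not clipped to [0, 20]).

## Synthetic cohort

The original clinical recordings are not deposited, so the generator
emulates their assumed structure; its defaults are the study conditions
and are not tuned per run:

* Healthy sessions: duration ~ N(13.6 s, 1.5 s) clipped to [10, 20] s;
  eight Hann-windowed sinusoid transfer cycles (one oscillation per
  cycle, shared cycle timing across axes and sensors, per-cycle duration
  CV 0.05); y and z are phase-shifted copies at relative amplitude 0.6
  and 0.4; dominant wrist ×0.5 and chest ×0.1 of the non-dominant-wrist
  0.8 g amplitude; white sensor noise SD 0.02 g.
* HD sessions: duration mean 13.6 + 0.85·severity s; cycle-duration CV
  0.05 + 0.03·severity; superimposed choreic bursts (Poisson rate
  0.1 + 0.05·severity /s; 0.2–0.5 s damped 6–12 Hz oscillations along
  random 3-D directions; peak amplitude ~ Exp(0.04·severity) g); chest
  burst amplitude scaled by trunk-chorea item / 4.
* Task effects: baseline complex duration ×1.15; dual ×1.3 with burst
  rate ×1.2 (dual-task interference).
* mULMS: each sub-item ~ Binomial(4, severity/20), so the target is
  integer, bounded and noisy like the clinical scale; severity drawn
  uniformly on [1, 18] for HD.
* Ordered task failure: mULMS ≥ 14 leaves only baseline simple;
  10 ≤ mULMS < 14 drops the dual task (thresholds chosen to approximate
  the reported clinical failure counts under the default severity
  distribution).

What the generator does *not* model: gravity-vector orientation and
sensor tilt, biomechanically realistic limb kinematics, bradykinesia and
dystonic posture dynamics, or between-subject baseline variability beyond
duration jitter.  Passing parameter-recovery tests therefore shows that
the pipeline recovers the group structure and severity coupling *the
generator encodes*, not clinical performance; the printed clinical
accuracies depend on the unavailable 92-participant dataset.

## Problem sizes and determinism

The default experiment (48 controls / 44 HD, seed 7, ≈ 250 recordings of
1 000–4 000 samples) extracts in about a minute and evaluates in a few
seconds on one CPU; session extraction is well under one second after the
kernels are compiled.  Every stochastic step (generator, fold assignment,
permutation nulls) derives from the single run seed, and identical
configurations reproduce identical artifacts.

## Known limitations

* JMIM with 5-bin EWD on 92 samples is a high-variance estimator; the
  selected feature sets vary across folds by design (leak-free mode).
* The adjusted-r² formula at n = 44, p = 5 gives 0.54 for r² = 0.59
  rather than a printed 0.53; the identity as implemented is exact and
  tested.
* The chest-ablation contrast is directional only: on easy synthetic
  cohorts both variants can saturate at 100 % and the contrast vanishes.
* The ε-insensitive SVR solution is deterministic but not
  permutation-exact at machine precision for degenerate duplicate rows;
  row-order invariance is asserted to 1e-8.
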