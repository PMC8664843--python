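# Methods

This note documents the models, algorithms and design choices behind
`cardiomech`: what each stage assumes, which tunables matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Signal model and pre-processing

A recording is a synchronous 6-channel sample matrix (3-axis accelerometer =
SCG, 3-axis gyroscope = GCG) at a common sampling rate (256 Hz default).
Channels are addressed by name, never by position; timestamps are seconds
from recording start and all cardiac intervals are reported in
milliseconds.

Band-pass filtering uses a Butterworth design applied forward–backward
(`sosfiltfilt`), so fiducial timing is not skewed by group delay; the
effective magnitude order doubles (a "4th-order" filter acts as 8th-order
in magnitude). This is documented behaviour, not compensated. Defaults:
1–45 Hz for SCG, 1–20 Hz for GCG, 1–10 Hz for the annotation stage.

**Artifact masking.** The sliding RMS (window *M*, default 500 ms, centered,
edge-truncated) is computed on the per-sample RMS resultant of all six
band-passed channels, and samples where it exceeds twice its median are
rejected. The source material does not state whether the RMS filter runs
per channel or on a combined signal; the joint-resultant choice keeps all
channels synchronized under a single mask. Samples exactly at the threshold
are kept, so an all-zero recording (median 0) is fully kept rather than
fully rejected. Masked regions are never spliced: each maximal clean run is
treated as an independent piece of signal.

**Chunking.** Within each clean run, *N*-second windows (default 10 s) are
tiled from the run start with stride N·(1−overlap); trailing partial
windows and runs shorter than *N* yield nothing. Overlap defaults to 0 for
binary detection and 0.5 for the 4-class severity task (data augmentation).
Anchoring at the run start is a choice; nothing downstream depends on it.

## Beat detection

The three axes of each modality are fused by a per-sample RMS, enveloped by
the magnitude of the analytic (Hilbert) signal, and smoothed with a
zero-phase 2nd-order 2 Hz low-pass. Because the linear and angular
envelopes carry different physical units, each is normalized by its own
median within the chunk before summation — median rather than max for
outlier robustness. Peaks of the summation signal are picked by an
adaptive dual-threshold tracker in the Pan–Tompkins tradition with the
classical constants: signal/noise levels updated with weights 0.125/0.875,
decision threshold = noise + 0.25·(signal − noise), 300 ms refractory, and
a search-back pass triggered at 1.66× the running mean interval accepting
candidates above half the threshold. The signal level initializes to the
90th percentile of the interior candidate peaks and the noise level to the
envelope median; candidates within 0.2 s of a chunk edge are discarded —
zero-phase filtering leaves edge transients there that would otherwise
inflate a time-windowed initial maximum and suppress every real beat in
the chunk. Each fused peak is then refined to
the local *signed* maximum of every band-passed axis within ±25 ms. A
chunk yielding fewer than two peaks is flagged unusable and excluded —
never a crash.

Amplitude invariance: because envelopes are median-normalized, globally
rescaling a chunk leaves the detected peak times bit-identical (tested).

## Fiducial annotation and the P/MA features

On the 1–10 Hz filtered GCG_X and GCG_Y, per beat: J is the signed local
maximum nearest the detector's refined peak; I/K are the nearest local
minima within 150 ms before/after J; L is the first local maximum within
200 ms after K; A is the last local maximum within 200 ms before I. These
search rules and window lengths are reconstructions (the classical
I/J/K/L/A definitions live in prior literature) and are all config-exposed.
The beat window spans 40% of the preceding inter-beat interval before J to
60% after; the first beat of a chunk borrows the following interval.

P is the sample with the largest |first difference|·fs of the annotated
axis within the beat window — the gyroscope measures angular *rate*, so the
first difference is angular *acceleration*, matching the feature's name
"maximum acceleration" (MA = the value at P). Magnitude is used so polarity
conventions cannot flip the feature. Whether P should be a signal extremum
or a derivative extremum was ambiguous; the derivative reading was chosen
and is flagged here.

Beats missing a required extremum, or violating A<I<J<K<L, are flagged
invalid and excluded from interval statistics rather than imputed. A chunk
with <50% valid beats is excluded from the feature matrix.

## Feature space

* **Time-domain HRV (15)** on the NN series (differences of consecutive
  valid J times on GCG_Y, the primary annotated axis; intervals bridging an
  invalid beat or a chunk boundary are dropped): AVNN, SDNN, RMSSD, pNN50,
  median, skewness, kurtosis, ENN, SENN, CENN, VAI, VLI, SD1, SD2, SD1/SD2.
  - pNN50 divides by the *total* NN count (the stated definition), not the
    number of successive differences; a config switch
    (`pnn50_denominator="n_diffs"`) restores the conventional form.
  - The printed long-axis Poincaré formula subtracts the constant 2·AVNN
    inside a standard deviation, which is shift-invariant — so SD2 as
    printed is identically SD1, and SD1/SD2 is 1 whenever defined. This is
    implemented as printed (default); `sd2_convention="conventional"`
    computes the usual std((NN_i + NN_{i+1})/√2) instead.
  - Entropies are Shannon entropies in bits of a fixed-width histogram
    (bin width 1/128 s for NN). ENN is the entropy of the NN_{i+1}
    marginal of the joint Poincaré binning, SENN the mutual information
    I(NN_{i+1}; NN_i), CENN the conditional entropy H(NN_{i+1}|NN_i), so
    ENN = SENN + CENN holds exactly by construction. These quantities were
    named but not defined in the source material.
  - Skewness/kurtosis are Fisher moment ratios, kurtosis *not*
    excess-adjusted (a normal sample tends to 3), bias-uncorrected; all
    standard deviations are population-style (divide by n). Fixed so the
    brute-force oracles in the tests are unambiguous.
* **GCG intervals (88)**: mean, median, std, skewness, kurtosis, entropy
  (Freedman–Diaconis binning), min, max for each of IVCT, LVET, IVRT, L–I,
  L–J, K–I, P–I, P–J, K–P, L–P and MA, pooled over both annotated axes and
  all valid beats in scope. Subject-level statistics pool all valid beats
  of the subject rather than averaging chunk features.
* **Frequency-domain HRV (30)**: Welch band powers (Hann window, 50%
  overlap) of VLF (0.0033–0.04 Hz), LF (0.04–0.15 Hz), HF (0.15–0.4 Hz),
  the LF/HF ratio and total power, per raw IMU axis. The PSD is computed on
  the raw artifact-masked signal, *not* the band-passed one: the 1 Hz
  high-pass would annihilate all three HRV bands. The Welch segment
  defaults to 120 s but adapts down to half the longest clean run (masking
  rarely leaves uninterrupted 240 s stretches), floored at a configurable
  30 s minimum below which the axis is flagged missing. This trades VLF
  resolution for availability and is the package's own design choice.

Chunk-level matrices carry 88 + 15 = 103 columns (chunks are too short for
the spectral bands); subject-level matrices carry all three blocks,
133 columns. Samples with missing features are dropped (or raise, per an
explicit policy flag) — the assembled matrix never contains NaN.

## Classification and evaluation

The 80/20 train/test split is stratified by class and grouped by subject:
at chunk level, every chunk of a subject lands on the same side (leakage
guard). Cross-validation is standard stratified 10-fold (folds adapt
downward when a class has fewer members than folds); at chunk level folds
are over chunks, matching the standard practice for this design. Grid
search maximizes mean CV F1 over per-family grids covering tree
depth/leaf/split/feature limits, split criterion, number of estimators,
learning rate (XGBoost) and class weights (inverse-frequency "balanced" as
a grid value for every family); the winner is refit on the full training
side. Binary metrics take AS as the positive class; the 4-class severity
task is macro-averaged (config-exposed). XGBoost grids include
min_child_weight = 0.5 because at subject-level sample sizes (tens of
subjects) the default cover constraint of 1 can forbid any split, and
XGBoost runs with exact greedy split finding: histogram binning places
thresholds at the sampled data extreme of a cluster, which has zero
generalization margin at these sample sizes, whereas exact splits at
midpoints between observed values.

A caution inherent to this design, visible even on synthetic data: the
subject-level problem is p ≫ n (133 features, tens of subjects). With
very few training subjects, some feature perfectly separates the training
labels by chance, ties the split gain of genuinely informative features,
and wins the tie deterministically — the cross-validated F1 reported by
the tuner drops when this happens, which is the intended warning signal.
The shipped study conditions use 10 subjects per class so the chance of a
spurious perfect separator among ~100 features is small.

## Filter optimization

F1(M, N) is maximized over M ∈ [100, 2000] ms, N ∈ [2, 25] s with a
Gaussian-process surrogate (Matérn-5/2 kernel on inputs scaled to the unit
square, white-noise term, normalized targets) and expected-improvement
acquisition: 8 Latin-hypercube initial points, then EI-guided probes up to
the budget (default 40), EI maximized over 512 random candidates per
iteration. Each probe rebuilds chunk-level features from scratch at that
(M, N) on *training recordings only* and scores the chosen family with
fixed default hyperparameters by 10-fold CV F1 (re-tuning inside the
objective would nest two searches). Probes with no usable chunks score 0;
evaluations are memoized on (M, N). The whole loop is deterministic under
its seed. An exhaustive grid sweep over the same objective provides the
oracle the optimizer is tested against.

## Shapley attribution

The characteristic function maps a feature subset to the mean CV F1 of the
family retrained on that subset, with v(∅) := 0 — an untrained model has
no F1 — so efficiency reads Σα = F1(full set). Hyperparameters are fixed
once on the full set, not re-tuned per subset (2^n re-tunings would be
computationally indefensible). Exact enumeration is guarded at 15 features;
the permutation-sampling estimator reports per-feature Monte-Carlo standard
errors and is deterministic under its seed. The comparison ranking uses the
classifier family's native split-gain/impurity (or |coef|) importance
through a uniform interface; non-linear SVMs expose no native importance
and raise.

## The synthetic generator

Each beat is a train of Gaussian lobes, one signed lobe per fiducial
(A +, I −, J +, K −, L + on the annotated gyroscope axes; a simpler I/J/K
train on the other four axes so every axis peaks at J), σ = 12 ms, with
offsets A −140, I −70, J 0, K +65, L +130 ms. Alternating signs make the
waveform oscillatory and give the annotator unambiguous targets whose
analytic extrema sit exactly at the configured times. The geometry was
chosen so that extrema survive the pipeline's double band-pass (1–20 Hz
then 1–10 Hz) with worst-case displacement under 2 samples at 256 Hz.

Disease classes differ morphologically: the L lobe shifts by +15/+30/+45 ms
(mild/moderate/severe), lengthening IVRT, and the systolic I–J–K complex is
scaled by 1.25/1.5/2.0, scaling the maximum angular acceleration (MA).
The whole I–J–K complex is scaled — not J alone — because the steepest
edge of the beat involves both lobes flanking J, and scaling only part of
it would break the linear MA contract. Inter-beat intervals follow a
stationary AR(1) process (default mean 800 ms, SD 50 ms, lag-1 0.4) whose
innovations are scaled so the population SD equals the target exactly;
class morphologies share identical IBI statistics by default, so class
separation lives in beat shape, not heart rate. White sensor noise is
added at a configurable fraction of each axis' template RMS (default
0.05); motion artifacts are 0.5–2 s bursts of amplified noise on all
channels simultaneously at a Poisson rate (default 2/min, gain 10×),
matching the removal model of the RMS filter. Cohorts add inter-subject
variability — a lognormal overall amplitude factor (SD 0.10 on the log
scale) and Gaussian fiducial-offset jitter (SD 3 ms) per subject — so
within-class feature spread is non-degenerate, as in a real cohort.

All randomness flows from one master seed through named substreams (IBI,
noise, artifacts, per-subject morphology), so a morphology-only config
change leaves beat timing bit-identical and every fixture is reproducible.

**What passing tests show — and don't.** The generator emulates exactly the
structure the pipeline assumes: quasi-periodic beats with known fiducials,
stationary broadband noise, and burst artifacts. It does not model
respiration, baseline wander, sensor drift, beat-to-beat morphological
variability, ectopy, or the physiological coupling between HRV bands and
autonomic state. Perfect end-to-end F1 on synthetic cohorts therefore
demonstrates the correctness and internal consistency of the
implementation under its own assumptions — not clinical performance, which
requires patient recordings that are not publicly available.

## Problem sizes

The shipped tests and the acceptance script use: 40–60 s recordings for
signal-chain checks, 280 s (≈350 beats) for SDNN recovery, twenty 300 s
recordings (10 healthy / 10 severe) for the end-to-end classification
runs, and six 120 s recordings for the filter-optimization comparison
(budget 40 vs a 5×5 grid, objective memoized). These sizes give stable statistics on
one CPU in about a minute each; all of them are package choices and scale
up linearly via the generator's `duration` and `n_per_class`.

## Known limitations

* Beat-level evaluation excludes a 0.2 s margin at chunk edges: a beat
  whose waveform support is cut by the chunk boundary is not scoreable.
* The envelope-peak to J-peak offset is morphology-dependent (energy
  centroid of the beat); the ±25 ms per-axis refinement absorbs it for the
  templates used here but very asymmetric morphologies could exceed it.
* With the printed SD2 formula, SD1/SD2 is constant 1 and carries no
  information; the conventional switch exists for scientific use.
* The subject-level "leave-one-out 10-fold" wording is interpreted as
  standard 10-fold CV with subject-partitioned folds.
* The 4-class severity pathway shares every component with the binary task
  (macro metrics, 50%-overlap chunking); its clinical error structure is
  not reproducible synthetically.
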