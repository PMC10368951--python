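# Methods

This document describes the models, parameter choices and numerical
decisions behind `attnfuse`: a pipeline for recognizing attention versus
rest states from multichannel EEG by fusing time-domain, frequency-domain
and non-linear dynamics features.

## 1. Recording model and paradigm

A session follows a block paradigm of 20 trials. Each trial is a 3 s cue,
a 60 s task segment and a 10 s rest interval (73 s per trial, 1,460 s per
session) sampled at 250 Hz on a 30-channel 10–20 montage
(Fp1 … O2). Half the trials are *attention* (serial mental arithmetic in
the motivating design), half *non-attention* (eyes-open rest), in
randomized order. Only task segments are analyzed: each 60 s segment is
cut into six contiguous 10 s epochs of 2,500 samples, giving 120 labelled
epochs per session (60 per state).

Signals are stored in microvolts. Two containers are supported: a
compressed NumPy array with a JSON metadata sidecar, and 16-bit EDF+C
written by a minimal built-in writer (one annotation channel carrying
task onsets/durations/states as time-stamped annotation lists) and read
back through `mne`. The EDF writer rounds each channel's physical range
to its 8-character header representation *before* quantizing, so the
digitization gain a reader reconstructs from the header is exactly the
gain used for writing; round-trip error is below two digitization steps.

## 2. Preprocessing

* **Band-pass filter**: zero-phase FIR, 0.5–50 Hz by default. The filter
  is a 1,651-tap Hamming windowed-sinc (transition width 0.5 Hz) applied
  by FFT convolution with symmetric taps, so group delay is exactly
  compensated without forward–backward filtering. Passband ripple is
  below 1% and 60 Hz is attenuated by >35 dB.
* **Epoching**: pure slicing of the annotated task segments; epochs
  inherit the trial's state label and chronological (trial, epoch)
  indices.
* **Artifact rejection**: an epoch is dropped when any channel exceeds
  ±100 µV peak amplitude (standard practice for transient artifacts such
  as blinks and electrode pops). A high-frequency (30–50 Hz) power
  z-score flag for myoelectric contamination is available but disabled
  by default. Rejection is logged per (trial, epoch) and is idempotent.

## 3. Feature extraction (123 per channel per epoch)

Features are computed per channel on each 2,500-sample epoch and
concatenated channel-major into one design-matrix row
(`CH:FEATURE` columns; 3,690 for the full montage).

### 3.1 Time domain (12)

Standard deviation, mean, peak-to-peak, skewness, excess kurtosis, RMS,
Hjorth mobility, 75th percentile, Hjorth complexity, variance,
decorrelation time and zero-crossing count. Hjorth descriptors use the
classical variance-ratio definitions with first differences:
activity = var(x), mobility = sd(Δx)/sd(x), complexity =
(sd(Δ²x)/sd(Δx))/(sd(Δx)/sd(x)). Skewness and kurtosis use the biased
moment estimators (m₃/m₂^1.5 and m₄/m₂² − 3) computed directly from
numpy moments. Decorrelation time is the first lag at which the biased
autocorrelation becomes non-positive; lags are scanned incrementally
with an FFT fallback for slowly decorrelating signals. Zero crossings
are strict sign changes of the mean-removed signal with exact zeros
skipped.

### 3.2 Frequency domain (48)

Spectra are Welch estimates (Hann window, 50% overlap, density scaling),
verified against Parseval's identity. Layout:

* 5 harmonic (spectral) centroids of the canonical bands
  δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz;
* 6 detail energies of a level-6 Daubechies-4 DWT in *periodization*
  mode (coarse→fine, cD6…cD1). Periodization keeps the transform
  orthogonal, so sub-band energies sum exactly to signal energy at
  lengths divisible by 2⁶;
* spectral Hjorth complexity (1);
* 5 band powers plus 10 pairwise band-power ratios in fixed order
  (δ/θ, δ/α, δ/β, δ/γ, θ/α, θ/β, θ/γ, α/β, α/γ, β/γ), ratio
  denominators guarded by a 1e-12 floor;
* log-log linear regression of the 1–40 Hz spectrum: slope, intercept,
  R², residual RMS (4);
* spectral Hjorth mobility (1); 95% spectral edge frequency (1);
* 5 band energies of fourth-order Butterworth band-filtered signals;
* 10 median frequencies over the sub-bands 0.5–2, 2–4, 4–5, 5–7, 7–10,
  10–13, 13–15, 15–20, 20–30, 30–40 Hz.

Spectral moments mₖ = ∫fᵏP(f)df use trapezoidal integration; spectral
Hjorth mobility is √(m₂/m₀) and complexity √(m₄/m₂)/√(m₂/m₀).

### 3.3 Non-linear dynamics (63)

Petrosian fractal dimension, line length, spectral entropy, Hurst
exponent (rescaled range), sample entropy; 10 Rényi, 10 Tsallis and 10
Shannon entropies (q = 2) of the normalized spectral distribution over
the ten sub-bands above; approximate entropy, SVD entropy, permutation
entropy (order 3, normalized by ln 3!), Higuchi fractal dimension
(k_max = 10); 7 wavelet-entropy terms (−p_j ln p_j over the normalized
energies of [cA6, cD6…cD1]); 14 Teager–Kaiser statistics (mean and
standard deviation of ψ(x[n]) = x²[n] − x[n−1]x[n+1] over each of the 7
DWT coefficient sets, coarse→fine); SVD Fisher information, detrended
fluctuation analysis (DFA) exponent, Katz fractal dimension.

Sample/approximate entropy use Chebyshev distance, tolerance
r = 0.2·sd(x), embedding m = 2. A match requires distance ≤ r. SampEn
counts template pairs of both lengths over N−m templates excluding
self-matches; ApEn includes self-matches with N−m+1 and N−m templates.
The degenerate-count guard returns ln((N−m)(N−m−1)) − ln 2 when no
m+1-length pair matches. Both are computed in a single O(N²) pass
compiled with numba (`@njit(cache=True)`), verified against brute-force
loop oracles to 1e-10.

DFA uses 16 log-spaced box sizes from 16 to N/4 with vectorized
first-order detrending. Its exponent is ~0.5 on white noise and ~1.5 on
Brownian motion; Higuchi FD tends to 2.0 on long white noise and Katz FD
to 1.0 on a straight line — these closed-form limits are part of the
test suite.

### 3.4 Fusion

The fused vector is the order-preserving concatenation time (12) +
frequency (48) + non-linear (63) = 123 named scalars per channel. Any
non-finite feature aborts design-matrix construction with the offending
(trial, epoch, channel, feature) named.

## 4. Classification

* **Intra-subject**: chronological 5-fold cross-validation. The epoch
  sequence is split into contiguous time-ordered blocks (remainder to
  the last fold); each block serves once as the test set, so training
  data never post-dates test data selection by shuffling.
* **Inter-subject**: leave-one-subject-out (LOSO) over a cohort.

Classifiers: random forest (100 trees, Gini impurity, fixed seed),
decision tree (entropy criterion, best splitter), linear-kernel SVM
(C = 2; the configured kernel coefficient 0.2 is recorded but inert for
a linear kernel). The SVM is wrapped in a pipeline with a standard
scaler fitted on training folds only; trees receive raw features.

## 5. Group statistics

* **State means**: per subject and state, epoch features are averaged
  after a single-pass ±3 SD outlier exclusion (computed within the
  subject-state cell).
* **Paired tests**: two-sided paired t-tests across subjects contrast
  attention vs non-attention per channel and feature; zero-variance
  differences are guarded with p = 1.
* **Functional connectivity**: Pearson correlation between
  band-filtered channel pairs per epoch, averaged within subject and
  state. Bands split α into lower (8–10 Hz) and upper (10–13 Hz)
  sub-bands. Edge-wise paired t-tests are Benjamini–Hochberg corrected
  at q = 0.05.
* **Topography**: band-power columns are Z-scored per subject across
  that subject's epochs, then averaged per state, yielding a
  (band, channel) map of state contrasts.
* **Time–frequency**: Morlet wavelet power (7 cycles, 1–50 Hz by
  default). Note the 7-cycle wavelet at 1 Hz needs >11 s of signal, so
  the default grid applies to trial-long segments, not single 10 s
  epochs.

## 6. Synthetic data generator

Because no public recording of this paradigm exists, the package ships a
session generator used for all validation.

**Model.** Each channel is a sum of band-limited Gaussian processes
synthesized in the frequency domain: a complex Gaussian spectrum is
masked per band, shaped by f^(−a/2) (default spectral exponent a = 1)
and inverse-FFT'd, with the analytic normalization chosen so the
expected variance matches the target exactly. Background RMS is 10 µV
with 1 µV white sensor noise; a fraction ρ = 0.3 of background variance
is shared across channels to induce realistic cross-channel correlation.
During *attention* task segments, θ/α/β amplitudes on prefrontal
(Fp1, Fp2, F7, F3, Fz, F4, F8) and occipital (O1, Oz, O2) channels are
scaled by √gain (default power gains 0.7, i.e. attention suppresses
these rhythms — the direction expected for externally oriented task
engagement). Optional transient artifacts are 0.5 s half-sine pulses of
300–500 µV at a configurable Poisson rate. Cohorts draw per-subject
log-normal gain jitter (sd 0.1) from spawned seed sequences;
per-subject seeds stay below 2³¹.

**Limitations.** The generator is deliberately a *statistical* model:
it reproduces band-power structure, 1/f shape, cross-channel
correlation and non-stationarity at the trial level, but not cortical
geometry, volume conduction, phase coupling, eye movements, or any
cognitive dynamics within a task segment. Effect sizes are set by the
band gains and are not calibrated to human data; classification
accuracies on strong synthetic effects (gain 0.5) saturate near 1.0 and
should not be compared with accuracies on real recordings. Connectivity
contrasts are null unless an explicit FC effect is configured.

## 7. Numerical choices

* Frequency-domain synthesis uses `next_fast_len` padding and one
  inverse FFT per (gain-envelope) band group per channel; bands sharing
  an envelope have disjoint spectral supports, so combining them in a
  single transform is distributionally identical to summing separate
  draws.
* The FIR filter is applied once via overlap-free FFT convolution
  (`mode="same"`); symmetric taps make the result zero-phase.
* DWT mode "periodization" (rather than symmetric padding) is chosen
  for exact energy conservation.
* SampEn/ApEn kernels are numba-compiled; the first call in a process
  pays a one-time JIT compilation cost.
* EDF physical ranges are rounded to their header representation before
  quantization (section 1).

## 8. Problem sizes for validation

Statistical validation needs many sessions, so the validation suite
scales the *montage*, never the paradigm (always 20 trials × 73 s at
250 Hz):

* 6-channel montage (Fp1, Fp2, F3, O1, Oz, Cz — five affected channels
  plus one midline control) for cohort simulations and effect recovery;
* 2-channel montage (Fp1, Cz) for type-I-error calibration, where many
  independent cohorts matter more than channel count: 30 null cohorts
  of 20 subjects give the false-positive rate of the paired feature
  tests a standard error of ~0.008;
* full 30-channel montage for structural checks.

Null calibration uses cohorts with all band gains at 1.0 (no state
effect); effect recovery uses gains of 0.5. With these sizes the whole
validation suite runs in well under half an hour on one CPU core.
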