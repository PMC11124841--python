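# Methods

This note records the modeling choices behind `motionloc`, the defaults and
their rationale, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Signal model and preprocessing

Recordings are treated as uniformly sampled per sensor group (inertial
channels at one rate, GPS fixes at another, audio at a third), with the
sample rate inferred as 1/median(Δt) from the timestamp column and required
to agree with any declared rate within 20 %. Units for inertial channels are
deliberately unspecified (g vs m/s²): every downstream feature is either
scale-invariant (skewness, kurtosis, entropy over the window's own range,
LPCC shape) or standardized by the refinery, so the pipeline is
unit-agnostic.

Inertial denoising uses a low-pass Butterworth filter, order 4 and cutoff
10 Hz at the default 32 Hz sampling — voluntary human motion concentrates
below ~10 Hz, and order 4 gives 80 dB/decade rolloff without ringing. The
filter is applied forward–backward (zero phase) so the nine channels stay
mutually time-aligned; two passes square the magnitude response, which the
tests check against the closed form. Note the digital filter's response
deviates from the analog closed form near Nyquist (bilinear-transform
frequency warping); the attenuation is always *at least* the analog
prediction, and the two-sided closed-form checks are run with the cutoff far
below Nyquist where warping is negligible.

GPS latitude and longitude are median-filtered independently with a centered
size-3 window (endpoints replicated), which removes isolated wild fixes
without smearing turns.

Segmentation produces 5 s windows. The default 50 % overlap is a throughput
choice: non-overlapping 5 s windows would yield few training rows per
recording. The Hamming taper is applied to the nine inertial channels only.
Audio clips are segmented untapered because the MFCC front end applies its
own per-frame Hamming window; tapering twice would modulate frame energies
with the position of the frame inside the 5 s window. GPS fixes travel with
the window raw, since trajectory features are time-domain quantities of the
fix sequence, not spectra.

## Features

**Physical stream.** Per channel: Shannon entropy over a 16-bin equal-width
histogram spanning the window's own range (parameter-free and
scale-adaptive; entropy is 0 for a constant window and capped at
log₂ 16 = 4 bits), population skewness, and population excess kurtosis.
Per accelerometer axis: LPCCs of an order-12 all-pole model, 12 cepstral
coefficients — the speech-processing convention, which comfortably covers
the handful of spectral peaks a gait signal has. The Levinson–Durbin
recursion operates on the biased autocorrelation; tests pin it to a direct
Toeplitz solve at 1e−8 and the cepstral recursion to the
inverse-transform-of-log-spectrum oracle at 1e−6. LPCCs are computed on the
accelerometer axes only; a config switch can extend them to the gyroscope.

**Localization stream.** GPS trajectory features use the haversine distance
on a 6,371 km sphere; bearings for the direction-change sum are chained only
over legs longer than a 1 m jitter floor, otherwise stationary GPS noise
(≈3 m per fix) would accumulate hundreds of spurious degrees. Step detection
finds peaks of the acceleration magnitude with prominence ≥ 0.5·std and
spacing ≥ 0.25 s (no sustainable human cadence exceeds 4 steps/s). Heading
uses the raw horizontal magnetometer components, θ = atan2(B, A); tilt
compensation is out of scope. The per-window heading feature is the circular
mean of per-sample headings. MFCCs follow the speech convention (pre-emphasis
0.97, 25 ms frames, 10 ms hop, 26 triangular mel filters, 13 coefficients,
floored log) and are summarized per window by the mean over frames — the
simplest order-invariant statistic. Missing GPS or audio yields zero fills
plus an explicit flag column, so "absent" is distinguishable from "measured
zero"; when a stream is present for every window the flag column is constant
and the variance threshold removes it.

Skewness and kurtosis appear in both streams; in the localization stream
they are computed on the inertial channels (configurable), and a constant
channel there contributes neutral zeros rather than an error, since
localization windows can legitimately contain dead channels (e.g., a
stationary magnetometer axis after filtering).

## Feature refinery

Selection keeps features with population variance strictly above τ;
τ defaults to 0, i.e. only constant columns are dropped. The refinery then
fits a per-feature Yeo–Johnson transform

ψ(x; λ) = ((x+1)^λ − 1)/λ for x ≥ 0 (ln(x+1) at λ = 0), and
−((−x+1)^{2−λ} − 1)/(2−λ) for x < 0 (−ln(−x+1) at λ = 2),

with λ maximizing the Gaussian profile log-likelihood (Jacobian included) by
bounded scalar search on [−5, 5], agreeing with a 10,001-point grid oracle to
1e−3. The sign of the λ = 2 branch is chosen so ψ is strictly increasing and
continuous in both arguments. After the transform, each column is
standardized with the training mean and standard deviation — the classifier
needs scale control, and "Gaussian-like" columns make the single learning
rate behave uniformly. All of this state lives in a serializable
`RefineryState`; applying a fitted state never reads the rows it is applied
to beyond the transform itself.

Class balancing operates on raw signal windows, not on feature vectors:
permuting the entries of a feature vector would destroy column semantics, so
minority windows are split into k = 3 contiguous equal segments (remainder
attached to the last), rearranged by a uniformly drawn non-identity
permutation applied identically to all channels (and the audio clip), and
features are re-extracted from the permuted window. The GPS sub-track is
carried unchanged — permuting fixes would fabricate impossible trajectories.
Augmentation runs inside each training fold only, never on test rows.

## Classifier

The MLP (64-64-32 ReLU hidden layers, softmax output) is implemented
directly in numpy because its training contract is specific: plain SGD
without momentum, constant learning rate 0.01, batch 32, at most 100 epochs,
early stopping when the validation cross-entropy fails to improve by ≥ 1e−4
for 10 consecutive epochs, with the best-validation weights restored. The
validation split (20 %) is stratified by class and drawn once per fit from
the run seed. Weights use Glorot-uniform initialization from the same seed,
making a fit bit-reproducible. Weight restoration tracks any strict
improvement while the patience counter only resets on improvements ≥ 1e−4;
this keeps the invariant "restored validation loss ≤ final-epoch validation
loss" exact. An independent check trains scikit-learn's `MLPClassifier` with
the same architecture on the same data and verifies both land in the same
accuracy regime.

Ties in the output probabilities resolve to the lowest class index
(classes are kept in sorted order).

## Evaluation protocol

Stratified K-fold (default K = 5, seeded) partitions windows; within each
fold, balancing, refinery fitting and classifier training see training
windows only, and the untouched test windows are predicted once. Test
predictions are pooled over folds into one confusion matrix rather than
averaging per-fold matrices. Mean accuracy is the unweighted mean of
per-class recalls, matching the row-normalized-confusion presentation.
AUC is the Mann–Whitney rank statistic with midranks for ties, one-vs-rest
per class, plus an unweighted macro mean; tests pin it to the O(n²) pairwise
oracle and to scikit-learn's trapezoidal implementation.

## Synthetic data

The generator emulates the *structure* of public wearable corpora — 32 Hz
tri-axial inertial channels, 1 Hz GPS, mono audio, per-recording labels, and
configurable class imbalance — with class signatures designed so that the
pipeline's feature set (not the raw samples) separates them: sitting is
low-variance noise about the gravity vector, standing adds a slow postural
drift, walking and running are periodic at 2 and 3 Hz with growing
amplitude; localization contexts differ in trajectory speed (stationary /
1.4 m/s pedestrian / 15 m/s vehicle with gentle turns), audio spectral shape
(indoor tones + pink-ish noise vs broadband outdoor noise vs engine hum) and
gait content. GPS fixes get 3 m Gaussian jitter, typical of consumer
receivers.

What this does **not** emulate: sensor placement variability, orientation
changes, label noise, device heterogeneity, magnetic disturbances, GPS
multipath, or the long-tailed label taxonomies of real corpora. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its feature set separates classes whose signatures differ in the ways
the features measure — not that real-world accuracy figures transfer.

Problem sizes used by the test suite and the acceptance script — ~200
windows per class for the four-class physical study (19 recordings of 30 s
per class, 11 windows each), ~90 windows per localization context, and a
220-window 10:1 imbalanced pair — are the package's standard study
conditions; they are large enough for stable pooled metrics while keeping a
full run in the low minutes.

For the imbalance experiment the two classes are deliberately overlapping
(gait 2.0 vs 2.3 Hz, amplitudes 1.0 vs 1.15, noise sd 0.9) so the class
prior actually matters; on fully separable classes balancing would change
nothing. Minority recall with augmentation exceeds recall without it across
seeds, but both remain well below 1 — the classes genuinely overlap.

## Degenerate inputs and numerical edges

- Constant windows: entropy returns 0; skewness/kurtosis/LPC raise a
  degenerate-signal error in the physical stream (a constant inertial channel
  on a live sensor indicates a defect worth surfacing, and the error names
  the window).
- All-zero audio: MFCCs stay finite through the log floor (1e−10).
- Tracks with fewer than 2 fixes: all-zero trajectory features, logged.
- Variance threshold removing every feature raises an error advising a lower
  threshold rather than silently passing an empty matrix.
- An empty prediction matrix yields an empty label list.
- `filtfilt` padding requires 3·(order+1) samples; shorter signals are
  rejected with a length error.

## Known limitations

- Heading is uncompensated for device tilt; on a non-level device the
  atan2 heading is biased.
- The MLP is CPU-only and modest; it is the reference architecture, not a
  performance ceiling.
- The haversine sphere (6,371 km) differs from WGS-84 geodesics by up to
  ~0.5 %; irrelevant at window scale.
- Feature extraction assumes equal-length channels within a sensor group and
  a single sample rate for all nine inertial channels.
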