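# Methods

## The pipeline

The package classifies human activities from multichannel inertial time
series. Four stages: (1) sliding-window segmentation and per-column min–max
scaling, (2) unsupervised per-sensor stacked denoising autoencoder (SDAE)
feature extraction, (3) supervised classification with a Boosting K-Fold
ensemble of gradient-boosted decision trees, (4) evaluation and
class-separability diagnostics.

## Preprocessing

Each recording is cut independently (windows never span recordings, so no
window mixes labels) into windows of `window_len` samples advanced by
`stride`; a window is emitted iff it fits entirely, giving
`floor((T − w)/s) + 1` windows. Two conventions are supported directly:
2.56 s windows with 50% overlap (w = 256, s = 128 at 100 Hz) and
non-overlapping 2.56 s windows (w = s = 128 at 50 Hz); a dense s = 8
setting suits small postural-transition corpora.

Windows are flattened row-major to `w·n_axes` columns and scaled to
`(x − min)/(max − min)` with **training-set extrema only**. Held-out data is
scaled with the same extrema and deliberately not clipped, so out-of-range
test values survive as values outside [0, 1]; columns constant in training
map to 0 (the 0/0 case). The 70/30 train/test split is stratified by label
(the stratification keeps class priors comparable across partitions) and
seeded.

## SDAE feature extraction

One independent stack per sensor, so each stack learns one sensor's
dynamics. Design choices, and why:

- **Corruption**: Bernoulli zero-masking at rate `dropout` (default 0.4),
  applied only during training. The denoising objective forces the encoder
  to fill in blanked coordinates from their context.
- **Activation**: logistic sigmoid for both encoder and decoder. Inputs are
  min–max scaled into [0, 1], so a (0, 1)-valued decoder is the natural
  reconstruction range and learned features stay bounded in (0, 1).
- **Loss**: mean squared reconstruction error against the clean input,
  averaged over both batch rows and coordinates.
- **Greedy pretraining**: layer l+1 trains on the *clean* (uncorrupted)
  encodings of layer l, with corruption re-applied inside each layer's own
  pretraining — the standard stacked-denoising recipe.
- **Fine-tuning**: unsupervised. The unrolled chain (all encoders, then all
  decoders in reverse) is trained end-to-end on the same corrupted-input
  reconstruction objective. Labels enter only in the classification stage;
  keeping fine-tuning unsupervised preserves the clean separation between
  the unsupervised feature extractor and the supervised classifier. The
  per-layer epoch budget and the fine-tuning budget are independently
  configurable (`epochs`, `fine_tune_epochs`; the latter defaults to the
  former).
- **Optimisation**: mini-batch Adam, learning rate 1e-3, batch 32, scaled
  uniform fan-in/fan-out weight initialisation, all seeded. Implemented in
  numpy with explicit backprop — the stacks here are small (hundreds of
  units), where a hand-rolled dense implementation is simple and fast.
- **Preset shapes** (`DATASET_SDAE_PRESETS`): [400, 200, 40] (barometer
  [150, 70, 20]) for the moving-modes corpus with pressure, [400, 200, 30]
  without, [100, 30] for the static-behaviour corpus, [30] for the
  postural-transition corpus; dropout 0.4, batch 32 throughout. With the
  [100, 30] preset over three sensors the concatenated feature vector is
  3 × 30 = 90-dimensional.

Divergence (non-finite loss) raises rather than returning garbage.

## Boosting K-Fold classification

A seeded stratified k-fold plan (k = 5) is processed sequentially. Fold f
trains a LightGBM multiclass model on its plan training indices **plus one
copy** of each sample misclassified in fold f−1's validation set; fold 1
gets no extras; after fold f the misjudged set is **replaced** by fold f's
own validation errors. Duplication multiplicity is exactly one (the
bookkeeping identity `train_size_f = base_f + misjudged_{f−1}` is asserted
in tests), and a perfect backend provably reduces the scheme to plain
stratified k-fold.

Prediction is a hard majority vote of the k models. Labels are encoded as
contiguous integers in first-appearance order; vote ties break toward the
smallest code (bincount-argmax). No model is refit on the full data — the
final predictions come from the k fold models only.

Backend hyperparameters are library defaults with 100 boosting rounds,
`deterministic=true` and a fixed seed; an xgboost backend is available via
`GBDTParams(backend="xgboost")` and is the default for the hand-crafted
baseline.

## Separability diagnostics

Within-class scatter uses the biased 1/N_i normalisation (consistent with
the population-moment convention used throughout the package), priors are
empirical class frequencies, and the between-class matrix is the half
double-prior-weighted sum of pairwise mean-difference outer products — which
equals the prior-weighted scatter of class means about the grand mean, an
identity verified to 1e-10 against a brute-force oracle. The report emits
total inner/outer traces plus one symmetric class-by-class table per
representation (within-class traces on the diagonal, pairwise between-class
traces off it); raw and learned features get separate tables rather than a
combined triangular layout.

## Metrics

Macro (unweighted) averaging of per-class precision/recall/F1; accuracy is
the confusion trace over the sample count. An empty predicted or truth
class yields a 0 metric with a warning rather than NaN.

## Baselines

- **Single SDAE**: softmax layer over the concatenated encoder outputs,
  trained by cross-entropy with Adam; encoder weights are fine-tuned
  jointly (disable with `fine_tune_encoder=False`).
- **Hand-crafted features + GBDT**: per window — vertical/horizontal
  acceleration statistics after projecting onto the window-mean gravity
  direction (mean, population variance/std, median, min, max, range, and
  all three quartiles Q1/Q2/Q3 by linear interpolation); modulus-series
  statistics for accelerometer/gyroscope/magnetometer adding kurtosis and
  skewness (population moments, 0 for constant series), RMS (read as a
  single root-mean-square feature), trapezoidal integral and double
  integral at the sensor sampling interval, lag-1 autocorrelation, and the
  magnitudes of the 7 lowest non-DC Fourier coefficients; pairwise Pearson
  correlations between the three axes; and barometric change (last − first)
  and standard deviation over 6 s and 10 s trailing sub-windows. Barometric
  features may use a longer trailing buffer than the classification window
  (`pressure_buffer`), since 6–10 s exceeds a 2.56 s window. Feature order
  is fixed and documented by column names.

## Synthetic data generator

The generator emulates exactly the structure the pipeline exploits, with
one signal model per class:

- static postures: constant gravity vector (9.81 m/s² at a class-specific
  orientation) + i.i.d. Gaussian noise;
- locomotion: class-specific gait fundamental (walk 1.8 Hz, stair-up
  1.4 Hz, stair-down 2.3 Hz — inside the 1–2.5 Hz band typical of human
  gait) with 2–3 harmonics on the accelerometer and phase-shifted
  harmonics on the gyroscope;
- magnetometer: a fixed reference field slowly rotating about the vertical
  (0.01 Hz heading wander) + noise;
- barometer: linear drift (±12 Pa/s for elevator classes, roughly a 1 m/s
  vertical speed) + noise.

Default noise sigmas (acc 0.05 m/s², gyro 0.02 rad/s, mag 0.1 µT, pressure
1 Pa) are low-noise consumer-IMU levels; the default dataset is 6 classes ×
20 recordings of 10 s at 50 Hz. All randomness derives from one seed via
per-recording child generators, so CSV output is byte-identical across runs.

What the generator does **not** model: biomechanical gait shape, sensor
bias random-walk, orientation dynamics (no quaternion integration),
inter-subject variability, or timestamp jitter. Passing tests on this data
therefore demonstrate the pipeline's mechanics — scaling, feature learning,
boosting bookkeeping, voting — and the direction of the separability
effect, not field accuracy on real recordings; published real-data
accuracies are not reproduction targets here.

## Problem sizes and numerical notes

The end-to-end check uses the default 120-recording dataset (360
non-overlapping 128-sample windows, 252 train / 108 test), two-layer
[100, 30] stacks with 15 + 15 epochs, and k = 5 — a configuration chosen to
exercise every stage faithfully at desk scale; it completes in seconds on
one CPU. Expected behaviour there: held-out accuracy ≥ 0.95 (measured 1.0)
and a within-class trace reduction from raw windows to learned features
(measured ≈ 8×).

Degenerate inputs are handled explicitly: constant scaling columns map to
0; constant series get 0 kurtosis/skewness/autocorrelation; a near-zero
mean acceleration falls back to the device z-axis for gravity
decomposition; recordings shorter than one window yield an empty output
with a warning. Published dataset share tables appear to truncate the third
decimal rather than round (e.g. 1325/10663 = 12.426% listed as 12.42%);
recomputed shares are reported unrounded and compared to one unit of
printed precision.
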