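# Methods

This note records the scientific and numerical choices behind
`tremorstage`: what each stage assumes, which parameters matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## 1. Problem setting

A participant traces patterns in five task epochs, with fatigue-inducing
exercise between epochs, so fatigue — and with it fatigue-induced
physiological tremor (FIPT, 8–14 Hz) — accumulates monotonically across the
session. The epoch number is therefore used as the tremor-level class label
(1–5). The classifier's job is to recover that level from short multimodal
sensor windows.

Sensing modalities and native rates:

| stream | channels | rate |
|---|---|---|
| upper-arm EMG | 8 | 500 Hz |
| forearm EMG | 8 | 500 Hz |
| upper-arm / forearm accelerometer | 3 axes each | 500 Hz |
| camera-derived forearm cross-sectional area | 1 | 50 fps |

## 2. Vision-based cross-sectional area (csavision)

Two square fiducial markers per camera view sit on opposite sides of the
forearm; the centroid distance in a view tracks one girth axis. The known
marker edge (25 mm) fixes the pixel-to-metric scale per view
(`px_per_mm`, derivable from the observed marker edge itself). The
cross-section is approximated as an ellipse, `Area = π(a/2)(b/2)` with full
axis lengths halved — the standard ellipse formula; whether girth
measurements should enter as full or semi-axes is a convention, and the
full-axis-with-halving form is adopted throughout (generator and estimator
agree, so the round trip is exact).

Open choices, resolved as follows:

- **Axis assignment.** The top-view distance is always the major axis and
  the side view the minor axis, regardless of magnitude; a `sort_axes` flag
  orders them by magnitude instead. A fixed assignment keeps the feature
  continuous when the two girths cross.
- **Rest area.** `Area_rest` is the mean area over an operator-designated
  rest interval, default the first 2 s of the recording. MMG_CSAC is then
  `(Area_i − Area_rest)/Area_rest`.
- **Smoothing.** Moving median (11 frames ≈ 0.22 s at 50 fps) to reject
  single-frame detection outliers, then a fifth-order Savitzky–Golay filter
  over 21 frames (≈ 0.42 s). Only the polynomial order is dictated by the
  sensing design; the windows are package defaults sized to suppress jitter
  while passing the slow (≲ 1 Hz) contraction dynamics, and both are
  exposed in the API.
- **Missing frames.** Frames where a marker is undetected are flagged and
  carried as NaN; gaps up to 5 frames (0.1 s) are bridged by linear
  interpolation before filtering, longer gaps stay missing. Fabricating
  detections is never allowed.
- **Detection backend.** Marker detection is pluggable. The built-in
  backend thresholds the image (Otsu), extracts connected components, and
  accepts filled, near-square regions; it is adequate for rendered or
  high-contrast footage and is exercised against renderer ground truth. An
  ArUco-dictionary backend is declared but requires OpenCV at run time;
  without it the pipeline ingests centroid/corner CSV tables instead.

## 3. Signal conditioning (signalprep)

- **EMG:** per-channel DC-offset removal over the recording; second-order
  Butterworth band-stop at 45–55 Hz (the power-line notch; the design names
  only the 50 Hz center, ±5 Hz is the common notch width); full-wave
  rectification; linear envelope via a second-order 6 Hz low-pass. All
  filters run forward–backward (zero phase) so modalities stay aligned;
  the envelope is clipped at zero after filtering.
- **Accelerometer:** signal magnitude vector per segment,
  `√(ax²+ay²+az²)`. The magnitude is invariant to axis permutation and
  sign, so armband orientation does not matter. The 50 Hz notch is applied
  to EMG only — tremor content lives far below 45 Hz and the conditioning
  path for MMG is the magnitude reduction.
- **Alignment:** polyphase resampling of every stream onto a 250 Hz
  timeline (anti-aliased 2:1 decimation for the 500 Hz sensors, 1:5
  band-limited interpolation for the camera channel), trimmed to the
  overlapping span.
- **Normalization:** per-channel standardization to zero mean and unit
  variance using the population (1/N) standard deviation, computed per
  recording — the classifier consumes one participant-session at a time,
  and per-recording statistics avoid leaking other participants' scales.
  Constant channels are zeroed and flagged rather than divided.

## 4. Windows, labels, feature sets (dataset)

Each aligned recording is cut at the five epoch boundaries; segment k
carries label k. Window slicing augments each segment with `n_windows`
sub-windows of `window_length` samples whose start offsets are drawn
uniformly at random (seeded). Uniform random placement is the standard
window-slicing augmentation; windows never cross an epoch boundary because
slicing operates on the labeled segment.

Feature sets ablate the modalities over a fixed canonical channel order
(EMG-UA 1–8, EMG-FA 1–8, ACC-UA, ACC-FA, CSAC):
set 1 = EMG+ACC+CSAC (19 channels), set 2 = EMG+ACC (18),
set 3 = EMG+CSAC (17), set 4 = ACC+CSAC (3).

The train/test split is stratified over windows at 9:1. Because windows
from one segment are near-duplicates, a window-level split is optimistic
about generalization to new sessions; a `grouped` option keeps all windows
of a source segment on one side. The default remains the window-level
split, which matches how such augmented datasets are commonly partitioned,
and the optimism caveat is stated here rather than hidden.

## 5. BiLSTM-GRU classifier (classifier)

Architecture: sequence input (N channels) → bidirectional LSTM, 50 hidden
units per direction, emitting the full sequence with forward/backward
states concatenated (GRU input width 100) → dropout 0.5 → GRU, 50 units,
final hidden state → dropout 0.5 → dense → softmax over 5 classes. One
label per sequence; the final-state readout is what turns a
sequence-to-sequence recurrent stack into a sequence classifier.

Loss is class-weighted cross-entropy in its standard non-negative form,
`−(1/L) Σₙ Σₘ wₘ tₙₘ ln yₙₘ`; class weights default to 1. Training:
Adam (β₁ 0.9, β₂ 0.999), initial learning rate 10⁻³ dropped ×0.1 every 10
epochs, mini-batch 64 drawn from a fresh shuffle each epoch (trailing
partial batches dropped, so iterations = epochs × ⌊n/64⌋), L2 weight decay
0.01 on weight matrices only (biases exempt), and global gradient-norm
clipping at 1. Dropout uses inverted masks, disabled at inference.

Implementation notes:

- The whole network, forward and backward-through-time, is written on
  numpy arrays in float32. Gradients were verified against central finite
  differences in float64 (worst relative error ≈ 6·10⁻⁶ across all
  parameter groups in the development checks; the test suite re-verifies
  the loss against a direct negative-log-likelihood oracle).
- Recurrent kernels run time-major with cached gate arrays so the weight
  gradients collapse into single large matrix products.
- Backpropagated recurrent gradients decay exponentially over hundreds of
  timesteps and drift into the CPU's denormal range; magnitudes below
  10⁻³⁰ are flushed to zero inside the BPTT recurrences. This is far below
  float32 resolution of any retained gradient and keeps the arithmetic out
  of the denormal slow path.
- Initialization: Glorot-uniform weights, zero biases except the LSTM
  forget gate (bias 1), all from one integer seed; a seeded run is
  bit-reproducible on a given BLAS.
- Parameter count obeys the closed form 2·4H(N+H+1) + 3G(2H+G+1) + C(G+1)
  (single-bias GRU convention); for N=19 that is 50,905 parameters.

## 6. Evaluation (evaluation)

Confusion matrix rows are true classes, columns predictions. Per class,
one-vs-rest precision, recall and F1; overall accuracy is trace/total (the
multiclass reduction of the TP/TN accuracy formula); macro metrics are
unweighted class means, and F1 is macro-averaged from per-class P and R
(not computed from pooled counts). Zero-denominator metrics are defined as
0 and flagged in the report. The ablation trains one network per feature
set on the identical split and seed, so differences isolate the sensing
modalities.

## 7. Synthetic cohort (simgen)

The generator emulates the statistical structure of fatigue progression,
not muscle physiology:

- **EMG** per epoch: band-limited Gaussian noise shaped by a fourth-order
  Butterworth low-pass whose cutoff is solved numerically (from the digital
  filter's frequency response) so the carrier's median frequency matches
  the level profile; the segment is then scaled to the profile's RMS. The
  defaults walk RMS gain 1.0→2.0 and median frequency 120→80 Hz linearly
  across levels — a clear, configurable rendering of the canonical fatigue
  signature. Baseline EMG RMS is 50 µV.
- **Accelerometer**: gravity-free by default (a 1 g offset is a config
  flag), white noise (σ = `noise_sd`, default 0.01 g) plus a tremor
  sinusoid along a fixed direction, amplitude 0→0.05 g across levels and
  frequency 9→13 Hz (inside the 8–14 Hz tremor band), upper arm at 0.6×
  the forearm amplitude.
- **CSA**: rest area 55 cm² (a typical adult forearm) times
  `1 + drift + 0.01·sin(2π·0.6 Hz·t) + noise`, with the mean elevation
  0→8 % across levels; 0.6 Hz matches a slow metronome-paced contraction
  rhythm.
- **Epochs**: five epochs of 20 s each (a typical static-hold duration),
  configurable. Determinism: each participant's stream derives from
  `(seed, crc32(participant_id))`, so cohorts are reproducible and
  participants are independent.
- **Marker rendering**: the CSA series maps to ellipse axes through a
  fixed aspect ratio (minor = 0.8 × major), each axis becomes a centroid
  separation in its view at a configurable scale (default 2 px/mm), with
  optional isotropic Gaussian centroid jitter. At zero jitter the vision
  pipeline inverts the rendering exactly.

What the generator does **not** emulate: motor-unit recruitment and EMG
nonstationarity within an epoch, tremor harmonics and amplitude modulation,
inter-participant variability in fatigue rates, camera perspective and
lens distortion, marker misdetections under motion blur. Consequently, a
high synthetic classification score demonstrates that the pipeline is
correctly wired and that the network can exploit the intended
discriminative structure — it does not predict accuracy on human data,
where class overlap is far larger.

## 8. Problem sizes in the shipped checks

The test suite and the reproduction script scale the study down so a
complete run fits comfortably on a single CPU: the end-to-end checks use
windows of 250 samples (1 s at 250 Hz), 20 windows per segment, and 15
training epochs; the reproduction script simulates 20 virtual participants
(2,000 windows, 1,800 train / 200 test) and reports the median held-out
accuracy over three training seeds. On the default well-separated
profiles these runs sit at or near 100 % accuracy; the per-seed values are
printed by the script.

## 9. Known limitations

- The window-level 9:1 split shares source segments between train and
  test; use `grouped=True` for session-level claims.
- The ellipse model ignores forearm cross-section eccentricity changes
  between views beyond the two measured girth axes.
- The built-in marker detector is intensity-based; real footage with
  clutter needs an ArUco-grade detector behind the same interface.
- Training is CPU-oriented; at full-scale parameters (1,000-sample
  windows, 30 epochs, large cohorts) a GPU implementation would be the
  practical choice.
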