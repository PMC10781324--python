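# Methods

## Problem and data model

A six-channel IMU stream pairs tri-axial acceleration (ax, ay, az, in g)
with tri-axial angular velocity (gx, gy, gz, in deg/s), sampled at 50 Hz.
The translation task maps a wrist-worn sensor's stream onto the stream a
tibia- or shoe-mounted sensor would record during the same walk. All
models consume and produce fixed 256-sample windows (5.12 s, at least two
full strides), with each channel min–max scaled to [0, 1].

Channel order is fixed as (ax, ay, az, gx, gy, gz) everywhere. Scaling is
per channel, fitted on the training split only, and reused verbatim for
validation, test and inference; out-of-range values at inference are
clipped to [0, 1] and zero-range channels map to 0. This keeps model
inputs bounded and prevents information leaking from the evaluation splits
into the scaler. Windows are cut with hop = length (no overlap) by
default; the hop is configurable.

## Architectures

All four models share the 256×6 → 256×6 contract and kernel size 3:

* **dense_ae** — Flatten(1536) → Dense 512/256/128 ReLU (encoder) → Dense
  256/512 ReLU → Dense 1536 sigmoid → Reshape(256, 6). The output layer
  must emit 256·6 = 1536 values for the reshape to close, which fixes its
  width at 1536.
* **cnn_ae** — Conv64 → MaxPool2 → Conv128 → MaxPool2 → Conv256 (encoder;
  lengths 256→128→64) → TranspConv 256 (stride 2) → TranspConv 128
  (stride 2) → TranspConv 64 (stride 1) → Conv6 sigmoid (lengths
  64→128→256→256). Convolutions are length-preserving (symmetric zero
  padding); the transposed-conv strides (2, 2, 1) mirror the two pooling
  steps — this is the unique stride assignment that restores length 256.
  Pooling is activation-free.
* **cnn_lstm** — Conv64 ReLU → LSTM64 → LSTM6, both LSTMs returning full
  sequences so one call translates a whole window. The tanh head's
  (−1, 1) range covers the (0, 1) target band, so no extra squashing layer
  is added; predictions are clipped to [0, 1] before inverse scaling.
* **unet** — the cnn_ae layout with the 128-filter (length 128) and
  64-filter (length 256) contraction activations concatenated onto the
  expansion at matching lengths, giving 384- and 192-channel inputs to the
  second and third transposed convolutions.

Because no deep-learning framework is part of the dependency set, the
layers (dense, 1-D convolution, max-pooling, transposed convolution, LSTM)
and Adam live in a small NumPy engine (`imugait.nn`). Transposed
convolution is implemented as zero-stuffing by the stride followed by a
length-preserving convolution. Every layer's analytic gradient is verified
against central differences in the test suite. Weights initialise from a
uniform fan-in-scaled distribution driven by the model seed, making every
build and training run bit-reproducible.

## Training protocol

The autoencoder-style models (dense_ae, cnn_ae, unet) train in three
stages: (1) unsupervised pretraining on wrist windows (input = label);
(2) encoder frozen, reconstruction layers trained on aligned wrist→target
pairs; (3) fine-tuning with the encoder unfrozen at a ten-fold lower
learning rate. The CNN-LSTM has no encoder/decoder split and trains in a
single supervised stage.

Fixed choices: MSE loss, Adam at 1e-3 (fine-tuning 1e-4), window-level
70/15/15 train/validation/test split by a seeded permutation with sizes
(floor 0.70n, floor 0.15n, remainder). Epoch count (default 100), batch
size (32) and early stopping (patience 10 epochs on validation loss, best
weights restored) are package defaults chosen for desk-scale determinism;
they are configuration, not protocol. Tiny datasets whose 15% validation
share floors to zero fall back to monitoring the training loss. Frozen
layers still propagate gradients but are skipped by the optimizer, so
their weights stay bit-identical through a training stage.

## Evaluation

Per-channel MAE and RMSE are computed after inverse scaling, in physical
units (g, deg/s), pooling all samples of all test windows rather than
averaging per-window metrics — the simplest unbiased pooling; the
difference is second order. The architecture comparison table evaluates
every model on the same held-out test set.

## Gait-parameter estimation

Gyro-y and the angular-velocity resultant are filtered with a zero-phase
(forward–backward) Butterworth low-pass, default order 4 and 5 Hz cutoff
(the reference event-detection setting is 12 Hz; the narrower band
suppresses reconstruction noise). Order and phase convention are package
choices: zero-phase filtering avoids biasing event times.

Both toe-offs and heel strikes appear as peaks in (optionally inverted)
gyro-y. The swing phase drives the resultant above a threshold (default
50 deg/s, configurable — it should sit well below the swing plateau of the
data at hand); each upward crossing starts a cycle, the candidate peak
nearest the crossing is labelled toe-off, and the peak at the far boundary
of the cycle heel strike. Candidate peaks are prominence-selected (default
20% of max |gyro-y|). Peaks between the two boundary peaks of a cycle are
discarded, and any remaining same-label adjacent pair keeps only its more
prominent member, so the output always alternates TO/HS. Fewer than one
full cycle yields empty events, not an error. `invert_y` defaults to true
for shoe-site signals, whose swing lobe polarity is opposite the
convention the peak rule assumes.

Stride duration is the difference between successive heel strikes; "gait
duration" is half the stride — the single-foot step-duration estimate
(a 1.136 s stride gives a 0.568 s gait duration); stance runs from a
heel strike to the next toe-off and swing from a toe-off to the next heel
strike, averaged over all complete cycles. Comparisons between a reference
and a test parameter set report absolute differences in milliseconds.

## Synthetic gait simulator

The generator emulates the qualitative site contrast of real walking
recordings: lower-limb signals with distinct short peaks (sharp gyro
spikes at toe-off and heel strike, a high acceleration transient at heel
strike) on a smooth swing lobe, versus a smooth, sine-like wrist signal.

Construction per session: stride periods are drawn as
stride_period + N(0, period_jitter_sd) (defaults 1.1 s, 0.02 s); heel
strikes accumulate those periods and each toe-off precedes its heel strike
by the swing share (1 − stance_fraction, default stance 0.6) of the
stride. Event times snap to the 50 Hz grid and are reported exactly as
ground truth. Shoe gyro-y is a positive half-sine swing lobe (200 deg/s)
between toe-off and heel strike plus two narrow negative Gaussian spikes
(σ = 20 ms, 300 deg/s) at the event samples, so a 50 Hz grid resolves them
with 2–3 samples; because the spikes sit at the lobe boundaries, the
filtered resultant rises through the detector threshold exactly once per
cycle. Acceleration channels carry a 3 g Gaussian transient at each heel
strike over a 1 g gravity baseline. The tibia is a 0.6× attenuated,
lightly smoothed copy of the shoe. The wrist is derived deterministically
from the shoe — 3 Hz zero-phase low-pass, gain 0.5, 0.15 s lag — plus a
per-channel arm-swing sinusoid at the stride frequency; this guarantees an
exactly invertible wrist→shoe relation, which grounds the learnability
tests. Additive white noise (sd in deg/s on gyro channels, 1% of that in
g on acceleration) comes from the single per-session generator, so a seed
fixes the session bit-for-bit.

What the simulator does **not** model: biomechanically faithful limb
kinematics, turning, stairs or running, sensor-axis misalignment between
sessions, drift, and multi-subject variability. Passing the learnability
tests therefore shows that the architectures, training protocol and event
detector behave correctly on a recoverable signal relation of the right
shape — not that wrist-worn hardware achieves any particular accuracy on
real walks.

## Reference experiment sizes

The bundled benchmark trains on 96 windows (~8.5 min of simulated walking)
with a 15/40/10-epoch pretrain/translate/fine-tune schedule over three
seeds — sizes chosen so the whole study runs in minutes on one CPU core
while leaving clear margins: the convolutional autoencoder and U-Net reach
scaled-unit test MAE well under 0.10 against a ~0.15 constant-mean
baseline, and the dense autoencoder trails both on every seed. The event
study uses a noiseless session (exact recovery, ±1 sample) and 20 noisy
sessions at gyro noise equal to 10% of the swing amplitude (mean stride
within one sample period). The wrist-only pretraining corpus of the full
protocol is emulated by the translation windows themselves at this scale;
`fit(X, y, X_pretrain=...)` accepts a larger separate corpus.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; it is meant for
  desk-scale studies, not for the multi-hour corpora the full protocol
  targets.
* The detector's threshold and prominence defaults assume amplitudes in
  the range the simulator produces; very low-amplitude recordings need the
  configurable values adjusted.
* Min–max scaling is sensitive to outliers in the training split; robust
  quantile scaling was deliberately not used to keep the inference
  contract simple and invertible.
* The window-level split means windows from the same session can appear in
  train and test; with the deterministic simulator this is intended (the
  task is learnability, not generalisation across subjects).
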