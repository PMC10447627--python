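# Methods

## Problem and signal model

A 4-channel A-mode ultrasound system strapped to a transfemoral residual limb
returns, at an 80 Hz tick clock, one 997-sample echo-amplitude profile per
tick, cycling through the channels round-robin (channels 1/3 anterior over
the quadriceps, 2/4 posterior over the hamstrings; each muscle group is
therefore sampled at 40 Hz). The 997 samples span 3.94 cm of tissue
(≈0.00395 cm/sample). Muscle deformation through the gait cycle moves the
high-echogenicity boundaries, so echo-peak depths carry information about the
concurrent knee and ankle kinematics of the prosthesis. The pipeline maps
each tick's ultrasound state to the four joint variables — knee position
(deg), knee velocity (deg/s), ankle position (deg), ankle velocity (deg/s) —
with one independently trained regression network per variable.

## Feature reduction

Per frame: (1) offset removal — subtract the frame mean (the simplest DC
removal; config-switchable to a fixed value or none); (2) rectification —
absolute value; (3) envelope — 77-point centered moving average. The window
runs over *depth*, not time, so a centered (non-causal) window is appropriate
even for online use. At the boundaries the mean is taken over the truncated
window (config-switchable to zero-padding; truncation avoids artificial edge
dips in echo envelopes); (4) trim the deepest 37 samples (997 → 960);
(5) partition into 48 contiguous non-overlapping 20-sample windows in depth
order and take each window's mean. Result: 48 non-negative features per
frame, each summarizing ≈0.08 cm of depth. The reduction is linear in the
rectified signal, hence scale-equivariant about the frame mean, and invariant
to permutations within a 20-sample window.

## Stream assembly and split

A 192-element feature vector holds the most recent 48-feature block from each
channel; each tick overwrites exactly one block. Emission starts at tick 3
(0-based), the first tick at which all four channels have reported — the
first three ticks are discarded rather than zero-filled, so no training row
contains fabricated data (≤37.5 ms of signal lost per trial). Labels are the
kinematic values at the emission tick (concurrent prediction, no lead/lag).
Block order is fixed as channel-number order; the models are channel-agnostic
but the order must be frozen for reproducibility. The protocol uses four
trials per subject: two normal-speed trials train, one normal-speed and one
fast-speed trial test; feature overlap between consecutive rows never crosses
a trial boundary, and the same trained models score both test sets.

## Regression networks

Architecture 192 → 10 → 10 → 10 → 1, ReLU after each hidden layer, linear
output, MSE loss: 2161 trainable parameters. Training details that the
protocol leaves open are fixed as: per-feature standardization computed from
the training rows; full-batch L-BFGS; max 1000 iterations; tolerance 1e-6; no
regularization (alpha = 0); seeded initialization, so a fixed seed and data
reproduce the model exactly. Non-convergence within the iteration budget is
recorded (a NaN sentinel appended to the loss trace and `converged_=False`)
and the model is still returned. The four variables are fit independently;
consequently predicted velocities are *not* the derivative of predicted
positions, and the tests assert that non-equality.

## Evaluation

- **nRMSE** = 100·RMSE / (max − min of the *recorded* signal over the
  evaluated test trial). Range normalization is the denominator consistent
  with the published RMSE↔nRMSE pairs for this protocol (e.g. a knee-position
  pair of 6.0 deg ↔ 9.0% implies a ≈67 deg evaluated range, physiologically
  plausible for walking; the other pairs imply ≈830 deg/s knee-velocity,
  ≈22 deg ankle, ≈280 deg/s ankle-velocity ranges, likewise plausible).
  Config-switchable to sd or mean normalization. nRMSE is reported on
  **unfiltered** predictions.
- **Causal filter**: 2nd-order low-pass Butterworth, 7 Hz cutoff at 80 Hz
  (within the optimal band for walking kinematics), designed by bilinear
  transform and applied forward-only, with the initial state set to the
  steady-state response of the first sample (suppresses the startup
  transient; constants pass through exactly). Forward-only filtering is what
  an online controller could use; its phase lag is the price. Filtered
  predictions feed the delay, peak-timing and range analyses.
- **Delay**: lag maximizing the normalized cross-correlation (both signals
  mean-removed) within ±0.25 s; positive = prediction lags; reported in ms at
  12.5 ms/sample. A peak correlation below 0.5 flags the estimate unreliable;
  delay is reported only for the normal-speed set, since large fast-set
  errors make the correlation unreliable. Note the filter alone contributes
  exactly 2 samples (25 ms) of lag: its impulse response peaks at sample 2.
- **Gait-cycle averaging**: strides run heel strike to heel strike; each is
  linearly resampled to 101 points (0–100% of gait) and averaged pointwise.
- **Peak timing**: (pct_predicted − pct_recorded)/100 × stride_time × 1000,
  rounded to the nearest integer ms (half away from zero). Antisymmetric in
  its two percentage arguments.
- **Range metrics**: range ratio = 100·range(pred)/range(actual) on the mean
  cycles; peak shortfall = 100·(actual_peak − pred_peak)/actual_peak for the
  named extremum (minima compared by magnitude).

## Synthetic data generator

The generator defines the study conditions the pipeline is tested under; no
human recordings are distributed.

- **Gait**: stride times i.i.d. normal per stride, truncated positive —
  normal speed 1.2 ± 0.1 s, fast 1.0 ± 0.2 s. Positions are truncated Fourier
  series in normalized phase (H = 4 harmonics, amplitudes drawn with 1/h
  decay, uniform phases, rescaled to the target range of motion); velocities
  are the exact analytic phase-derivative divided by the instantaneous stride
  time. ROM defaults: knee 65°, ankle 20° — inferred from the published
  RMSE/nRMSE ratios for this protocol, since residual-limb kinematic ranges
  are not reported directly; they are assumptions, and flagged as such.
- **Echoes**: 3 reflectors per channel at baseline depths 0.6–3.2 cm,
  Gaussian pulses of 15 samples FWHM, amplitudes 0.6–1.2 with exponential
  depth attenuation (0.3 /cm), DC offset 0.5, white noise sd 0.05. Reflector
  depths move as d0 + a·f(phase) with a ∈ 0.15–0.35 cm and f a unit sinusoid
  of harmonic 1 or 2 (harmonic 0 denotes a monotone ramp, used in tests);
  depth excursions are validated against the 3.94 cm span at construction.
- **Trials**: default duration 8 s → 640 ticks/trial and 637 emitted rows,
  so two training trials yield ~1274 rows, the order of magnitude of a 10 m
  walk test. Stride events are the phase-wrap ticks (synthetic ground truth;
  no heel-strike detector is needed). One experiment seed fans out to
  profile/echo/trial/model sub-seeds through a seed sequence, making the
  entire run bit-reproducible.
- **Normal vs fast**: both profiles share one shape seed (same walker); the
  fast profile shortens strides and scales ROM by 1.15, emulating the larger
  joint excursions of faster walking. Because the echo-phase coupling is
  unchanged, a model trained at normal speed systematically under-ranges on
  the fast set — the extrapolation failure the protocol is designed to expose.

**What passing tests do and do not show.** The generator produces kinematics
that are exact functions of gait phase plus stride-time jitter, and echoes
whose deformation is a clean function of the same phase; real recordings add
sensor motion under the socket, tissue-property variation, fatigue, and
non-phase-locked voluntary activity. Recovery results on synthetic data
therefore validate the *pipeline arithmetic and learnability under the
assumed structure*, not clinical performance; conversely, the geometry,
timing, filtering, delay and peak-conversion checks are exact properties of
the method and transfer as-is.

## Numerical choices and degenerate inputs

Envelope boundary handling and offset mode as above; nRMSE raises a named
error for constant reference signals; cycle averaging requires ≥2 stride
events; range metrics reject zero reference range or peak; filter cutoffs at
or above Nyquist are rejected at spec construction; echo models whose depth
excursions leave the penetration span are rejected at construction, not at
render time. Derived seeds are kept below 2³¹. Delay search ties resolve to
the smallest lag scanned first (−max_lag upward); in practice the correlation
peak is unique on non-degenerate signals.

## Problem sizes

Defaults were chosen so a full experiment (4 trials × 640 frames, four
networks, both test sets) runs in seconds on one CPU, matching the scale of
the protocol it models (training sets of several hundred to ~1000 frames and
seconds-scale training per model).

## Known limitations

No tissue acoustics (speed of sound, time-gain compensation), no
biomechanically validated muscle model, no socket–limb interaction forces, no
heel-strike detection for real data (stride events must be supplied), no
inter-subject pooling, and no online/real-time path — the filtering is causal
precisely so the offline results speak to online feasibility, but the
implementation is offline.
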