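# sonokin

Offline analysis pipeline mapping **A-mode ultrasound sonomyography** from a
transfemoral residual limb to **prosthesis knee/ankle kinematics** during
level-ground walking.

A wearable 4-channel A-mode ultrasound system polls its transducers
round-robin at 80 Hz (one channel refreshed per 12.5 ms tick, full refresh in
50 ms). Each reading is a 1-D echo-amplitude profile of 997 samples spanning
3.94 cm of soft tissue: peaks mark high-echogenicity boundaries (muscle
fascia) whose depths shift as the residual-limb muscles deform through the
gait cycle. The pipeline asks whether those deformations predict the walking
kinematics of the prosthetic knee and ankle.

## Method

1. **Feature reduction** (per frame): subtract the frame mean, rectify
   (|x − x̄|), smooth with a 77-point centered moving average to get the
   envelope, drop the deepest 37 samples (997 → 960), and average 48
   contiguous 20-sample windows → 48 features, ≈0.08 cm of depth each.
2. **Stream assembly**: at every tick the refreshed channel overwrites its
   48-feature block inside a 192-feature vector (channel c at positions
   48(c−1)…48c−1); rows are emitted once all four channels have reported
   (tick 3), labeled with the concurrent kinematics. Of four walking trials,
   two train and two (one normal-speed, one fast-speed) test; rows never
   cross trials.
3. **Regression**: one small network per joint variable (knee position, knee
   velocity, ankle position, ankle velocity) — 192 → 10 → 10 → 10 → 1 with
   ReLU activations (2161 parameters), minimizing MSE on standardized inputs
   (full-batch L-BFGS, seeded).
4. **Evaluation**: RMSE and range-normalized RMSE
   (nRMSE = 100·RMSE/(max−min) of the recording) on unfiltered predictions; a
   causal (one-way) 2nd-order 7 Hz Butterworth filter before delay, peak-timing
   and range analyses; cross-correlation delay (±0.25 s window, flagged
   unreliable below 0.5 peak correlation); stride-averaged 0–100% gait cycles;
   peak timing converted from gait-% to ms; range-ratio and peak-shortfall
   metrics.

No recordings are deposited for this kind of study, so a first-class
**synthetic-data module** generates trials with the structure the analysis
assumes: stride times ~N(1.2, 0.1²) s (normal) or N(1.0, 0.2²) s (fast),
truncated-Fourier knee/ankle trajectories (knee ROM 65°, ankle 20°; velocities
the exact analytic derivative), and echo trains whose Gaussian reflector
pulses move with gait phase. See `docs/methods.md`.

## Worked example

```python
from sonokin import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(seed=1))
print(result.report.summary_markdown())
```

prints (about 10 s on one CPU):

| test set | variable | RMSE | nRMSE % | filtered nRMSE % | delay ms |
|---|---|---|---|---|---|
| normal_test | knee_pos | 1.10 | 1.7 | 8.1 | 37.5 |
| normal_test | knee_vel | 20.53 | 3.2 | 11.7 | 37.5 |
| normal_test | ankle_pos | 0.37 | 1.8 | 7.8 | 37.5 |
| normal_test | ankle_vel | 6.20 | 3.0 | 10.3 | 37.5 |
| fast_test | knee_pos | 4.03 | 5.4 | 13.5 | - |
| fast_test | knee_vel | 136.31 | 8.5 | 12.6 | - |
| fast_test | ankle_pos | 1.16 | 5.1 | 12.6 | - |
| fast_test | ankle_vel | 39.70 | 7.7 | 11.4 | - |

Reading the table: the four networks recover the held-out normal-speed
kinematics to within a few percent of each signal's range (RMSE in deg or
deg/s, nRMSE as % of range). The fast-speed set is strictly worse — the model
extrapolates to stride times and ranges it never saw — and causal filtering
raises nRMSE because of the phase lag it introduces (here ≈37.5 ms by
cross-correlation, i.e. 3 ticks; delay is only reported for the normal-speed
set, where correlations are reliable). `result.report.scores` additionally
holds per-variable gait-cycle peak timings and range ratios; e.g. the fast-set
knee-velocity range ratio drops to ≈48%, the under-ranging signature of
extrapolation.

The same experiment runs from the shell:

```bash
sonokin run-all --seed 1 --out report.json
# or stepwise: sonokin simulate / features / train / evaluate
```

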