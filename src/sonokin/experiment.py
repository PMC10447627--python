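"""One-command end-to-end synthetic experiment.

Simulates four walking trials for one synthetic subject (two normal-
speed training trials, one normal-speed and one fast-speed test trial),
extracts features, assembles the supervised datasets, trains the four
per-variable networks on the pooled training rows, and scores them —
all deterministically from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import EvalReport, FilterSpec, evaluate_experiment
from .features import FrameFeatureExtractor
from .io import ExperimentConfig
from .model import KinematicsRegressor
from .stream import SupervisedDataset, build_supervised_dataset, split_trials
from .synth import (
    KINEMATIC_VARIABLES,
    TrialRecording,
    make_echo_model,
    make_gait_profile,
    simulate_trial,
)


@dataclass
class ExperimentResult:
    """Report plus the fitted artifacts, for inspection and reuse."""

    report: EvalReport
    models: dict[str, KinematicsRegressor]
    train_datasets: dict[str, SupervisedDataset]  # pooled rows per variable
    trials: dict[str, object]                     # split_trials partition
    extractor: FrameFeatureExtractor


def _derive_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 for downstream consumers
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def simulate_subject(config: ExperimentConfig) -> list[TrialRecording]:
    """Simulate the four trials of one synthetic subject.

    The normal and fast gait profiles share one shape seed (same walker)
    but differ in stride-time statistics and in range of motion (fast
    strides are shorter and cover a larger ROM, scaled by
    fast_rom_scale), so the fast test set probes extrapolation exactly
    as a faster self-selected pace does.
    """
    s_shape, s_echo, s_t1, s_t2, s_tn, s_tf, *_ = _derive_seeds(config.seed, 10)
    kw = dict(n_harmonics=config.n_harmonics, knee_rom_deg=config.knee_rom_deg,
              ankle_rom_deg=config.ankle_rom_deg)
    profile_normal = make_gait_profile("normal", s_shape, **kw)
    profile_fast = make_gait_profile("fast", s_shape, rom_scale=config.fast_rom_scale, **kw)
    echo = make_echo_model(s_echo, n_reflectors=config.n_reflectors,
                           pulse_fwhm_samples=config.pulse_fwhm_samples,
                           attenuation_per_cm=config.attenuation_per_cm,
                           dc_offset=config.dc_offset, noise_sd=config.noise_sd)
    dur = config.trial_duration_s
    return [simulate_trial(profile_normal, echo, dur, "train1", s_t1),
            simulate_trial(profile_normal, echo, dur, "train2", s_t2),
            simulate_trial(profile_normal, echo, dur, "normal_test", s_tn),
            simulate_trial(profile_fast, echo, dur, "fast_test", s_tf)]


def _pool_training_rows(trials, variable: str, extractor, warmup: int) -> SupervisedDataset:
    parts = [build_supervised_dataset(t, variable, extractor=extractor, warmup=warmup)
             for t in trials]
    return SupervisedDataset(X=np.vstack([p.X for p in parts]),
                             y=np.concatenate([p.y for p in parts]),
                             variable_name=variable, trial_role="train",
                             ticks=np.concatenate([p.ticks for p in parts]))


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Full pipeline: simulate -> features -> datasets -> 4 models -> report."""
    config = config or ExperimentConfig()
    seeds = _derive_seeds(config.seed, 10)
    model_seeds = dict(zip(KINEMATIC_VARIABLES, seeds[6:10]))
    split = split_trials(simulate_subject(config))
    extractor = FrameFeatureExtractor(frame_samples=config.frame_samples,
                                      offset=config.offset_mode,
                                      window=config.envelope_window,
                                      trim=config.trim_samples,
                                      n_windows=config.n_windows,
                                      win_len=config.window_len,
                                      edge_mode=config.edge_mode)
    models: dict[str, KinematicsRegressor] = {}
    train_datasets: dict[str, SupervisedDataset] = {}
    for var in KINEMATIC_VARIABLES:
        ds = _pool_training_rows(split["train"], var, extractor, config.warmup_ticks)
        train_datasets[var] = ds
        models[var] = KinematicsRegressor(hidden_widths=config.hidden_widths,
                                          max_iter=config.max_iter, tol=config.tol,
                                          alpha=config.alpha,
                                          random_state=model_seeds[var],
                                          variable_name=var).fit(ds.X, ds.y)
    spec = FilterSpec(order=config.filter_order, cutoff_hz=config.filter_cutoff_hz)
    report = evaluate_experiment(models,
                                 {"normal_test": split["normal_test"],
                                  "fast_test": split["fast_test"]},
                                 filter_spec=spec, extractor=extractor,
                                 norm=config.nrmse_norm, warmup=config.warmup_ticks)
    report.seed = config.seed
    report.config_hash = config.hash()
    return ExperimentResult(report=report, models=models,
                            train_datasets=train_datasets, trials=split,
                            extractor=extractor)
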