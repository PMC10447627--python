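"""Scoring of kinematic predictions against recorded trajectories.

Metrics: RMSE and range-normalized RMSE (reported on unfiltered
predictions), a causal (one-way) 2nd-order 7 Hz Butterworth filter whose
phase lag mimics what an online controller would see, cross-correlation
delay between filtered prediction and recording, stride-averaged gait
cycles on a 0-100% grid, peak-timing differences converted from gait
percent to milliseconds, and range/peak-shortfall ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sp_signal

from .acquisition import SAMPLE_RATE_HZ
from .errors import ConfigurationError, EvaluationError, InsufficientDataError
from .model import KinematicsRegressor
from .stream import WARMUP_TICKS, build_supervised_dataset
from .synth import KINEMATIC_VARIABLES, TrialRecording

TEST_SETS = ("normal_test", "fast_test")


@dataclass(frozen=True)
class FilterSpec:
    """Causal low-pass Butterworth: order 2, 7 Hz cutoff at 80 Hz."""

    order: int = 2
    cutoff_hz: float = 7.0
    sample_rate_hz: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_hz < self.sample_rate_hz / 2.0:
            raise ConfigurationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, "
                f"{self.sample_rate_hz / 2.0}) Hz (below Nyquist)")


@dataclass(frozen=True)
class DelayEstimate:
    """Cross-correlation delay; positive means the prediction lags."""

    delay_ms: float
    peak_correlation: float
    reliable: bool


def rmse_nrmse(pred, actual, norm: str = "range") -> tuple[float, float]:
    """RMSE and normalized RMSE (percent) of a prediction.

    norm selects the nRMSE denominator: "range" (max - min of the
    recorded signal over the evaluated segment; default), "sd" or "mean".
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size < 2:
        raise EvaluationError(
            f"pred and actual must share a length >= 2, got {pred.shape} vs {actual.shape}")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    if norm == "range":
        denom = float(actual.max() - actual.min())
    elif norm == "sd":
        denom = float(actual.std())
    elif norm == "mean":
        denom = float(np.abs(actual.mean()))
    else:
        raise ConfigurationError(f"norm must be 'range', 'sd' or 'mean', got {norm!r}")
    if denom == 0.0:
        raise EvaluationError(f"nRMSE undefined: {norm} of the recorded signal is zero")
    return rmse, 100.0 * rmse / denom


def butterworth_coefficients(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Digital (b, a) for the spec, designed by bilinear transform."""
    return sp_signal.butter(spec.order, spec.cutoff_hz,
                            fs=spec.sample_rate_hz, btype="low")


def causal_butterworth(x, spec: FilterSpec | None = None) -> np.ndarray:
    """Forward-only Butterworth filtering with steady-state initialization.

    The filter state is initialized to the steady-state response for the
    first sample value, so a constant input passes through unchanged and
    startup transients are suppressed.  The forward-only pass incurs the
    phase lag an online filter would.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise EvaluationError("cannot filter non-finite input")
    b, a = butterworth_coefficients(spec)
    zi = sp_signal.lfilter_zi(b, a) * x[0]
    y, _ = sp_signal.lfilter(b, a, x, zi=zi)
    return y


def estimate_delay(pred_filtered, actual, sample_rate_hz: float = SAMPLE_RATE_HZ,
                   max_lag_s: float = 0.25, min_correlation: float = 0.5) -> DelayEstimate:
    """Delay (ms) maximizing the normalized cross-correlation within +/-max_lag.

    Both signals are mean-removed internally.  Positive delay means the
    prediction lags the recording.  If the peak correlation falls below
    min_correlation the estimate is flagged unreliable (as happens when
    prediction error is large, e.g. on the fast-speed set).
    """
    p = np.asarray(pred_filtered, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise EvaluationError(f"signals must be equal-length 1-D, got {p.shape} vs {a.shape}")
    p = p - p.mean()
    a = a - a.mean()
    max_lag = int(round(max_lag_s * sample_rate_hz))
    if p.size <= max_lag + 2:
        raise InsufficientDataError("signals too short for the delay search window")
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = p[lag:], a[:a.size - lag]
        else:
            x, y = p[:p.size + lag], a[-lag:]
        denom = math.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
        r = float(np.dot(x, y)) / denom if denom > 0 else 0.0
        if r > best_r:
            best_lag, best_r = lag, r
    delay_ms = best_lag * 1000.0 / sample_rate_hz
    return DelayEstimate(delay_ms, best_r, best_r >= min_correlation)


def average_gait_cycle(signal_values, stride_events, n_points: int = 101) -> np.ndarray:
    """Stride-averaged signal on a 0-100% gait grid.

    Each stride (between consecutive heel-strike indices) is resampled
    by linear interpolation to n_points spanning 0-100% of the cycle,
    then averaged pointwise across strides.
    """
    x = np.asarray(signal_values, dtype=float)
    events = np.asarray(stride_events, dtype=int)
    if events.size < 2:
        raise InsufficientDataError("need at least 2 stride events to average a cycle")
    grid = np.linspace(0.0, 1.0, n_points)
    cycles = []
    for s, e in zip(events[:-1], events[1:]):
        seg = x[s:e + 1]
        t = np.linspace(0.0, 1.0, seg.size)
        cycles.append(np.interp(grid, t, seg))
    return np.mean(cycles, axis=0)


def peak_delay_ms(pct_predicted: float, pct_recorded: float, stride_time_s: float) -> int:
    """Gait-percent peak-timing difference converted to integer milliseconds.

    (pct_predicted - pct_recorded)/100 * stride_time * 1000, rounded to
    the nearest millisecond (half away from zero); antisymmetric in the
    two percentages.
    """
    ms = (pct_predicted - pct_recorded) / 100.0 * stride_time_s * 1000.0
    return int(math.floor(ms + 0.5)) if ms >= 0 else -int(math.floor(-ms + 0.5))


def range_metrics(pred_cycle, actual_cycle, extremum: str = "max") -> dict[str, float]:
    """Range ratio and peak shortfall of a predicted vs recorded mean cycle.

    range_ratio_percent = 100 * range(pred) / range(actual);
    peak_shortfall_percent = 100 * (actual_peak - pred_peak) / actual_peak
    for the named extremum ("max" or "min"; "min" compares magnitudes of
    the negative-going peak).
    """
    p = np.asarray(pred_cycle, dtype=float)
    a = np.asarray(actual_cycle, dtype=float)
    if p.shape != a.shape:
        raise EvaluationError(f"cycles must share a grid, got {p.shape} vs {a.shape}")
    a_range = float(a.max() - a.min())
    if a_range == 0.0:
        raise EvaluationError("recorded cycle has zero range")
    out = {"range_ratio_percent": 100.0 * float(p.max() - p.min()) / a_range}
    if extremum == "max":
        peak_a, peak_p = float(a.max()), float(p.max())
    elif extremum == "min":
        peak_a, peak_p = -float(a.min()), -float(p.min())
    else:
        raise ConfigurationError(f"extremum must be 'max' or 'min', got {extremum!r}")
    if peak_a == 0.0:
        raise EvaluationError("recorded peak is zero; shortfall undefined")
    out["peak_shortfall_percent"] = 100.0 * (peak_a - peak_p) / peak_a
    return out


@dataclass
class VariableScores:
    """All metrics for one joint variable on one test set."""

    rmse: float
    nrmse_percent: float
    nrmse_filtered_percent: float
    delay_ms: float | None = None
    delay_correlation: float | None = None
    delay_reliable: bool | None = None
    peak_timings: list[dict] = field(default_factory=list)
    range_ratio_percent: float | None = None
    peak_shortfall_max_percent: float | None = None
    peak_shortfall_min_percent: float | None = None


@dataclass
class EvalReport:
    """Per-variable, per-test-set metrics for one experiment."""

    scores: dict[str, dict[str, VariableScores]]   # [test_set][variable]
    stride_time_s: dict[str, float]                # mean stride per test set
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    seed: int | None = None
    config_hash: str | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "filter": {"order": self.filter_spec.order,
                       "cutoff_hz": self.filter_spec.cutoff_hz,
                       "sample_rate_hz": self.filter_spec.sample_rate_hz},
            "stride_time_s": dict(self.stride_time_s),
            "scores": {ts: {var: vars(vs) for var, vs in per_var.items()}
                       for ts, per_var in self.scores.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary_markdown(self) -> str:
        lines = ["| test set | variable | RMSE | nRMSE % | filtered nRMSE % | delay ms |",
                 "|---|---|---|---|---|---|"]
        for ts, per_var in self.scores.items():
            for var, vs in per_var.items():
                delay = "-" if vs.delay_ms is None else f"{vs.delay_ms:.1f}"
                lines.append(f"| {ts} | {var} | {vs.rmse:.2f} | {vs.nrmse_percent:.1f} "
                             f"| {vs.nrmse_filtered_percent:.1f} | {delay} |")
        return "\n".join(lines)


def _row_aligned_events(trial: TrialRecording, warmup: int) -> np.ndarray:
    ev = trial.stride_events - warmup
    return ev[(ev >= 0) & (ev < trial.n_ticks - warmup)]


def evaluate_experiment(models: Mapping[str, KinematicsRegressor],
                        test_trials: Mapping[str, TrialRecording],
                        filter_spec: FilterSpec | None = None,
                        extractor=None, norm: str = "range",
                        warmup: int = WARMUP_TICKS) -> EvalReport:
    """Score the four trained models on the normal- and fast-speed test trials.

    RMSE/nRMSE use the unfiltered predictions; the causal filter is
    applied before delay, peak-timing and range analyses.  The delay is
    reported only for the normal-speed set (fast-speed correlations are
    unreliable by construction of the protocol).
    """
    spec = filter_spec or FilterSpec()
    missing = [v for v in KINEMATIC_VARIABLES if v not in models]
    if missing:
        raise ConfigurationError(f"missing models for variables {missing}")
    scores: dict[str, dict[str, VariableScores]] = {}
    stride_time_s: dict[str, float] = {}
    for test_set in TEST_SETS:
        if test_set not in test_trials:
            raise ConfigurationError(f"missing test trial {test_set!r}")
        trial = test_trials[test_set]
        events_rows = _row_aligned_events(trial, warmup)
        stride_time = float(np.diff(trial.stride_events).mean() / trial.sample_rate_hz)
        stride_time_s[test_set] = stride_time
        per_var: dict[str, VariableScores] = {}
        for var in KINEMATIC_VARIABLES:
            ds = build_supervised_dataset(trial, var, extractor=extractor, warmup=warmup)
            pred = models[var].predict(ds.X)
            rmse, nrmse = rmse_nrmse(pred, ds.y, norm=norm)
            filt = causal_butterworth(pred, spec)
            _, nrmse_filt = rmse_nrmse(filt, ds.y, norm=norm)
            vs = VariableScores(rmse=rmse, nrmse_percent=nrmse,
                                nrmse_filtered_percent=nrmse_filt)
            if test_set == "normal_test":
                d = estimate_delay(filt, ds.y, sample_rate_hz=trial.sample_rate_hz)
                vs.delay_ms = d.delay_ms
                vs.delay_correlation = d.peak_correlation
                vs.delay_reliable = d.reliable
            if events_rows.size >= 2:
                actual_cycle = average_gait_cycle(ds.y, events_rows)
                pred_cycle = average_gait_cycle(filt, events_rows)
                for extremum, fn in (("max", np.argmax), ("min", np.argmin)):
                    pct_rec = float(fn(actual_cycle))
                    pct_pred = float(fn(pred_cycle))
                    vs.peak_timings.append({
                        "extremum": extremum,
                        "pct_recorded": pct_rec,
                        "pct_predicted": pct_pred,
                        "delay_ms": peak_delay_ms(pct_pred, pct_rec, stride_time)})
                vs.range_ratio_percent = range_metrics(pred_cycle, actual_cycle)[
                    "range_ratio_percent"]
                for extremum, key in (("max", "peak_shortfall_max_percent"),
                                      ("min", "peak_shortfall_min_percent")):
                    peak = actual_cycle.max() if extremum == "max" else -actual_cycle.min()
                    if abs(peak) > 1e-9:
                        setattr(vs, key, range_metrics(pred_cycle, actual_cycle,
                                                       extremum=extremum)[
                            "peak_shortfall_percent"])
            per_var[var] = vs
        scores[test_set] = per_var
    return EvalReport(scores=scores, stride_time_s=stride_time_s, filter_spec=spec)
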