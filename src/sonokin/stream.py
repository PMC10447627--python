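"""Round-robin assembly of 192-feature vectors and the trial-level split.

At every 80 Hz tick exactly one channel delivers a fresh 48-feature
block; the feature vector holds the most recent block from each of the
four channels (channel c occupies positions (c-1)*48 .. c*48-1).  The
first vector is emitted once every channel has reported at least once
(tick 3, 0-based), so no row ever contains placeholder data.  Trials
never share rows: two trials train the models, one normal-speed and one
fast-speed trial test them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .acquisition import N_CHANNELS
from .errors import ConfigurationError, SequencingError
from .features import N_FEATURES_PER_CHANNEL, ChannelFeatures, FrameFeatureExtractor
from .synth import KINEMATIC_VARIABLES, TRIAL_ROLES, TrialRecording

N_FEATURES_TOTAL = N_CHANNELS * N_FEATURES_PER_CHANNEL  # 192
WARMUP_TICKS = N_CHANNELS - 1


@dataclass(frozen=True)
class FeatureVector:
    """The 192-element concatenation of the latest features of all channels."""

    values: np.ndarray
    tick: int
    updated_channel: int


@dataclass
class SupervisedDataset:
    """Tick-ordered (X, y) rows for one joint variable of one trial."""

    X: np.ndarray            # (T - warmup, 192)
    y: np.ndarray            # (T - warmup,)
    variable_name: str
    trial_role: str
    ticks: np.ndarray        # original trial tick of each row


def _block(channel: int) -> slice:
    return slice((channel - 1) * N_FEATURES_PER_CHANNEL,
                 channel * N_FEATURES_PER_CHANNEL)


def update_feature_vector(prev: FeatureVector, feats: ChannelFeatures) -> FeatureVector:
    """Fold one fresh channel block into the running feature vector."""
    if feats.tick != prev.tick + 1:
        raise SequencingError(
            f"tick discontinuity: previous vector at tick {prev.tick}, "
            f"features at tick {feats.tick}")
    if feats.channel not in range(1, N_CHANNELS + 1):
        raise ConfigurationError(f"channel must be 1..{N_CHANNELS}, got {feats.channel}")
    values = prev.values.copy()
    values[_block(feats.channel)] = feats.values
    return FeatureVector(values, feats.tick, feats.channel)


def build_supervised_dataset(trial: TrialRecording, variable_name: str,
                             extractor: FrameFeatureExtractor | None = None,
                             warmup: int = WARMUP_TICKS) -> SupervisedDataset:
    """Assemble the per-tick 192-feature rows and concurrent labels.

    Row t (t >= warmup) concatenates, per channel, the features of that
    channel's most recent frame at or before tick t; the label is the
    named joint variable at the same tick.  Equivalent to folding
    update_feature_vector over the trial's frames and discarding the
    warm-up ticks.
    """
    if variable_name not in KINEMATIC_VARIABLES:
        raise ConfigurationError(
            f"unknown variable_name {variable_name!r}; expected one of {KINEMATIC_VARIABLES}")
    if extractor is None:
        extractor = FrameFeatureExtractor()
    feats = extractor.fit_transform(trial.frames)  # (T, 48)
    n_ticks = feats.shape[0]
    if n_ticks <= warmup:
        raise ConfigurationError(
            f"trial of {n_ticks} ticks is shorter than the {warmup}-tick warm-up")
    ticks = np.arange(warmup, n_ticks)
    X = np.empty((ticks.size, N_FEATURES_TOTAL))
    for c in range(1, N_CHANNELS + 1):
        # most recent tick <= t whose round-robin channel is c
        src = ticks - ((ticks - (c - 1)) % N_CHANNELS)
        X[:, _block(c)] = feats[src]
    y = trial.kinematic(variable_name)[warmup:]
    return SupervisedDataset(X, y, variable_name, trial.trial_role, ticks)


def split_trials(trials: Iterable[TrialRecording]) -> Mapping[str, object]:
    """Role-driven partition into {train: [t1, t2], normal_test, fast_test}."""
    trials = list(trials)
    roles = [t.trial_role for t in trials]
    if sorted(roles) != sorted(TRIAL_ROLES):
        raise ConfigurationError(
            f"expected exactly one trial per role {TRIAL_ROLES}, got roles {roles}")
    by_role = {t.trial_role: t for t in trials}
    return {"train": [by_role["train1"], by_role["train2"]],
            "normal_test": by_role["normal_test"],
            "fast_test": by_role["fast_test"]}
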