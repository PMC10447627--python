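"""Configuration and trial persistence.

Trials round-trip losslessly through HDF5 (frames, kinematics, stride
events, role); experiment configuration lives in one YAML file whose
keys expose every pipeline constant and every choice the method leaves
open (offset mode, envelope edge handling, nRMSE normalization,
optimizer settings), so nothing is hidden.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import ConfigurationError, ParseError
from .synth import KINEMATIC_VARIABLES, TRIAL_ROLES, TrialRecording


@dataclass
class ExperimentConfig:
    """All knobs of one end-to-end synthetic experiment."""

    seed: int = 0
    # synthetic trials
    trial_duration_s: float = 8.0
    n_harmonics: int = 4
    knee_rom_deg: float = 65.0
    ankle_rom_deg: float = 20.0
    fast_rom_scale: float = 1.15
    n_reflectors: int = 3
    pulse_fwhm_samples: float = 15.0
    attenuation_per_cm: float = 0.3
    dc_offset: float = 0.5
    noise_sd: float = 0.05
    # feature geometry
    frame_samples: int = 997
    envelope_window: int = 77
    trim_samples: int = 37
    n_windows: int = 48
    window_len: int = 20
    offset_mode: str = "mean"
    edge_mode: str = "truncate"
    # stream
    warmup_ticks: int = 3
    # regressor
    hidden_widths: tuple[int, ...] = (10, 10, 10)
    max_iter: int = 1000
    tol: float = 1e-6
    alpha: float = 0.0
    # evaluation
    filter_order: int = 2
    filter_cutoff_hz: float = 7.0
    nrmse_norm: str = "range"

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(self.hidden_widths)
        if self.trim_samples + self.n_windows * self.window_len != self.frame_samples:
            raise ConfigurationError(
                f"geometry mismatch: trim {self.trim_samples} + "
                f"{self.n_windows}x{self.window_len} != frame length {self.frame_samples}")
        if self.trial_duration_s <= 0:
            raise ConfigurationError("trial_duration_s must be positive")

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["hidden_widths"] = list(self.hidden_widths)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ParseError(f"malformed YAML config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ParseError(f"config {path} must be a mapping, got {type(data).__name__}")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"config {path} has unknown keys {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_trial(trial: TrialRecording, path) -> None:
    """Persist one trial to an HDF5 file (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=trial.frames)
        f.create_dataset("channels", data=trial.channels)
        f.create_dataset("kinematics", data=trial.kinematics)
        f.create_dataset("stride_events", data=trial.stride_events)
        f.attrs["trial_role"] = trial.trial_role
        f.attrs["sample_rate_hz"] = trial.sample_rate_hz
        f.attrs["kinematic_variables"] = list(KINEMATIC_VARIABLES)


def read_trial(path) -> TrialRecording:
    """Load a trial written by write_trial, validating structure."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"trial file {path} does not exist")
    with h5py.File(path, "r") as f:
        for key in ("frames", "channels", "kinematics", "stride_events"):
            if key not in f:
                raise ParseError(f"trial file {path} is missing dataset {key!r}")
        frames = f["frames"][()]
        channels = f["channels"][()]
        kinematics = f["kinematics"][()]
        stride_events = f["stride_events"][()]
        role = f.attrs.get("trial_role")
        sample_rate = float(f.attrs.get("sample_rate_hz", 80.0))
    if role is None or role not in TRIAL_ROLES:
        raise ParseError(f"trial file {path} has missing/unknown trial_role {role!r}")
    if kinematics.shape[0] != frames.shape[0]:
        missing = frames.shape[0] - kinematics.shape[0]
        raise ParseError(
            f"trial file {path}: kinematics has {kinematics.shape[0]} ticks but frames "
            f"has {frames.shape[0]} ({missing:+d} tick mismatch; first divergent tick "
            f"{min(kinematics.shape[0], frames.shape[0])})")
    if channels.shape[0] != frames.shape[0]:
        raise ParseError(f"trial file {path}: channels/frames tick mismatch")
    if stride_events.size and (np.any(np.diff(stride_events) <= 0)
                               or stride_events.min() < 0):
        raise ParseError(f"trial file {path}: stride_events not strictly increasing")
    return TrialRecording(frames, channels, kinematics, stride_events,
                          str(role), sample_rate)
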