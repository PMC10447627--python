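"""Synthetic gait trials: periodic joint kinematics plus A-mode echo trains.

No public recordings exist for this kind of experiment, so the package
ships a generator that reproduces the statistical structure the analysis
assumes: a walker with stride times drawn around a speed-class mean
(normal: 1.2 +/- 0.1 s, fast: 1.0 +/- 0.2 s), smooth periodic knee/ankle
trajectories expressed as truncated Fourier series in normalized gait
phase, and per-channel echo trains whose reflector depths deform with
gait phase.  Velocities are the exact analytic phase-derivative of the
positions scaled by the instantaneous stride rate, so position and
velocity streams are mutually consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import (
    DEPTH_PER_SAMPLE_CM,
    FRAME_SAMPLES,
    N_CHANNELS,
    PENETRATION_DEPTH_CM,
    SAMPLE_RATE_HZ,
    channel_at_tick,
)
from .errors import ConfigurationError, DepthRangeError

KINEMATIC_VARIABLES = ("knee_pos", "knee_vel", "ankle_pos", "ankle_vel")
POSITION_VARIABLES = ("knee_pos", "ankle_pos")
TRIAL_ROLES = ("train1", "train2", "normal_test", "fast_test")

#: (stride_time_mean_s, stride_time_sd_s) per walking-speed class
SPEED_CLASSES = {"normal": (1.2, 0.1), "fast": (1.0, 0.2)}

_MIN_STRIDE_S = 0.2  # positivity floor for truncated stride-time draws


@dataclass(frozen=True)
class GaitProfile:
    """Periodic knee/ankle trajectories plus stride-time statistics.

    Positions (deg) are truncated Fourier series of normalized phase
    p in [0, 1); velocities (deg/s) are d(pos)/dp times the phase rate
    1/stride_time.
    """

    speed_class: str
    stride_time_mean: float
    stride_time_sd: float
    amplitudes: dict[str, np.ndarray]  # per position variable, (H,) deg
    phases: dict[str, np.ndarray]      # per position variable, (H,) rad
    offsets: dict[str, float]          # per position variable, deg

    def sample_stride_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n stride durations, normal truncated to be positive."""
        out = rng.normal(self.stride_time_mean, self.stride_time_sd, size=n)
        while np.any(out <= _MIN_STRIDE_S):
            bad = out <= _MIN_STRIDE_S
            out[bad] = rng.normal(self.stride_time_mean, self.stride_time_sd,
                                  size=int(bad.sum()))
        return out


@dataclass(frozen=True)
class KinematicsSample:
    """One 80 Hz sample of the four predicted joint variables."""

    knee_pos: float
    knee_vel: float
    ankle_pos: float
    ankle_vel: float
    tick: int = 0


@dataclass(frozen=True)
class RawFrame:
    """One 997-sample A-mode reading from one channel at one tick."""

    samples: np.ndarray
    channel: int
    tick: int = 0


@dataclass(frozen=True)
class EchoModel:
    """Parametric echo trains for the four channels.

    Each channel carries K Gaussian echo pulses.  Reflector k sits at a
    baseline depth d0 (cm) and moves as d0 + a * f(phase) where the
    phase-coupling f is sin(2*pi*h*phase + psi) for harmonic h >= 1 or
    the monotone ramp 2*phase - 1 for h == 0; f is bounded in [-1, 1]
    either way, so d0 +/- a must stay inside the 0..3.94 cm span.
    Pulse amplitude decays exponentially with depth (attenuation), and a
    DC offset plus white Gaussian noise complete the frame.
    """

    base_depths_cm: np.ndarray       # (4, K)
    mod_amps_cm: np.ndarray          # (4, K)
    amplitudes: np.ndarray           # (4, K)
    coupling_harmonics: np.ndarray   # (4, K) ints; 0 = monotone ramp
    coupling_phases: np.ndarray      # (4, K) rad
    pulse_fwhm_samples: float = 15.0
    attenuation_per_cm: float = 0.3
    dc_offset: float = 0.5
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.base_depths_cm, self.mod_amps_cm,
                                        self.amplitudes, self.coupling_harmonics,
                                        self.coupling_phases)}
        if len(shapes) != 1 or next(iter(shapes))[0] != N_CHANNELS:
            raise ConfigurationError(
                f"echo parameter arrays must share one ({N_CHANNELS}, K) shape, got {shapes}")
        lo = self.base_depths_cm - np.abs(self.mod_amps_cm)
        hi = self.base_depths_cm + np.abs(self.mod_amps_cm)
        if np.any(lo < 0.0) or np.any(hi > PENETRATION_DEPTH_CM):
            raise DepthRangeError(
                "modulated reflector depths leave the "
                f"[0, {PENETRATION_DEPTH_CM}] cm penetration span "
                f"(extremes {lo.min():.3f}..{hi.max():.3f} cm)")

    def reflector_depths(self, channel: int, phase: float) -> np.ndarray:
        """Instantaneous reflector depths (cm) for one channel at a phase."""
        c = channel - 1
        h = self.coupling_harmonics[c]
        psi = self.coupling_phases[c]
        p = phase % 1.0
        f = np.where(h > 0, np.sin(2.0 * np.pi * h * p + psi), 2.0 * p - 1.0)
        return self.base_depths_cm[c] + self.mod_amps_cm[c] * f


@dataclass
class TrialRecording:
    """Synchronized 80 Hz streams for one 10 m-walk-like trial."""

    frames: np.ndarray        # (T, 997)
    channels: np.ndarray      # (T,) channel refreshed at each tick
    kinematics: np.ndarray    # (T, 4) columns = KINEMATIC_VARIABLES
    stride_events: np.ndarray  # heel-strike tick indices, strictly increasing
    trial_role: str
    sample_rate_hz: float = SAMPLE_RATE_HZ

    @property
    def n_ticks(self) -> int:
        return self.frames.shape[0]

    def kinematic(self, name: str) -> np.ndarray:
        if name not in KINEMATIC_VARIABLES:
            raise ConfigurationError(
                f"unknown kinematic variable {name!r}; expected one of {KINEMATIC_VARIABLES}")
        return self.kinematics[:, KINEMATIC_VARIABLES.index(name)]


def make_gait_profile(speed_class: str, seed: int, *, n_harmonics: int = 4,
                      knee_rom_deg: float = 65.0, ankle_rom_deg: float = 20.0,
                      rom_scale: float = 1.0) -> GaitProfile:
    """Draw a seeded gait profile for one walking-speed class.

    Harmonic amplitudes are drawn with a 1/h decay and rescaled so the
    position range of motion over the cycle matches the requested ROM
    (knee default 65 deg, ankle 20 deg); phases are uniform.  The same
    seed yields the same trajectory shape for either speed class, so a
    normal/fast pair with one seed models one walker at two speeds.
    """
    if speed_class not in SPEED_CLASSES:
        raise ConfigurationError(
            f"unknown speed_class {speed_class!r}; expected one of {sorted(SPEED_CLASSES)}")
    mean, sd = SPEED_CLASSES[speed_class]
    rng = np.random.default_rng(seed)
    amplitudes: dict[str, np.ndarray] = {}
    phases: dict[str, np.ndarray] = {}
    offsets: dict[str, float] = {}
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    for var, rom, base_offset in (("knee_pos", knee_rom_deg, 32.0),
                                  ("ankle_pos", ankle_rom_deg, -5.0)):
        h = np.arange(1, n_harmonics + 1)
        amp = rng.uniform(0.5, 1.0, n_harmonics) / h
        psi = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
        series = np.sum(amp[:, None] * np.sin(2.0 * np.pi * h[:, None] * grid
                                              + psi[:, None]), axis=0)
        amp *= rom * rom_scale / (series.max() - series.min())
        amplitudes[var] = amp
        phases[var] = psi
        offsets[var] = base_offset + rng.uniform(-2.0, 2.0)
    return GaitProfile(speed_class, mean, sd, amplitudes, phases, offsets)


def kinematics_at(profile: GaitProfile, phase, stride_time: float | None = None,
                  tick: int = 0):
    """Evaluate the profile at a phase (wrapped modulo 1).

    Velocities are the analytic derivative of position with respect to
    phase divided by the stride time (default: the class mean), i.e.
    deg/s at the instantaneous phase rate.  Accepts scalar or array
    phase; returns a KinematicsSample for scalars, a dict of arrays
    otherwise.
    """
    st = profile.stride_time_mean if stride_time is None else float(stride_time)
    p = np.asarray(phase, dtype=float) % 1.0
    out: dict[str, np.ndarray] = {}
    for var in POSITION_VARIABLES:
        amp = profile.amplitudes[var]
        psi = profile.phases[var]
        h = np.arange(1, amp.size + 1)
        arg = 2.0 * np.pi * np.multiply.outer(h, p) + psi.reshape((-1,) + (1,) * p.ndim)
        pos = profile.offsets[var] + np.sum(amp.reshape((-1,) + (1,) * p.ndim)
                                            * np.sin(arg), axis=0)
        dpos_dphase = np.sum((amp * 2.0 * np.pi * h).reshape((-1,) + (1,) * p.ndim)
                             * np.cos(arg), axis=0)
        out[var] = pos
        out[var.replace("_pos", "_vel")] = dpos_dphase / st
    if p.ndim == 0:
        return KinematicsSample(*(float(out[v]) for v in KINEMATIC_VARIABLES), tick=tick)
    return out


def make_echo_model(seed: int, *, n_reflectors: int = 3,
                    pulse_fwhm_samples: float = 15.0,
                    attenuation_per_cm: float = 0.3,
                    dc_offset: float = 0.5, noise_sd: float = 0.05) -> EchoModel:
    """Draw a seeded echo model with n_reflectors Gaussian pulses per channel.

    Baseline depths are spread over 0.6-3.2 cm (sorted shallow to deep per
    channel), modulation amplitudes 0.15-0.35 cm, and phase couplings use
    harmonic 1 or 2 with uniform phase offsets, so the echo train deforms
    smoothly and distinctively with gait phase on every channel.
    """
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0.6, 3.2, (N_CHANNELS, n_reflectors)), axis=1)
    mod = rng.uniform(0.15, 0.35, (N_CHANNELS, n_reflectors))
    amps = rng.uniform(0.6, 1.2, (N_CHANNELS, n_reflectors))
    harmonics = rng.integers(1, 3, (N_CHANNELS, n_reflectors))
    psis = rng.uniform(0.0, 2.0 * np.pi, (N_CHANNELS, n_reflectors))
    return EchoModel(base, mod, amps, harmonics, psis,
                     pulse_fwhm_samples=pulse_fwhm_samples,
                     attenuation_per_cm=attenuation_per_cm,
                     dc_offset=dc_offset, noise_sd=noise_sd)


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def synth_raw_frame(echo_model: EchoModel, channel: int, phase: float,
                    rng: np.random.Generator | None = None, tick: int = 0) -> RawFrame:
    """Render one 997-sample frame for a channel at a gait phase.

    Samples = DC offset + sum over reflectors of
    amplitude * exp(-attenuation * depth) * Gaussian pulse centered at the
    sample index of the modulated depth, plus white noise if the model's
    noise_sd > 0 and an rng is supplied.
    """
    if channel not in range(1, N_CHANNELS + 1):
        raise ConfigurationError(f"channel must be 1..{N_CHANNELS}, got {channel}")
    idx = np.arange(FRAME_SAMPLES, dtype=float)
    depths = echo_model.reflector_depths(channel, phase)
    centers = depths / DEPTH_PER_SAMPLE_CM
    gains = (echo_model.amplitudes[channel - 1]
             * np.exp(-echo_model.attenuation_per_cm * depths))
    sigma = echo_model.pulse_fwhm_samples * _FWHM_TO_SIGMA
    pulses = gains[:, None] * np.exp(-0.5 * ((idx[None, :] - centers[:, None]) / sigma) ** 2)
    samples = echo_model.dc_offset + pulses.sum(axis=0)
    if rng is not None and echo_model.noise_sd > 0.0:
        samples = samples + rng.normal(0.0, echo_model.noise_sd, FRAME_SAMPLES)
    return RawFrame(samples, channel, tick)


def simulate_trial(profile: GaitProfile, echo_model: EchoModel, duration_s: float,
                   trial_role: str, seed: int) -> TrialRecording:
    """Simulate one trial of floor(duration * 80) ticks.

    Channels cycle 1,2,3,4; gait phase advances by dt/stride_time with a
    fresh stride time drawn at every phase wrap; heel-strike events are
    the ticks at which a new stride begins (including tick 0).  The same
    seed reproduces the trial bit for bit.
    """
    if duration_s <= 0:
        raise ConfigurationError(f"duration_s must be positive, got {duration_s}")
    if trial_role not in TRIAL_ROLES:
        raise ConfigurationError(
            f"unknown trial_role {trial_role!r}; expected one of {TRIAL_ROLES}")
    rng = np.random.default_rng(seed)
    n_ticks = int(math.floor(duration_s * SAMPLE_RATE_HZ))
    dt = 1.0 / SAMPLE_RATE_HZ
    frames = np.empty((n_ticks, FRAME_SAMPLES))
    channels = np.empty(n_ticks, dtype=np.int64)
    kin = np.empty((n_ticks, len(KINEMATIC_VARIABLES)))
    stride_time = float(profile.sample_stride_times(1, rng)[0])
    phase = 0.0
    events = [0]
    for t in range(n_ticks):
        ch = channel_at_tick(t)
        channels[t] = ch
        frames[t] = synth_raw_frame(echo_model, ch, phase, rng, tick=t).samples
        s = kinematics_at(profile, phase, stride_time, tick=t)
        kin[t] = (s.knee_pos, s.knee_vel, s.ankle_pos, s.ankle_vel)
        phase += dt / stride_time
        if phase >= 1.0:
            phase -= 1.0
            stride_time = float(profile.sample_stride_times(1, rng)[0])
            if t + 1 < n_ticks:
                events.append(t + 1)
    return TrialRecording(frames, channels, kin,
                          np.asarray(events, dtype=np.int64), trial_role)
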