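"""Reduction of one 997-sample A-mode frame to 48 windowed-envelope features.

Stages, in order: remove the DC offset (frame mean by default), rectify
(absolute value), smooth with a 77-point centered moving average to get
the envelope, drop the deepest 37 samples (997 -> 960), then partition
into 48 contiguous 20-sample windows and take each window's mean.  With
997 samples spanning 3.94 cm each feature summarizes ~0.08 cm of depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from sklearn.base import BaseEstimator, TransformerMixin

from .acquisition import FRAME_SAMPLES
from .errors import ConfigurationError, NonFiniteError, ShapeError
from .synth import RawFrame

N_FEATURES_PER_CHANNEL = 48
ENVELOPE_WINDOW = 77
TRIM_SAMPLES = 37
WINDOW_LEN = 20


@dataclass(frozen=True)
class ChannelFeatures:
    """The 48 windowed-mean features extracted from one frame."""

    values: np.ndarray
    channel: int
    tick: int = 0


def preprocess_frame(samples, offset: str | float = "mean",
                     n_samples: int = FRAME_SAMPLES) -> np.ndarray:
    """Offset-remove and rectify one raw frame: |x - offset|.

    offset: "mean" (default) subtracts the frame mean, "none" subtracts
    nothing, or a number subtracts that fixed value.
    """
    x = np.asarray(samples, dtype=float)
    if x.shape != (n_samples,):
        raise ShapeError(f"expected a frame of shape ({n_samples},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise NonFiniteError("frame contains non-finite samples")
    if offset == "mean":
        off = x.mean()
    elif offset == "none":
        off = 0.0
    elif isinstance(offset, (int, float)):
        off = float(offset)
    else:
        raise ConfigurationError(f"offset must be 'mean', 'none' or a number, got {offset!r}")
    return np.abs(x - off)


def envelope(x, window: int = ENVELOPE_WINDOW, edge_mode: str = "truncate") -> np.ndarray:
    """Centered moving-average envelope, same length as the input.

    edge_mode "truncate" (default) averages over the part of the window
    that overlaps the signal near the boundaries; "zero" pads with zeros
    and always divides by the full window length.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ConfigurationError(f"window must be odd and positive, got {window}")
    if window > x.size:
        raise ConfigurationError(f"window {window} exceeds signal length {x.size}")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    if edge_mode == "truncate":
        counts = np.convolve(np.ones(x.size), kernel, mode="same")
    elif edge_mode == "zero":
        counts = float(window)
    else:
        raise ConfigurationError(f"edge_mode must be 'truncate' or 'zero', got {edge_mode!r}")
    return sums / counts


def trim_and_window(env, trim: int = TRIM_SAMPLES,
                    n_windows: int = N_FEATURES_PER_CHANNEL,
                    win_len: int = WINDOW_LEN) -> np.ndarray:
    """Drop the deepest `trim` samples, then mean over contiguous windows.

    The retained samples are partitioned, in depth order, into n_windows
    non-overlapping windows of win_len samples; feature k is the mean of
    window k.
    """
    env = np.asarray(env, dtype=float)
    if trim + n_windows * win_len != env.size:
        raise ConfigurationError(
            f"geometry mismatch: trim {trim} + {n_windows}x{win_len} "
            f"!= signal length {env.size}")
    kept = env[:env.size - trim]
    return kept.reshape(n_windows, win_len).mean(axis=1)


def extract_channel_features(frame: RawFrame, offset: str | float = "mean",
                             window: int = ENVELOPE_WINDOW,
                             trim: int = TRIM_SAMPLES,
                             n_windows: int = N_FEATURES_PER_CHANNEL,
                             win_len: int = WINDOW_LEN,
                             edge_mode: str = "truncate") -> ChannelFeatures:
    """Full per-frame reduction: preprocess -> envelope -> trim & window."""
    x = preprocess_frame(frame.samples, offset=offset)
    env = envelope(x, window=window, edge_mode=edge_mode)
    values = trim_and_window(env, trim=trim, n_windows=n_windows, win_len=win_len)
    return ChannelFeatures(values, frame.channel, frame.tick)


class FrameFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping raw frames (n, 997) to features (n, 48).

    Stateless (fit is a no-op that validates geometry); exists so the
    reduction composes with sklearn pipelines and so whole trials can be
    transformed vectorized.  Parameters default to the device geometry:
    997 samples, 77-point envelope window, trim 37, 48 windows of 20.
    """

    def __init__(self, frame_samples: int = FRAME_SAMPLES, offset: str | float = "mean",
                 window: int = ENVELOPE_WINDOW, trim: int = TRIM_SAMPLES,
                 n_windows: int = N_FEATURES_PER_CHANNEL, win_len: int = WINDOW_LEN,
                 edge_mode: str = "truncate"):
        self.frame_samples = frame_samples
        self.offset = offset
        self.window = window
        self.trim = trim
        self.n_windows = n_windows
        self.win_len = win_len
        self.edge_mode = edge_mode

    def _validate_geometry(self) -> None:
        if self.window % 2 == 0 or not (1 <= self.window <= self.frame_samples):
            raise ConfigurationError(
                f"window must be odd and within 1..{self.frame_samples}, got {self.window}")
        if self.trim + self.n_windows * self.win_len != self.frame_samples:
            raise ConfigurationError(
                f"geometry mismatch: trim {self.trim} + {self.n_windows}x{self.win_len} "
                f"!= frame length {self.frame_samples}")
        if self.edge_mode not in ("truncate", "zero"):
            raise ConfigurationError(f"edge_mode must be 'truncate' or 'zero', "
                                     f"got {self.edge_mode!r}")

    def fit(self, X, y=None):
        self._validate_geometry()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.frame_samples:
            raise ShapeError(
                f"expected frames of shape (n, {self.frame_samples}), got {X.shape}")
        self.n_features_in_ = self.frame_samples
        return self

    def transform(self, X) -> np.ndarray:
        self._validate_geometry()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.frame_samples:
            raise ShapeError(
                f"expected frames of shape (n, {self.frame_samples}), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise NonFiniteError("frames contain non-finite samples")
        if self.offset == "mean":
            off = X.mean(axis=1, keepdims=True)
        elif self.offset == "none":
            off = 0.0
        elif isinstance(self.offset, (int, float)):
            off = float(self.offset)
        else:
            raise ConfigurationError(
                f"offset must be 'mean', 'none' or a number, got {self.offset!r}")
        rect = np.abs(X - off)
        kernel = np.ones(self.window)
        # zero-padded windowed sums along depth; divide by in-bounds counts
        sums = convolve1d(rect, kernel, axis=1, mode="constant", cval=0.0)
        if self.edge_mode == "truncate":
            counts = np.convolve(np.ones(self.frame_samples), kernel, mode="same")
            env = sums / counts[None, :]
        else:
            env = sums / self.window
        kept = env[:, :self.frame_samples - self.trim]
        return kept.reshape(X.shape[0], self.n_windows, self.win_len).mean(axis=2)
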