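"""Band-pass filtering, Hamming-tapered windowing, adaptive normalization.

The chain mirrors online myoelectric processing: a 10–500 Hz band-pass
removes baseline wander and high-frequency noise, running mean/SD
statistics with exponential forgetting normalize the stream and
compensate slow drift, and 10-s sliding windows with a Hamming taper
feed feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import EMGRecording

__all__ = [
    "SignalWindow",
    "bandpass_filter",
    "segment_windows",
    "adaptive_normalize",
    "AdaptiveNormalizer",
]


@dataclass
class SignalWindow:
    """One tapered window of one channel: samples (volts), start time."""

    samples: np.ndarray
    channel: int
    start_s: float
    sampling_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("a SignalWindow holds a single channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size


def bandpass_filter(rec: EMGRecording, lo: float, hi: float,
                    order: int = 4) -> EMGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    A 4th-order Butterworth run forward-backward (``sosfiltfilt``)
    realizes the stated band with zero phase distortion; length is
    preserved.
    """
    nyq = rec.sampling_rate / 2
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must lie below Nyquist {nyq} Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rec.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, rec.samples, axis=0)
    return EMGRecording(samples=filtered, sampling_rate=rec.sampling_rate,
                        meta=_dc_replace(rec.meta))


def window_count(n_samples: int, n_window: int, stride: int) -> int:
    """floor((L - N)/stride) + 1 windows fit in L samples."""
    if n_samples < n_window:
        raise ValueError("recording shorter than one window")
    return (n_samples - n_window) // stride + 1


def segment_windows(rec: EMGRecording, window_s: float, overlap: float,
                    taper: bool = True) -> list[list[SignalWindow]]:
    """Cut each channel into Hamming-tapered sliding windows.

    Returns one list of :class:`SignalWindow` per channel; window k of
    every channel covers the same time span.  Stride is
    ``N * (1 - overlap)`` samples.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    n_window = int(round(window_s * rec.sampling_rate))
    if n_window < 2:
        raise ValueError("window too short at this sampling rate")
    stride = max(1, int(round(n_window * (1 - overlap))))
    count = window_count(rec.n_samples, n_window, stride)
    ham = np.hamming(n_window) if taper else np.ones(n_window)
    out: list[list[SignalWindow]] = []
    for c in range(rec.n_channels):
        chan = []
        for k in range(count):
            start = k * stride
            chan.append(SignalWindow(
                samples=rec.samples[start:start + n_window, c] * ham,
                channel=c,
                start_s=start / rec.sampling_rate,
                sampling_rate=rec.sampling_rate,
            ))
        out.append(chan)
    return out


class AdaptiveNormalizer:
    """Running mean/SD with exponential forgetting, per channel.

    Emulates background statistics that update asynchronously while the
    stream is processed: each incoming block is transformed with the
    statistics accumulated so far, ``(x - mean) / sd``, then the
    statistics decay toward the new block with half-life
    ``half_life_s`` (default 10 s).

    The mean estimate uses Holt's level + trend smoothing (level
    half-life ``half_life_s``, trend half-life half of that): a single
    EWMA lags a linear ramp by roughly its half-life and therefore
    never removes steady drift, while the trend term tracks a ramp
    with no asymptotic error.  The variance uses a plain EWMA at the
    same half-life.
    """

    def __init__(self, half_life_s: float = 10.0, eps: float = 1e-12):
        if half_life_s <= 0:
            raise ValueError("half-life must be positive")
        self.half_life_s = half_life_s
        self.eps = eps
        self._level: np.ndarray | None = None
        self._trend: np.ndarray | None = None
        self._var: np.ndarray | None = None

    def _decay(self, block_duration_s: float, half_life_s: float) -> float:
        return 0.5 ** (block_duration_s / half_life_s)

    @property
    def mean(self) -> np.ndarray | None:
        """Current drift-compensated mean prediction."""
        if self._level is None:
            return None
        return self._level + self._trend

    def process(self, block: np.ndarray, sampling_rate: float) -> np.ndarray:
        """Normalize one (n_samples, n_channels) block, update stats."""
        block = np.atleast_2d(np.asarray(block, dtype=float))
        m = block.mean(axis=0)
        v = block.var(axis=0)
        if self._level is None:
            self._level = m.copy()
            self._trend = np.zeros_like(m)
            self._var = v.copy()
        sd = np.sqrt(self._var)
        guarded = sd < self.eps
        if np.any(guarded):
            warnings.warn("zero moving SD; using unit divisor", RuntimeWarning)
        out = (block - self.mean) / np.where(guarded, 1.0, sd)
        dt_s = block.shape[0] / sampling_rate
        a = self._decay(dt_s, self.half_life_s)
        a_t = self._decay(dt_s, self.half_life_s / 2.0)
        new_level = a * (self._level + self._trend) + (1 - a) * m
        self._trend = a_t * self._trend + (1 - a_t) * (new_level - self._level)
        self._level = new_level
        self._var = a * self._var + (1 - a) * v
        return out


def adaptive_normalize(rec: EMGRecording, half_life_s: float = 10.0,
                       block_s: float = 1.0) -> EMGRecording:
    """Stream *rec* through an :class:`AdaptiveNormalizer` block-wise.

    The first block initializes the statistics (so a constant stream
    maps to zeros from the start).  Output is dimensionless.
    """
    norm = AdaptiveNormalizer(half_life_s=half_life_s)
    n_block = max(1, int(round(block_s * rec.sampling_rate)))
    blocks = []
    for start in range(0, rec.n_samples, n_block):
        blocks.append(norm.process(rec.samples[start:start + n_block],
                                   rec.sampling_rate))
    return EMGRecording(samples=np.vstack(blocks),
                        sampling_rate=rec.sampling_rate,
                        meta=_dc_replace(rec.meta))
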