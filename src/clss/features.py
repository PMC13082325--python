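"""The 18 per-channel window features and the 3-D feature tensor.

Fourteen time-domain descriptors and four frequency-domain descriptors
are computed per channel per window.  With x_i (i = 1..N) the window
samples:

========  =====================================================
ME        mean energy, (1/N) sum x_i^2
EMAV      enhanced mean absolute value, (1/N) sum |x_i|^{p_i},
          p_i = 0.75 on the central 0.2N..0.8N span, else 0.5
AAC       average amplitude change, (1/(N-1)) sum |x_{i+1}-x_i|
MFL       maximum fractal length, log10 sqrt(sum (x_{i+1}-x_i)^2)
SKEW      standardized third moment
KURT      excess kurtosis (Gaussian -> 0)
VAR, SD   population variance / standard deviation (1/N)
RMS       sqrt(ME)
ZCR       zero crossings, #{i : x_i * x_{i+1} < 0}
IEMG      signal integration, sum |x_i|
ASS       |sum sign(x_i) sqrt(|x_i|)|
WAMP      Willison amplitude, #{i : |x_{i+1}-x_i| >= T}
LOGD      log detector, exp((1/N) sum ln(|x_i| + eps))
RLOW/RMID/RHIGH  spectral energy fractions below 20 Hz, 20-50 Hz,
          above 50 Hz (Welch PSD)
MDF       median frequency of the PSD, Hz
========  =====================================================

The tensor stacks windows x channels x 18 with per-feature z-scoring
fitted on the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .preprocess import SignalWindow

__all__ = [
    "FEATURE_NAMES",
    "TIME_DOMAIN_NAMES",
    "FREQ_DOMAIN_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "FeatureTensor",
    "build_feature_tensor",
]

TIME_DOMAIN_NAMES = (
    "ME", "EMAV", "AAC", "MFL", "SKEW", "KURT", "VAR", "SD", "RMS",
    "ZCR", "IEMG", "ASS", "WAMP", "LOGD",
)
FREQ_DOMAIN_NAMES = ("RLOW", "RMID", "RHIGH", "MDF")
FEATURE_NAMES = TIME_DOMAIN_NAMES + FREQ_DOMAIN_NAMES

#: Willison-amplitude threshold, in the (normalized, dimensionless)
#: units the windows carry after adaptive normalization.
DEFAULT_WAMP_THRESHOLD = 0.1

#: Guard for LOGD (and silent windows generally).
EPS = 1e-12


def time_domain_features(window: SignalWindow,
                         wamp_threshold: float = DEFAULT_WAMP_THRESHOLD,
                         ) -> dict[str, float]:
    """The 14 time-domain features of one window.

    All-zero windows are legal: MFL and LOGD fall back to the epsilon
    guard rather than raising.
    """
    x = window.samples
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(x)
    absx = np.abs(x)

    me = float(np.mean(x**2))
    i = np.arange(1, n + 1)
    p = np.where((i >= 0.2 * n) & (i <= 0.8 * n), 0.75, 0.5)
    emav = float(np.mean(absx**p))
    aac = float(np.mean(np.abs(dx)))
    mfl = float(np.log10(np.sqrt(np.sum(dx**2)) + EPS))
    sd = float(np.std(x))
    var = float(np.var(x))
    centered = x - x.mean()
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4 - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    rms = float(np.sqrt(me))
    zcr = int(np.count_nonzero(x[:-1] * x[1:] < 0))
    iemg = float(np.sum(absx))
    ass = float(abs(np.sum(np.sign(x) * np.sqrt(absx))))
    wamp = int(np.count_nonzero(np.abs(dx) >= wamp_threshold))
    logd = float(np.exp(np.mean(np.log(absx + EPS))))
    return {
        "ME": me, "EMAV": emav, "AAC": aac, "MFL": mfl, "SKEW": skew,
        "KURT": kurt, "VAR": var, "SD": sd, "RMS": rms, "ZCR": zcr,
        "IEMG": iemg, "ASS": ass, "WAMP": wamp, "LOGD": logd,
    }


def frequency_domain_features(window: SignalWindow,
                              sampling_rate: float | None = None,
                              ) -> dict[str, float]:
    """Band-energy ratios (<20, 20–50, >50 Hz) and median frequency.

    Welch PSD with 1-s Hamming segments at 50% overlap.  The three
    ratios sum to one; MDF is the smallest frequency at which the
    cumulative PSD reaches half the total.
    """
    fs = sampling_rate if sampling_rate is not None else window.sampling_rate
    x = window.samples
    if x.size < fs:
        raise ValueError("need at least one second of data for the PSD")
    nperseg = int(round(fs))
    f, p = welch(x, fs=fs, window="hamming", nperseg=nperseg,
                 noverlap=nperseg // 2)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power; cannot form spectral ratios")
    rlow = float(p[f < 20].sum() / total)
    rmid = float(p[(f >= 20) & (f <= 50)].sum() / total)
    rhigh = float(p[f > 50].sum() / total)
    cum = np.cumsum(p)
    mdf = float(f[np.searchsorted(cum, 0.5 * total)])
    return {"RLOW": rlow, "RMID": rmid, "RHIGH": rhigh, "MDF": mdf}


def extract_features(window: SignalWindow,
                     wamp_threshold: float = DEFAULT_WAMP_THRESHOLD,
                     ) -> np.ndarray:
    """All 18 features of one window, ordered as :data:`FEATURE_NAMES`."""
    feats = time_domain_features(window, wamp_threshold)
    feats.update(frequency_domain_features(window))
    return np.array([feats[k] for k in FEATURE_NAMES])


@dataclass
class FeatureTensor:
    """The 3-D dataset: windows x channels x 18, plus labels.

    ``zscore_mean`` / ``zscore_sd`` hold the per-feature statistics the
    tensor was standardized with (fitted on training windows only) so
    they can be reused at inference time.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    feature_names: tuple = FEATURE_NAMES
    zscore_mean: np.ndarray | None = None
    zscore_sd: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected (windows, channels, {len(FEATURE_NAMES)}) array, "
                f"got {self.values.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("one label per window required")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def build_feature_tensor(channel_windows: list[list[SignalWindow]],
                         labels=None,
                         zscore: bool = True,
                         train_indices=None,
                         wamp_threshold: float = DEFAULT_WAMP_THRESHOLD,
                         ) -> FeatureTensor:
    """Assemble the tensor from per-channel window lists.

    Parameters
    ----------
    channel_windows
        ``channel_windows[c][k]`` is window k of channel c; all
        channels must hold the same number of windows.
    labels
        Optional per-window integer labels.
    zscore
        Standardize each of the 18 features across windows (and
        channels).  Statistics come from ``train_indices`` windows when
        given, else from all windows; zero-SD features use a unit
        divisor.
    """
    counts = {len(ws) for ws in channel_windows}
    if len(counts) != 1:
        raise ValueError(f"channels disagree on window count: {sorted(counts)}")
    n_windows = counts.pop()
    n_channels = len(channel_windows)
    values = np.empty((n_windows, n_channels, len(FEATURE_NAMES)))
    for c, ws in enumerate(channel_windows):
        for k, w in enumerate(ws):
            values[k, c] = extract_features(w, wamp_threshold)
    mean = sd = None
    if zscore:
        fit = values if train_indices is None else values[np.asarray(train_indices)]
        mean = fit.reshape(-1, len(FEATURE_NAMES)).mean(axis=0)
        sd = fit.reshape(-1, len(FEATURE_NAMES)).std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        values = (values - mean) / sd
    return FeatureTensor(values=values,
                         labels=None if labels is None else np.asarray(labels),
                         zscore_mean=mean, zscore_sd=sd)
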