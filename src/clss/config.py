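"""Configuration schema, signal/table I/O, seeding and logging.

The configuration mirrors the acquisition chain of the wearable
sensing/stimulation platform: up to 8 bipolar EMG pairs feed an analog
front end, up to 12 stimulation pairs hang off the pulse generator, and
the analysis chain is band-pass -> windowing -> features -> classifier.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GESTURE_CODES",
    "SystemConfig",
    "RecordingMeta",
    "EMGRecording",
    "ConfigError",
    "ParseError",
    "validate_config",
    "read_config",
    "write_config",
    "read_recording",
    "write_recording",
    "write_feature_table",
    "read_feature_table",
    "child_rng",
    "child_seed",
    "get_logger",
    "log_stage",
]

#: The nine hand-gesture classes: thumbs up, acute angle, OK, thumb
#: flexion, hand open, hang loose, power grip, wrist extension, wrist
#: flexion.  Order fixes the integer label used throughout.
GESTURE_CODES = ("TU", "AA", "OK", "TF", "HO", "HL", "PG", "WE", "WF")

MAX_EMG_PAIRS = 8   # sensing front-end channel limit
MAX_ES_PAIRS = 12   # stimulation channel limit


class ConfigError(ValueError):
    """A configuration field violates an invariant; ``.field`` names it."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class ParseError(ValueError):
    """A signal or table file is malformed."""


@dataclass
class SystemConfig:
    """Whole-pipeline configuration.

    Defaults follow the analysis chain: 10–500 Hz band-pass, 10-s
    windows, 80/20 split, 150 training epochs.  The sampling rate is a
    package default (2000 Hz leaves margin above the 500 Hz band edge);
    it is configurable because acquisition hardware varies.
    """

    n_emg_pairs: int = 4
    n_es_pairs: int = 4
    sampling_rate: float = 2000.0
    bandpass_lo: float = 10.0
    bandpass_hi: float = 500.0
    window_s: float = 10.0
    window_overlap: float = 0.5
    split_train_fraction: float = 0.8
    epochs: int = 150
    seed: int = 0


def validate_config(cfg: SystemConfig) -> SystemConfig:
    """Validate every invariant of *cfg*; return it unchanged if valid.

    Raises
    ------
    ConfigError
        Naming the offending field.
    """
    if not (1 <= cfg.n_emg_pairs <= MAX_EMG_PAIRS):
        raise ConfigError("n_emg_pairs", f"must be in [1, {MAX_EMG_PAIRS}], got {cfg.n_emg_pairs}")
    if not (1 <= cfg.n_es_pairs <= MAX_ES_PAIRS):
        raise ConfigError("n_es_pairs", f"must be in [1, {MAX_ES_PAIRS}], got {cfg.n_es_pairs}")
    if not np.isfinite(cfg.sampling_rate) or cfg.sampling_rate <= 0:
        raise ConfigError("sampling_rate", "must be a positive finite frequency")
    if not (0 < cfg.bandpass_lo < cfg.bandpass_hi):
        raise ConfigError("bandpass_lo", "require 0 < bandpass_lo < bandpass_hi")
    if not (cfg.bandpass_hi < cfg.sampling_rate / 2):
        raise ConfigError("bandpass_hi", "band edge must lie below Nyquist")
    if cfg.window_s <= 0:
        raise ConfigError("window_s", "window length must be positive")
    if not (0 <= cfg.window_overlap < 1):
        raise ConfigError("window_overlap", "overlap fraction must be in [0, 1)")
    if not (0 < cfg.split_train_fraction < 1):
        raise ConfigError("split_train_fraction", "train fraction must be in (0, 1)")
    if cfg.epochs < 1:
        raise ConfigError("epochs", "need at least one epoch")
    if not (0 <= int(cfg.seed) < 2**63):
        raise ConfigError("seed", "seed must be a non-negative integer")
    return cfg


def write_config(cfg: SystemConfig, path: str | Path) -> None:
    """Write *cfg* as an INI file with a single ``[clss]`` section."""
    parser = configparser.ConfigParser()
    parser["clss"] = {k: repr(v) for k, v in dataclasses.asdict(cfg).items()}
    with open(path, "w") as fh:
        parser.write(fh)


def read_config(path: str | Path) -> SystemConfig:
    """Read an INI config written by :func:`write_config` (validated)."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read or "clss" not in parser:
        raise ParseError(f"{path}: missing [clss] section")
    kwargs = {}
    fields = {f.name: f.type for f in dataclasses.fields(SystemConfig)}
    for key, raw in parser["clss"].items():
        if key not in fields:
            raise ParseError(f"{path}: unknown config key {key!r}")
        value = float(raw)
        if fields[key] == "int":
            value = int(value)
        kwargs[key] = value
    return validate_config(SystemConfig(**kwargs))


@dataclass
class RecordingMeta:
    """Provenance of one recording: subject, gesture and channel names."""

    subject_id: str = ""
    gesture_code: str | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.gesture_code is not None and self.gesture_code not in GESTURE_CODES:
            raise ConfigError(
                "gesture_code",
                f"{self.gesture_code!r} not one of {GESTURE_CODES}",
            )


@dataclass
class EMGRecording:
    """A multichannel sampled voltage trace.

    ``samples`` is (n_samples, n_channels) in volts.
    """

    samples: np.ndarray
    sampling_rate: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_samples, n_channels) array")
        if not self.meta.channel_names:
            self.meta.channel_names = [f"ch{i}" for i in range(self.samples.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# Signal I/O
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "# clss-recording"


def write_recording(rec: EMGRecording, path: str | Path) -> None:
    """Write a recording as tab-separated columnar text (volts).

    Layout: two comment lines carrying sampling rate and meta, one
    header line of channel names, then one row per sample.  The format
    round-trips bit-exactly through :func:`read_recording`.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX} rate={rec.sampling_rate!r} "
                 f"subject={rec.meta.subject_id} gesture={rec.meta.gesture_code or '-'}\n")
        fh.write("\t".join(rec.meta.channel_names) + "\n")
        np.savetxt(fh, rec.samples, fmt="%.17g", delimiter="\t")


def _read_columnar(path: Path) -> EMGRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty file")
        if not first.startswith(_HEADER_PREFIX):
            raise ParseError(f"{path}: missing recording header line")
        tokens = dict(t.split("=", 1) for t in first[len(_HEADER_PREFIX):].split())
        try:
            rate = float(tokens["rate"])
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: malformed rate in header") from exc
        names_line = fh.readline()
        if not names_line.strip():
            raise ParseError(f"{path}: missing channel-name line")
        names = names_line.rstrip("\n").split("\t")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed sample rows") from exc
    if data.size == 0:
        raise ParseError(f"{path}: no sample rows")
    if data.shape[1] != len(names):
        raise ParseError(
            f"{path}: {len(names)} header channels but {data.shape[1]} data columns"
        )
    if not np.all(np.isfinite(data)):
        raise ParseError(f"{path}: non-finite samples")
    gesture = tokens.get("gesture", "-")
    meta = RecordingMeta(
        subject_id=tokens.get("subject", ""),
        gesture_code=None if gesture in ("-", "") else gesture,
        channel_names=names,
    )
    return EMGRecording(samples=data, sampling_rate=rate, meta=meta)


def _read_edf(path: Path) -> EMGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T  # mne returns (channels, samples) in volts
    meta = RecordingMeta(channel_names=list(raw.ch_names))
    return EMGRecording(samples=data, sampling_rate=float(raw.info["sfreq"]), meta=meta)


def read_recording(path: str | Path, format: str = "columnar") -> EMGRecording:
    """Read a recording from columnar text or EDF.

    Parameters
    ----------
    format
        ``"columnar"`` (tab-separated text, the native format) or
        ``"edf"`` (read-only, via mne).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "columnar":
        return _read_columnar(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def write_feature_table(tensor, path: str | Path) -> None:
    """Write a feature tensor as CSV: window, channel, 18 feature columns.

    ``tensor`` is a :class:`clss.features.FeatureTensor`.  Labels, when
    present, are written as an extra ``label`` column.
    """
    arr = tensor.values
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        rows = ", ".join(f"(window {w}, channel {c})" for w, c, _ in bad[:5])
        raise ValueError(f"non-finite features at {rows}")
    n_windows, n_channels, n_feat = arr.shape
    idx = np.indices((n_windows, n_channels)).reshape(2, -1).T
    df = pd.DataFrame(arr.reshape(-1, n_feat), columns=list(tensor.feature_names))
    df.insert(0, "channel", idx[:, 1])
    df.insert(0, "window", idx[:, 0])
    if tensor.labels is not None:
        df["label"] = np.repeat(tensor.labels, n_channels)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path):
    """Read a CSV written by :func:`write_feature_table` back to a tensor."""
    from .features import FEATURE_NAMES, FeatureTensor

    df = pd.read_csv(path)
    n_windows = int(df["window"].max()) + 1
    n_channels = int(df["channel"].max()) + 1
    df = df.sort_values(["window", "channel"])
    values = df[list(FEATURE_NAMES)].to_numpy().reshape(n_windows, n_channels, -1)
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy().reshape(n_windows, n_channels)[:, 0]
    return FeatureTensor(values=values, labels=labels)


# ---------------------------------------------------------------------------
# Seed management & logging
# ---------------------------------------------------------------------------

def child_seed(root_seed: int, *stream: str | int) -> int:
    """Derive a deterministic child seed (< 2**31) for a named stream."""
    # crc32, not hash(): the latter is salted per interpreter process
    entropy = [int(root_seed)]
    for s in stream:
        entropy.append(zlib.crc32(s.encode()) if isinstance(s, str) else int(s))
    digest = np.random.SeedSequence(entropy)
    return int(digest.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(root_seed: int, *stream: str | int) -> np.random.Generator:
    """A generator seeded deterministically from a root seed and stream tags."""
    return np.random.default_rng(child_seed(root_seed, *stream))


def get_logger(name: str = "clss") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def log_stage(stage: str, seed: int | None = None, **extra) -> None:
    """Structured one-line stage log: stage name, wall time, seed."""
    parts = [f"stage={stage}", f"wall={time.time():.3f}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts += [f"{k}={v}" for k, v in extra.items()]
    get_logger().info(" ".join(parts))
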