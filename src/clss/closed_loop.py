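"""Closed-loop orchestration: EMG stream -> gesture -> stimulation program.

Ties the chain together the way the wearable system runs it: the
incoming multichannel EMG stream is band-passed, adaptively
normalized, cut into Hamming windows, reduced to the 18-feature
tensor, classified, and the recognized gesture is mapped to a
stimulation program (dorsal channels for extension, volar for
flexion).  A minimum-RMS gate suppresses stimulation on rest windows.

Also hosts the outcome metric used to compare stimulated and
spontaneous gestures: the aggregated joint-angle error, the root of
the sum of squared differences across 14 finger/wrist joints.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .classifier import ShuffleBlockNet
from .config import GESTURE_CODES, EMGRecording, SystemConfig
from .features import FEATURE_NAMES, FeatureTensor, build_feature_tensor
from .preprocess import adaptive_normalize, bandpass_filter, segment_windows
from .stimulation import (  # noqa: F401  (module surface)
    ElectrodeLayout,
    StimProgram,
    StimWaveform,
    default_layout,
    make_biphasic,
    plan_stimulation,
)

__all__ = [
    "JOINT_NAMES", "JointAngleVector", "aggregated_angle_error",
    "extract_feature_dataset", "run_closed_loop",
    "StimWaveform", "StimProgram", "make_biphasic", "plan_stimulation",
]

#: The 14-joint ordering used for angle vectors: thumb CMC/MCP/IP,
#: MCP and PIP of index through little finger, and wrist
#: flexion-extension.
JOINT_NAMES = (
    "thumb_CMC", "thumb_MCP", "thumb_IP",
    "index_MCP", "index_PIP",
    "middle_MCP", "middle_PIP",
    "ring_MCP", "ring_PIP",
    "little_MCP", "little_PIP",
    "wrist_FE",
    "index_DIP", "middle_DIP",
)


@dataclass
class JointAngleVector:
    """14 joint angles in degrees, ordered as :data:`JOINT_NAMES`."""

    angles_deg: np.ndarray

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.shape != (len(JOINT_NAMES),):
            raise ValueError(f"need exactly {len(JOINT_NAMES)} joint angles")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("joint angles must be finite")


def aggregated_angle_error(stimulated, spontaneous) -> float:
    """Root of the sum of squared joint-angle differences (degrees).

    Both arguments are :class:`JointAngleVector` or length-14 arrays.
    """
    a = stimulated.angles_deg if isinstance(stimulated, JointAngleVector) \
        else np.asarray(stimulated, dtype=float)
    b = spontaneous.angles_deg if isinstance(spontaneous, JointAngleVector) \
        else np.asarray(spontaneous, dtype=float)
    if a.shape != (len(JOINT_NAMES),) or b.shape != (len(JOINT_NAMES),):
        raise ValueError(f"both angle vectors must have length {len(JOINT_NAMES)}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def extract_feature_dataset(recordings: list[EMGRecording], cfg: SystemConfig,
                            train_indices=None) -> FeatureTensor:
    """Preprocess a labeled recording collection into the 3-D tensor.

    Each recording is band-passed, adaptively normalized and windowed;
    windows from all recordings are concatenated (per channel) and the
    18 features are z-scored with training-window statistics when
    ``train_indices`` is given.
    """
    chan_windows: list[list] = []
    labels: list[int] = []
    for rec in recordings:
        r = bandpass_filter(rec, cfg.bandpass_lo, cfg.bandpass_hi)
        r = adaptive_normalize(r)
        ws = segment_windows(r, cfg.window_s, cfg.window_overlap)
        if not chan_windows:
            chan_windows = [[] for _ in range(len(ws))]
        for c, wlist in enumerate(ws):
            chan_windows[c].extend(wlist)
        if rec.meta.gesture_code is not None:
            labels.extend([GESTURE_CODES.index(rec.meta.gesture_code)]
                          * len(ws[0]))
    return build_feature_tensor(
        chan_windows, labels if labels else None, train_indices=train_indices)


def run_closed_loop(stream: EMGRecording, model: ShuffleBlockNet,
                    cfg: SystemConfig,
                    zscore_mean: np.ndarray, zscore_sd: np.ndarray,
                    layout: ElectrodeLayout | None = None,
                    rms_gate_v: float = 25e-6) -> list[dict]:
    """Process an EMG stream window by window and emit stimulation
    programs.

    Per window: preprocess -> features (z-scored with the training
    statistics) -> classify -> plan stimulation, unless the window's
    raw band-passed RMS falls below ``rms_gate_v`` (rest gate, no
    program emitted).  Returns one log row per window with the window
    time, gating outcome, predicted gesture, program channels and
    wall-time latency bookkeeping.  Deterministic given the model and
    stream.
    """
    if zscore_mean is None or zscore_sd is None:
        raise ValueError("z-scoring statistics from training are required")
    zscore_mean = np.asarray(zscore_mean, dtype=float)
    zscore_sd = np.asarray(zscore_sd, dtype=float)
    if zscore_mean.shape != (len(FEATURE_NAMES),):
        raise ValueError("z-score statistics must cover the 18 features")
    layout = layout or default_layout()
    filtered = bandpass_filter(stream, cfg.bandpass_lo, cfg.bandpass_hi)
    raw_windows = segment_windows(filtered, cfg.window_s, cfg.window_overlap,
                                  taper=False)
    normalized = adaptive_normalize(filtered)
    norm_windows = segment_windows(normalized, cfg.window_s, cfg.window_overlap)
    tensor = build_feature_tensor(norm_windows, zscore=False)
    feats = (tensor.values - zscore_mean) / zscore_sd

    log = []
    n_windows = tensor.n_windows
    for k in range(n_windows):
        t0 = time.perf_counter()
        raw_rms = float(np.sqrt(np.mean(
            [np.mean(raw_windows[c][k].samples ** 2)
             for c in range(len(raw_windows))])))
        row = {
            "window": k,
            "start_s": norm_windows[0][k].start_s,
            "rms_v": raw_rms,
            "gated": raw_rms < rms_gate_v,
            "gesture": None,
            "program_channels": [],
        }
        if not row["gated"]:
            pred = int(model.predict(feats[k:k + 1])[0])
            program = plan_stimulation(GESTURE_CODES[pred], layout)
            row["gesture"] = GESTURE_CODES[pred]
            row["program_channels"] = program.channels
        row["latency_s"] = time.perf_counter() - t0
        log.append(row)
    return log
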