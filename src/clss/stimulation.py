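"""Charge-balanced biphasic stimulation waveforms and gesture programs.

The stimulator delivers symmetric biphasic pulses: two rectangular
phases of equal magnitude and width with opposite sign (optionally
separated by an interphase gap), repeated at the pulse frequency.
Symmetry gives zero net charge per period, which is what makes the
waveform skin-safe.  A :class:`StimProgram` maps a recognized gesture
to the electrode channels and waveform that evoke it: dorsal channels
drive extension, volar channels drive flexion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GESTURE_CODES

__all__ = [
    "StimWaveform", "ElectrodeLayout", "StimProgram",
    "make_biphasic", "plan_stimulation",
    "EXTENSION_GESTURES", "FLEXION_GESTURES",
]

#: Gestures dominated by finger/wrist extension vs flexion; the rest
#: are mixed and use channels on both forearm aspects.
EXTENSION_GESTURES = ("WE", "HO")
FLEXION_GESTURES = ("WF", "PG", "TF")


@dataclass
class StimWaveform:
    """A sampled symmetric biphasic pulse train.

    ``samples`` holds the full trace (volts at the electrode);
    ``polarity_order`` says whether the leading phase is cathodic
    (negative) or anodic.
    """

    amplitude_v: float
    phase_width_us: float
    gap_us: float
    frequency_hz: float
    duration_s: float
    sampling_rate: float
    polarity_order: str
    samples: np.ndarray

    @property
    def n_pulses(self) -> int:
        return int(np.floor(self.frequency_hz * self.duration_s))

    def single_pulse(self) -> np.ndarray:
        """Samples of one period (for fiber simulation coupling)."""
        period = int(round(self.sampling_rate / self.frequency_hz))
        return self.samples[:period]


def make_biphasic(amplitude_v: float, phase_width_us: float, gap_us: float,
                  frequency_hz: float, duration_s: float,
                  sampling_rate: float,
                  polarity_order: str = "cathodic-first") -> StimWaveform:
    """Sample a symmetric biphasic pulse train.

    Each period holds phase one, an interphase gap, and the reversed
    phase two; ``floor(f * duration)`` full pulses fit in the trace.
    Raises if the two phases plus gap exceed one period.
    """
    if polarity_order not in ("cathodic-first", "anodic-first"):
        raise ValueError("polarity_order must be cathodic-first or anodic-first")
    if amplitude_v < 0 or phase_width_us < 0 or gap_us < 0:
        raise ValueError("amplitude, phase width and gap must be non-negative")
    if frequency_hz <= 0 or duration_s <= 0 or sampling_rate <= 0:
        raise ValueError("frequency, duration and sampling rate must be positive")
    if (2 * phase_width_us + gap_us) * frequency_hz > 1e6:
        raise ValueError("phases plus gap do not fit in one period")
    period_samples = int(round(sampling_rate / frequency_hz))
    n_phase = int(round(phase_width_us * 1e-6 * sampling_rate))
    n_gap = int(round(gap_us * 1e-6 * sampling_rate))
    if n_phase < 1:
        raise ValueError("phase width unresolved at this sampling rate")
    if 2 * n_phase + n_gap > period_samples:
        raise ValueError("sampled phases plus gap exceed the sampled period")
    lead = -1.0 if polarity_order == "cathodic-first" else 1.0
    pulse = np.zeros(period_samples)
    pulse[:n_phase] = lead * amplitude_v
    pulse[n_phase + n_gap:2 * n_phase + n_gap] = -lead * amplitude_v
    n_total = int(round(duration_s * sampling_rate))
    n_pulses = int(np.floor(frequency_hz * duration_s))
    samples = np.zeros(n_total)
    for p in range(n_pulses):
        start = p * period_samples
        if start + 2 * n_phase + n_gap > n_total:
            break  # never truncate a phase: that would unbalance charge
        seg = samples[start:start + period_samples]
        seg[:] = pulse[:seg.size]
    return StimWaveform(
        amplitude_v=amplitude_v, phase_width_us=phase_width_us, gap_us=gap_us,
        frequency_hz=frequency_hz, duration_s=duration_s,
        sampling_rate=sampling_rate, polarity_order=polarity_order,
        samples=samples)


@dataclass
class ElectrodeLayout:
    """Stimulation channel layout: channel name -> forearm side."""

    channels: dict  # name -> "dorsal" | "volar"

    def __post_init__(self):
        for name, side in self.channels.items():
            if side not in ("dorsal", "volar"):
                raise ValueError(f"channel {name!r}: side must be dorsal or volar")
        if len(self.channels) > 12:
            raise ValueError("at most 12 stimulation electrode pairs")

    def on_side(self, side: str) -> list[str]:
        return [n for n, s in self.channels.items() if s == side]


def default_layout() -> ElectrodeLayout:
    return ElectrodeLayout({
        "d1": "dorsal", "d2": "dorsal", "v1": "volar", "v2": "volar",
    })


@dataclass
class StimProgram:
    """gesture -> (channels, waveform) assignment."""

    gesture_code: str
    entries: list  # list of (channel name, StimWaveform)
    sides: dict = field(default_factory=dict)  # channel -> side

    def __post_init__(self):
        if self.gesture_code not in GESTURE_CODES:
            raise ValueError(f"unknown gesture {self.gesture_code!r}")
        if len(self.entries) > 12:
            raise ValueError("program exceeds 12 stimulation channels")
        used_sides = {self.sides[ch] for ch, _ in self.entries if ch in self.sides}
        if self.gesture_code in EXTENSION_GESTURES and "dorsal" not in used_sides:
            raise ValueError(f"{self.gesture_code} needs at least one dorsal channel")
        if self.gesture_code in FLEXION_GESTURES and "volar" not in used_sides:
            raise ValueError(f"{self.gesture_code} needs at least one volar channel")

    @property
    def channels(self) -> list[str]:
        return [ch for ch, _ in self.entries]


def plan_stimulation(gesture_code: str,
                     layout: ElectrodeLayout | None = None,
                     amplitude_v: float = 30.0,
                     phase_width_us: float = 200.0,
                     frequency_hz: float = 20.0,
                     duration_s: float = 1.0,
                     sampling_rate: float = 200000.0) -> StimProgram:
    """Deterministic gesture -> stimulation mapping.

    Extension gestures (WE, HO) route to dorsal channels, flexion
    gestures (WF, PG, TF) to volar channels, mixed gestures to both
    sides.  The real system tunes this per subject; this is the
    documented default table.
    """
    if gesture_code not in GESTURE_CODES:
        raise ValueError(f"unknown gesture {gesture_code!r}")
    layout = layout or default_layout()
    if gesture_code in EXTENSION_GESTURES:
        chans = layout.on_side("dorsal")
        if not chans:
            raise ValueError("layout lacks dorsal channels for an extension gesture")
    elif gesture_code in FLEXION_GESTURES:
        chans = layout.on_side("volar")
        if not chans:
            raise ValueError("layout lacks volar channels for a flexion gesture")
    else:
        dorsal, volar = layout.on_side("dorsal"), layout.on_side("volar")
        if not dorsal or not volar:
            raise ValueError("mixed gesture needs channels on both sides")
        chans = dorsal[:1] + volar[:1]
    wf = make_biphasic(amplitude_v, phase_width_us, 0.0, frequency_hz,
                       duration_s, sampling_rate)
    return StimProgram(gesture_code=gesture_code,
                       entries=[(ch, wf) for ch in chans],
                       sides=dict(layout.channels))
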