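"""Trigger-pulse detection, movement decoding and window extraction.

Trials are marked on an analog trigger channel by short rectangular pulses
whose amplitude encodes movement identity (15 mV = movement 1, ..., 40 mV =
movement 6).  Detection runs on the original acquisition grid, where a 5 ms
pulse spans ~10 samples at 2 kHz; onsets are then mapped onto the decimated
analysis grid.  Analysis windows of 3 s (trial duration plus one second of
reaction/termination latency) are cut from each device channel at each
decoded onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .preprocess import ProcessedRecording, normalize

__all__ = [
    "TriggerEvent",
    "EpochWindow",
    "detect_triggers",
    "decode_movement",
    "extract_windows",
]

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_V = 0.002  # closed +/-2 mV band around each 5 mV level


@dataclass(frozen=True)
class TriggerEvent:
    onset_index: int  # on the analysis (post-decimation) grid
    onset_s: float
    amplitude_V: float
    movement_id: int


@dataclass
class EpochWindow:
    subject_id: str
    trial_index: int  # 1-based position in the session
    movement_id: int
    device: str  # "reference" | "prototype"
    samples: np.ndarray
    rate_hz: float


def decode_movement(
    amplitude_V: float,
    levels_V: np.ndarray | list[float],
    tolerance_V: float = DEFAULT_TOLERANCE_V,
) -> int | None:
    """Nearest-level decoding with a closed tolerance band.

    Returns the 1-based id of the nearest configured level when the gap is
    at most tolerance_V, else None (never a default id).
    """
    levels = np.asarray(levels_V, dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ConfigError("trigger levels must be strictly ascending")
    gaps = np.abs(levels - amplitude_V)
    k = int(np.argmin(gaps))
    # tiny absolute slack so the closed boundary |gap| == tolerance survives
    # binary floating-point representation of millivolt values
    if gaps[k] <= tolerance_V + 1e-12:
        return k + 1
    return None


def detect_triggers(
    trigger: np.ndarray,
    rate: float,
    levels_V: np.ndarray | list[float],
    tolerance_V: float = DEFAULT_TOLERANCE_V,
    pulse_ms: float = 5.0,
    refractory_s: float = 1.0,
    target_rate: float | None = None,
) -> list[TriggerEvent]:
    """Find pulses, decode their amplitude, and place onsets on the analysis grid.

    A pulse onset is the first sample exceeding half the smallest configured
    level; the amplitude is the median of the above-threshold samples within
    the nominal pulse span.  Crossings within refractory_s of an accepted
    onset are suppressed.  Pulses whose amplitude matches no level within the
    tolerance are logged and excluded.
    """
    trigger = np.asarray(trigger, dtype=float)
    levels = np.asarray(levels_V, dtype=float)
    if rate <= 0:
        raise ConfigError("rate must be positive")
    threshold = levels.min() / 2.0
    width = max(int(round(pulse_ms / 1000.0 * rate)), 1)
    refractory = int(round(refractory_s * rate))
    factor = 1.0 if target_rate is None else rate / target_rate

    above = trigger > threshold
    rising = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        rising = np.union1d(rising, [0])

    events: list[TriggerEvent] = []
    last_onset = -refractory - 1
    for i0 in rising:
        if i0 - last_onset <= refractory:
            continue
        seg = trigger[i0 : i0 + width]
        seg = seg[seg > threshold]
        amplitude = float(np.median(seg)) if seg.size else float(trigger[i0])
        movement = decode_movement(amplitude, levels, tolerance_V)
        last_onset = i0
        if movement is None:
            logger.warning(
                "trigger pulse at %.3f s: amplitude %.4f V matches no level "
                "within +/-%.4f V; excluded",
                i0 / rate, amplitude, tolerance_V,
            )
            continue
        events.append(
            TriggerEvent(
                onset_index=int(i0 // factor),
                onset_s=i0 / rate,
                amplitude_V=amplitude,
                movement_id=movement,
            )
        )
    return events


def extract_windows(
    recording: ProcessedRecording,
    events: list[TriggerEvent],
    window_s: float = 3.0,
    offset_s: float = 0.0,
    subject_id: str = "S1",
) -> list[EpochWindow]:
    """Cut one window per device per event from the processed channels.

    Windows that would run past the end of the recording are dropped with a
    warning.  With a per_window normalization scope on the recording, each
    window is peak-normalized individually.
    """
    if window_s <= 0:
        raise ConfigError("window_s must be positive")
    rate = recording.sampling_rate_hz
    length = int(round(window_s * rate))
    shift = int(round(offset_s * rate))
    per_window_norm = not recording.normalized

    windows: list[EpochWindow] = []
    n = len(recording.reference_emg)
    for trial, ev in enumerate(events, start=1):
        start = ev.onset_index + shift
        if start < 0 or start + length > n:
            logger.warning(
                "trial %d at %.3f s: window [%d, %d) exceeds recording of %d "
                "samples; dropped", trial, ev.onset_s, start, start + length, n,
            )
            continue
        for device in ("reference", "prototype"):
            seg = getattr(recording, f"{device}_emg")[start : start + length]
            seg = np.array(seg, dtype=float)
            if per_window_norm:
                seg = normalize(seg)
            windows.append(
                EpochWindow(
                    subject_id=subject_id,
                    trial_index=trial,
                    movement_id=ev.movement_id,
                    device=device,
                    samples=seg,
                    rate_hz=rate,
                )
            )
    return windows
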