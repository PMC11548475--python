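"""Rate reduction, Butterworth band-pass filtering and peak normalization.

The processing chain mirrors standard surface-EMG conditioning: decimate the
2 kHz acquisition to 500 Hz (with an anti-aliasing FIR low-pass), band-pass
20-200 Hz with a zero-phase 4th-order Butterworth, then scale each channel
to the -1..1 range by dividing by its maximum absolute value.  The trigger
channel is never filtered or normalized; it stays on the acquisition grid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .errors import ConfigError, DegenerateInputError
from .simulate import DualRecording

__all__ = [
    "PreprocessParams",
    "ProcessedRecording",
    "downsample",
    "bandpass",
    "normalize",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessParams:
    target_rate_hz: float = 500.0
    band_hz: tuple[float, float] = (20.0, 200.0)
    filter_order: int = 4
    zero_phase: bool = True
    normalization_scope: str = "per_recording"  # or "per_window"

    def __post_init__(self) -> None:
        if self.target_rate_hz <= 0:
            raise ConfigError("target_rate_hz must be positive")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError("band_hz must satisfy 0 < low < high")
        if hi >= self.target_rate_hz / 2:
            raise ConfigError("band high edge must lie below target Nyquist")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.normalization_scope not in ("per_recording", "per_window"):
            raise ConfigError("normalization_scope must be per_recording|per_window")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d


@dataclass
class ProcessedRecording:
    """Both EMG channels after downsample/band-pass/normalize."""

    time_s: np.ndarray
    reference_emg: np.ndarray
    prototype_emg: np.ndarray
    sampling_rate_hz: float
    normalized: bool
    metadata: dict


def downsample(
    x: np.ndarray, source_rate: float, target_rate: float
) -> np.ndarray:
    """Integer-factor decimation with a zero-phase anti-aliasing FIR.

    The low-pass cuts at 0.8x the target Nyquist so content up to the 200 Hz
    analysis band survives while anything that would alias is removed.
    """
    if source_rate <= 0 or target_rate <= 0:
        raise ConfigError("rates must be positive")
    ratio = source_rate / target_rate
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ConfigError(
            f"source rate {source_rate} is not an integer multiple of {target_rate}"
        )
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    cutoff = 0.8 * (target_rate / 2.0)
    numtaps = 20 * factor + 1
    taps = signal.firwin(numtaps, cutoff, fs=source_rate)
    filtered = signal.filtfilt(taps, [1.0], x)
    return filtered[::factor]


def bandpass(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float] = (20.0, 200.0),
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass; forward-backward when zero_phase."""
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ConfigError(f"band {band} invalid for rate {rate}")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, band, btype="bandpass", fs=rate, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def normalize(x: np.ndarray) -> np.ndarray:
    """Scale to -1..1 by the maximum absolute value: y = x / max|x|."""
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero signal")
    return x / peak


def preprocess_recording(
    recording: DualRecording, params: PreprocessParams | None = None
) -> ProcessedRecording:
    """Apply downsample -> band-pass -> normalize to both EMG channels.

    With normalization_scope="per_window" the peak scaling is deferred to the
    epoching stage and the returned channels are only filtered.
    """
    params = params or PreprocessParams()
    fs = recording.sampling_rate_hz
    channels = {}
    for name in ("reference_emg", "prototype_emg"):
        y = downsample(getattr(recording, name), fs, params.target_rate_hz)
        y = bandpass(
            y, params.target_rate_hz, params.band_hz,
            params.filter_order, params.zero_phase,
        )
        if params.normalization_scope == "per_recording":
            y = normalize(y)
        channels[name] = y
    n = len(channels["reference_emg"])
    return ProcessedRecording(
        time_s=np.arange(n) / params.target_rate_hz,
        reference_emg=channels["reference_emg"],
        prototype_emg=channels["prototype_emg"],
        sampling_rate_hz=params.target_rate_hz,
        normalized=params.normalization_scope == "per_recording",
        metadata={
            "source_rate_hz": fs,
            "params": params.to_dict(),
            **recording.metadata,
        },
    )
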