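"""Seeded simulator for synchronized dual-device surface-EMG sessions.

The generator emulates the acquisition setup the analysis pipeline expects:
a single muscle source recorded in parallel by a clean reference device and
a noisier prototype whose analog front end (first-order ~20.7 Hz high-pass,
~330 Hz low-pass, 60 Hz notch) is modeled with digital IIR filters, plus an
analog trigger channel whose 5 ms pulse amplitude (15-40 mV in 5 mV steps)
encodes which of the six movements each trial belongs to.

The muscle source itself is band-limited Gaussian noise amplitude-modulated
by a trapezoidal contraction envelope: a crude but standard surrogate for
surface EMG, whose interference-pattern statistics are well approximated by
modulated colored noise.  Movement identity deliberately does not change the
source statistics; it only labels the trigger pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal

from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "DualRecording",
    "build_schedule",
    "generate_source",
    "apply_prototype_channel",
    "make_trigger_channel",
    "generate_session",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the session simulator.

    Amplitudes are in normalized source units (contraction plateau = 1);
    the trigger channel is in volts.
    """

    sampling_rate_hz: float = 2000.0
    n_movements: int = 6
    reps_per_movement: int = 10
    contraction_s: float = 2.0
    rest_s: float = 5.0
    trigger_levels_mV: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    trigger_pulse_ms: float = 5.0
    source_band_hz: tuple[float, float] = (20.0, 300.0)
    envelope_rise_ms: float = 200.0
    envelope_fall_ms: float = 200.0
    reaction_delay_ms: float = 150.0
    reaction_jitter_ms: float = 50.0
    rest_level: float = 0.03  # baseline envelope, fraction of plateau
    prototype_gain: float = 1.0
    prototype_hp_hz: float = 20.7
    prototype_lp_hz: float = 330.0
    prototype_notch_hz: float = 60.0
    prototype_chain: bool = True
    reference_noise_sd: float = 0.02
    prototype_noise_sd: float = 0.08
    mains_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.n_movements < 1 or self.reps_per_movement < 1:
            raise ConfigError("n_movements and reps_per_movement must be >= 1")
        if self.contraction_s <= 0 or self.rest_s <= 0:
            raise ConfigError("contraction_s and rest_s must be positive")
        levels = np.asarray(self.trigger_levels_mV, dtype=float)
        if len(levels) != self.n_movements:
            raise ConfigError(
                f"{len(levels)} trigger levels for {self.n_movements} movements"
            )
        if np.any(np.diff(levels) <= 0):
            raise ConfigError("trigger levels must be strictly increasing")
        if self.trigger_pulse_ms <= 0:
            raise ConfigError("trigger_pulse_ms must be positive")
        lo, hi = self.source_band_hz
        nyq = self.sampling_rate_hz / 2
        if not (0 < lo < hi < nyq):
            raise ConfigError(f"source band {self.source_band_hz} outside (0, {nyq})")
        if self.reference_noise_sd < 0 or self.prototype_noise_sd < 0:
            raise ConfigError("noise standard deviations must be nonnegative")
        if self.rest_level < 0 or self.rest_level > 0.05:
            raise ConfigError("rest_level must lie in [0, 0.05]")
        if self.reaction_delay_ms < 0:
            raise ConfigError("reaction_delay_ms must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.n_movements * self.reps_per_movement

    @property
    def duration_s(self) -> float:
        """Leading rest, then each trial contributes contraction + rest."""
        return self.rest_s + self.n_trials * (self.contraction_s + self.rest_s)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trigger_levels_mV"] = list(self.trigger_levels_mV)
        d["source_band_hz"] = list(self.source_band_hz)
        return d


@dataclass
class DualRecording:
    """A synchronized session: both EMG channels plus the trigger channel."""

    time_s: np.ndarray
    reference_emg: np.ndarray
    prototype_emg: np.ndarray
    trigger: np.ndarray
    sampling_rate_hz: float
    schedule: list[tuple[float, int]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("reference_emg", "prototype_emg", "trigger"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"channel {name} length differs from time axis")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)


def build_schedule(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Randomly ordered, balanced trial schedule.

    Every movement id 1..n_movements appears exactly reps_per_movement times;
    the order is a seeded permutation.  The first onset falls after an initial
    rest period and consecutive onsets are contraction_s + rest_s apart.
    """
    ids = np.repeat(np.arange(1, config.n_movements + 1), config.reps_per_movement)
    ids = rng.permutation(ids)
    period = config.contraction_s + config.rest_s
    onsets = config.rest_s + period * np.arange(config.n_trials)
    return [(float(t), int(m)) for t, m in zip(onsets, ids)]


def _contraction_envelope(
    schedule: list[tuple[float, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Trapezoidal envelope: rest baseline, per-trial ramp/hold/ramp.

    Each trial's ramp starts a jittered reaction delay after the cue onset,
    emulating the latency with which participants initiate the movement.
    """
    fs = config.sampling_rate_hz
    t = np.arange(n) / fs
    rise = config.envelope_rise_ms / 1000.0
    fall = config.envelope_fall_ms / 1000.0
    base = config.rest_level

    bp_t = [0.0]
    bp_v = [base]
    for onset, _mid in schedule:
        delay = config.reaction_delay_ms / 1000.0
        if config.reaction_jitter_ms > 0:
            delay += rng.normal(0.0, config.reaction_jitter_ms / 1000.0)
        delay = max(delay, 0.0)
        t0 = onset + delay
        t_end = t0 + config.contraction_s
        pts = [(t0, base), (t0 + rise, 1.0), (t_end, 1.0), (t_end + fall, base)]
        for tt, vv in pts:
            if tt > bp_t[-1]:
                bp_t.append(tt)
                bp_v.append(vv)
    bp_t.append(max(t[-1] + 1.0 / fs, bp_t[-1] + 1e-9))
    bp_v.append(base)
    return np.interp(t, bp_t, bp_v)


def generate_source(
    schedule: list[tuple[float, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise modulated by the contraction envelope.

    The carrier is white noise band-passed to source_band_hz (4th-order
    Butterworth) and rescaled to unit standard deviation, so the envelope
    value is directly the local RMS of the source.
    """
    n = int(round(config.duration_s * config.sampling_rate_hz))
    for onset, _ in schedule:
        if onset < 0 or onset + config.contraction_s > config.duration_s:
            raise ConfigError(f"trial onset {onset} s outside session duration")
    white = rng.standard_normal(n)
    sos = signal.butter(
        4, config.source_band_hz, btype="bandpass", fs=config.sampling_rate_hz,
        output="sos",
    )
    carrier = signal.sosfilt(sos, white)
    sd = carrier.std()
    if sd > 0:
        carrier = carrier / sd
    envelope = _contraction_envelope(schedule, config, rng, n)
    return carrier * envelope


def _prototype_chain_sos(config: SimulationConfig) -> np.ndarray:
    nyq = config.sampling_rate_hz / 2
    for name, f in (
        ("prototype_hp_hz", config.prototype_hp_hz),
        ("prototype_lp_hz", config.prototype_lp_hz),
        ("prototype_notch_hz", config.prototype_notch_hz),
    ):
        if not (0 < f < nyq):
            raise ConfigError(f"{name}={f} Hz outside (0, Nyquist={nyq})")
    hp = signal.butter(
        1, config.prototype_hp_hz, btype="highpass",
        fs=config.sampling_rate_hz, output="sos",
    )
    lp = signal.butter(
        2, config.prototype_lp_hz, btype="lowpass",
        fs=config.sampling_rate_hz, output="sos",
    )
    # two cascaded biquad notches approximate the board's 4th-order 60 Hz notch
    b, a = signal.iirnotch(
        config.prototype_notch_hz, Q=30.0, fs=config.sampling_rate_hz
    )
    notch = signal.tf2sos(b, a)
    return np.vstack([hp, lp, notch, notch])


def apply_prototype_channel(
    source: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pass the source through the prototype's analog-chain model.

    Causal (forward-only) IIR filtering, gain scaling, then additive white
    Gaussian noise of sd prototype_noise_sd when an rng is supplied.  With
    prototype_chain=False the filters are bypassed (useful for the identity
    channel limit).
    """
    x = np.asarray(source, dtype=float)
    if config.prototype_chain:
        sos = _prototype_chain_sos(config)
        y = signal.sosfilt(sos, x)
    else:
        y = x.copy()
    y = y * config.prototype_gain
    if rng is not None and config.prototype_noise_sd > 0:
        y = y + rng.normal(0.0, config.prototype_noise_sd, size=y.shape)
    return y


def make_trigger_channel(
    schedule: list[tuple[float, int]], config: SimulationConfig
) -> np.ndarray:
    """Rectangular 5 ms pulses; amplitude encodes the movement id in volts."""
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    width = int(round(config.trigger_pulse_ms / 1000.0 * fs))
    width = max(width, 1)
    trig = np.zeros(n)
    last_end = -1
    for onset, mid in sorted(schedule):
        if not 1 <= mid <= config.n_movements:
            raise ConfigError(f"movement id {mid} outside 1..{config.n_movements}")
        i0 = int(round(onset * fs))
        if i0 <= last_end:
            raise ConfigError(f"trigger pulses overlap at onset {onset} s")
        i1 = min(i0 + width, n)
        trig[i0:i1] = config.trigger_levels_mV[mid - 1] / 1000.0
        last_end = i1 - 1
    return trig


def generate_session(config: SimulationConfig) -> DualRecording:
    """Simulate one full session, deterministically from config.rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    schedule = build_schedule(config, rng)
    source = generate_source(schedule, config, rng)
    n = len(source)
    t = np.arange(n) / config.sampling_rate_hz

    mains = 0.0
    if config.mains_amplitude > 0:
        mains = config.mains_amplitude * np.sin(
            2 * np.pi * config.prototype_notch_hz * t
        )

    reference = source + mains
    if config.reference_noise_sd > 0:
        reference = reference + rng.normal(0.0, config.reference_noise_sd, size=n)
    prototype = apply_prototype_channel(source + mains, config, rng)
    trigger = make_trigger_channel(schedule, config)

    return DualRecording(
        time_s=t,
        reference_emg=reference,
        prototype_emg=prototype,
        trigger=trigger,
        sampling_rate_hz=config.sampling_rate_hz,
        schedule=schedule,
        metadata={"rng_seed": config.rng_seed, "config": config.to_dict()},
    )
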