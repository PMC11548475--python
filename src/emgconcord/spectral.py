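"""Frequency-domain and cross-correlation comparison of the two channels.

Complements the scalar concordance statistics with (i) the one-sided FFT
magnitude spectrum, (ii) a lag-resolved normalized cross-correlation whose
zero-lag value is exactly the Pearson correlation of the two channels, and
(iii) a Hann-tapered short-time Fourier spectrogram compared across channels
by normalized 2-D cross-correlation, summarized by its peak coefficient and
peak (time, frequency) shift.  The squared peak coefficient is the fraction
of one channel's time-frequency variability explained by the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "SpectrogramParams",
    "fft_spectrum",
    "cross_correlation",
    "CrossCorrelation",
    "spectrogram",
    "Spectrogram",
    "spectrogram_xcorr2d",
    "explained_variance",
]


@dataclass(frozen=True)
class SpectrogramParams:
    window_samples: int = 256
    overlap_fraction: float = 0.5
    taper: str = "hann"
    rate_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ConfigError("window_samples must be >= 2")
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigError("overlap_fraction must lie in [0, 1)")
        if self.taper != "hann":
            raise ConfigError(f"unsupported taper {self.taper!r}")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")


def fft_spectrum(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT magnitude |X(k)| and its frequency axis in Hz."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ConfigError("fft_spectrum needs at least 2 samples")
    if rate <= 0:
        raise ConfigError("rate must be positive")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    return freqs, mag


@dataclass
class CrossCorrelation:
    lags: np.ndarray  # in samples; positive lag = second signal delayed
    coefficients: np.ndarray  # Pearson correlation at each lag
    peak_lag: int
    peak_value: float
    zero_lag_value: float


def cross_correlation(
    a: np.ndarray, b: np.ndarray, max_lag: int | None = None
) -> CrossCorrelation:
    """Lag-resolved Pearson correlation with overlap-only normalization.

    At lag k >= 0 the coefficient is the Pearson correlation of a[0:n-k]
    with b[k:n] (b delayed by k samples); negative lags mirror the roles.
    The zero-lag coefficient therefore equals the ordinary Pearson
    correlation of the full signals.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("signals must be equal-length 1-D")
    n = a.size
    if n < 3:
        raise ConfigError("cross_correlation needs at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    if max_lag is None:
        max_lag = n // 2
    max_lag = int(min(max_lag, n - 2))

    # overlap sums for every lag via cumulative sums
    ca, ca2 = np.cumsum(a), np.cumsum(a * a)
    cb, cb2 = np.cumsum(b), np.cumsum(b * b)
    full = signal.correlate(b, a, mode="full", method="auto")
    # full[(n-1)+k] = sum_j b[j+k] * a[j]  for k >= 0

    lags = np.arange(-max_lag, max_lag + 1)
    coeffs = np.empty(lags.size)
    for idx, k in enumerate(lags):
        m = n - abs(k)
        if k >= 0:
            sa, qa = ca[m - 1], ca2[m - 1]
            sb, qb = cb[n - 1] - (cb[k - 1] if k else 0.0), \
                     cb2[n - 1] - (cb2[k - 1] if k else 0.0)
            cross = full[(n - 1) + k]
        else:
            sb, qb = cb[m - 1], cb2[m - 1]
            sa = ca[n - 1] - ca[-k - 1]
            qa = ca2[n - 1] - ca2[-k - 1]
            cross = full[(n - 1) + k]
        num = cross - sa * sb / m
        den = np.sqrt((qa - sa * sa / m) * (qb - sb * sb / m))
        coeffs[idx] = num / den if den > 0 else np.nan

    peak_idx = int(np.nanargmax(coeffs))
    zero_idx = max_lag
    return CrossCorrelation(
        lags=lags,
        coefficients=coeffs,
        peak_lag=int(lags[peak_idx]),
        peak_value=float(coeffs[peak_idx]),
        zero_lag_value=float(coeffs[zero_idx]),
    )


@dataclass
class Spectrogram:
    freqs_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray  # shape (freqs, times)


def spectrogram(x: np.ndarray, params: SpectrogramParams) -> Spectrogram:
    """Short-time Fourier magnitude with a Hann taper."""
    x = np.asarray(x, dtype=float)
    if x.size < params.window_samples:
        raise ConfigError(
            f"signal of {x.size} samples shorter than window of "
            f"{params.window_samples}"
        )
    noverlap = int(params.overlap_fraction * params.window_samples)
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=params.rate_hz,
        window="hann",
        nperseg=params.window_samples,
        noverlap=noverlap,
        mode="magnitude",
    )
    return Spectrogram(freqs_hz=freqs, times_s=times, magnitude=sxx)


def spectrogram_xcorr2d(
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    min_overlap_fraction: float = 0.5,
) -> tuple[float, tuple[int, int]]:
    """Normalized 2-D cross-correlation of two equal-shape magnitude grids.

    At each 2-D shift the overlapping region of both grids is mean-subtracted
    and unit-scaled (a per-shift Pearson coefficient); shifts whose overlap
    covers less than min_overlap_fraction of the grid are ignored.  Returns
    the peak coefficient and its (row, column) = (frequency, time) shift;
    ties within 1e-9 are resolved toward the smallest shift.
    """
    a = np.asarray(grid_a, dtype=float)
    b = np.asarray(grid_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ConfigError("grids must be equal-shape 2-D arrays")
    r, c = a.shape
    ones = np.ones_like(a)

    counts = signal.correlate(ones, ones, mode="full", method="fft")
    counts = np.maximum(np.rint(counts), 1.0)
    sa = signal.correlate(a, ones, mode="full", method="fft")
    qa = signal.correlate(a * a, ones, mode="full", method="fft")
    sb = signal.correlate(ones, b, mode="full", method="fft")
    qb = signal.correlate(ones, b * b, mode="full", method="fft")
    cross = signal.correlate(a, b, mode="full", method="fft")

    num = cross - sa * sb / counts
    var_a = np.maximum(qa - sa * sa / counts, 0.0)
    var_b = np.maximum(qb - sb * sb / counts, 0.0)
    den = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        coeff = np.where(den > 0, num / den, np.nan)
    coeff = np.clip(coeff, -1.0, 1.0)

    min_count = min_overlap_fraction * r * c
    coeff[counts < min_count] = np.nan
    if np.all(np.isnan(coeff)):
        raise DegenerateInputError("no admissible shift with sufficient overlap")

    peak = np.nanmax(coeff)
    di, dj = np.indices(coeff.shape)
    # sign convention matches cross_correlation: positive shift means the
    # second grid is displaced toward larger indices (delayed)
    shift_i = (r - 1) - di
    shift_j = (c - 1) - dj
    candidates = np.abs(coeff - peak) <= 1e-9
    dist = np.where(candidates, np.abs(shift_i) + np.abs(shift_j), np.inf)
    best = np.unravel_index(np.argmin(dist), dist.shape)
    return float(coeff[best]), (int(shift_i[best]), int(shift_j[best]))


def explained_variance(r: float) -> float:
    """Coefficient of determination r**2 of a correlation coefficient."""
    if abs(r) > 1:
        raise ConfigError(f"|r| must not exceed 1, got {r}")
    return float(r * r)
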