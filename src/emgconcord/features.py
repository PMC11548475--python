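"""Canonical definitions of the 22 time-domain EMG feature indices.

This file is the single source of truth for every feature formula; all other
modules consume features exclusively through :func:`feature_vector` and
``FEATURE_NAMES``.  Conventions, stated once:

* Windows are 1-based in the formulas: x_1..x_N, differences
  Delta_i = x_{i+1} - x_i.
* Piecewise weight/exponent boundaries compare the 1-based index against
  fractional multiples of N with closed inequalities, e.g. the MMAV central
  band is 0.25*N <= i <= 0.75*N (equivalently i >= ceil(0.25*N)).
* ASM and ASS raise samples to fractional powers; for negative samples the
  principal complex root is used and the modulus of the complex sum is
  returned.  This mirrors how naive numeric environments evaluate these
  expressions and is a deliberate, documented choice.
* Logarithms are guarded by a small epsilon (default 1e-10); KURT on a
  zero-variance window is undefined and returned as NaN with a warning.
* COV divides by the window mean, which is near zero for band-passed EMG;
  values computed from a mean below sqrt(epsilon) are flagged so aggregation
  stages can optionally exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError

__all__ = [
    "FEATURE_NAMES",
    "FeatureParams",
    "amplitude_features",
    "difference_features",
    "threshold_count_features",
    "statistical_features",
    "feature_vector",
]

# Fixed presentation order of the feature table.
FEATURE_NAMES: tuple[str, ...] = (
    "FZC", "EWL", "EMAV", "ASM", "ASS", "CARD", "LDASDV", "LDAMV",
    "MYOP", "VO", "MMAV", "MMAV2", "IEMG", "RMS", "WA", "LD",
    "MAV", "MAD", "IQR", "KURT", "COV", "SD",
)


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds and exponents, in normalized (-1..1) amplitude units."""

    fzc_threshold: float = 0.01
    wa_threshold: float = 0.01
    myop_threshold: float = 0.016
    card_threshold: float = 0.01
    v_order: float = 2.0
    log_epsilon: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("fzc_threshold", "wa_threshold", "myop_threshold",
                     "card_threshold"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.v_order <= 0:
            raise ConfigError("v_order must be positive")
        if self.log_epsilon <= 0:
            raise ConfigError("log_epsilon must be positive")


def _check_window(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ConfigError("feature window must be 1-D with at least 2 samples")
    return x


def _enhanced_exponents(n: int) -> np.ndarray:
    """p_i = 0.75 in the central 0.2N <= i <= 0.8N band, 0.5 outside."""
    i = np.arange(1, n + 1)
    return np.where((i >= 0.2 * n) & (i <= 0.8 * n), 0.75, 0.5)


def amplitude_features(x: np.ndarray, params: FeatureParams | None = None) -> dict:
    """Magnitude-based indices: IEMG, MAV, MMAV, MMAV2, EMAV, RMS, VO, LD, ASM, ASS."""
    params = params or FeatureParams()
    x = _check_window(x)
    n = x.size
    i = np.arange(1, n + 1)
    ax = np.abs(x)
    eps = params.log_epsilon

    central = (i >= 0.25 * n) & (i <= 0.75 * n)
    w_mmav = np.where(central, 1.0, 0.5)
    w_mmav2 = np.where(central, 1.0, np.where(i < 0.25 * n, 4 * i / n, 4 * (n - i) / n))
    p = _enhanced_exponents(n)

    asm = np.abs(np.sum(np.power(x.astype(complex), p)))
    ass = np.abs(np.sum(np.power(x.astype(complex), 0.5)))

    return {
        "IEMG": float(np.sum(ax)),
        "MAV": float(np.mean(ax)),
        "MMAV": float(np.mean(w_mmav * ax)),
        "MMAV2": float(np.mean(w_mmav2 * ax)),
        "EMAV": float(np.mean(ax ** p)),
        "RMS": float(np.sqrt(np.mean(x ** 2))),
        "VO": float(np.mean(ax ** params.v_order) ** (1.0 / params.v_order)),
        "LD": float(np.exp(np.mean(np.log(ax + eps)))),
        "ASM": float(asm),
        "ASS": float(ass),
    }


def difference_features(x: np.ndarray, params: FeatureParams | None = None) -> dict:
    """First-difference indices: EWL, LDAMV, LDASDV."""
    params = params or FeatureParams()
    x = _check_window(x)
    n = x.size
    eps = params.log_epsilon
    d = np.diff(x)

    # EWL exponent indexed by the right endpoint i = 2..N of each difference
    p = _enhanced_exponents(n)[1:]
    ewl = float(np.sum(np.abs(d) ** p))

    damv = float(np.mean(np.abs(d)))
    dasdv = float(np.sqrt(np.mean(d ** 2)))
    return {
        "EWL": ewl,
        "LDAMV": float(np.log(damv + eps)),
        "LDASDV": float(np.log(dasdv + eps)),
    }


def threshold_count_features(
    x: np.ndarray, params: FeatureParams | None = None
) -> dict:
    """Threshold/count indices: FZC, WA, MYOP, CARD."""
    params = params or FeatureParams()
    x = _check_window(x)
    n = x.size
    d = np.diff(x)

    sign_change = x[:-1] * x[1:] < 0
    fzc = int(np.sum(sign_change & (np.abs(d) >= params.fzc_threshold)))
    wa = int(np.sum(np.abs(d) >= params.wa_threshold))
    myop = float(np.mean(np.abs(x) >= params.myop_threshold))
    s = np.sort(x)
    card = int(np.sum(np.abs(np.diff(s)) > params.card_threshold))
    return {"FZC": float(fzc), "WA": float(wa), "MYOP": myop, "CARD": float(card)}


def statistical_features(
    x: np.ndarray, params: FeatureParams | None = None
) -> tuple[dict, dict]:
    """Dispersion/shape indices: SD, MAD, IQR, KURT, COV.

    Returns (values, flags); flags marks COV computed from a near-zero mean
    and KURT undefined on a constant window.
    """
    params = params or FeatureParams()
    x = _check_window(x)
    n = x.size
    eps = params.log_epsilon
    mean = float(np.mean(x))
    centered = x - mean

    sd = float(np.sqrt(np.sum(centered ** 2) / (n - 1)))
    mad = float(np.mean(np.abs(centered)))
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    iqr = float(q3 - q1)

    flags: dict[str, bool] = {}
    m2 = float(np.mean(centered ** 2))
    if m2 == 0.0:
        warnings.warn("zero-variance window: KURT undefined, returning NaN")
        kurt = float("nan")
        flags["KURT"] = True
    else:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))

    denom = mean if mean != 0.0 else eps
    cov = float(sd / denom)
    if abs(mean) < np.sqrt(eps):
        flags["COV"] = True

    return {"SD": sd, "MAD": mad, "IQR": iqr, "KURT": kurt, "COV": cov}, flags


def feature_vector(
    x: np.ndarray,
    params: FeatureParams | None = None,
    return_flags: bool = False,
):
    """All 22 features of a window, in ``FEATURE_NAMES`` order.

    Returns a 1-D float array of length 22, or ``(array, flags)`` when
    return_flags is set.
    """
    params = params or FeatureParams()
    values: dict[str, float] = {}
    values.update(amplitude_features(x, params))
    values.update(difference_features(x, params))
    values.update(threshold_count_features(x, params))
    stat, flags = statistical_features(x, params)
    values.update(stat)
    vec = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    if return_flags:
        return vec, flags
    return vec
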