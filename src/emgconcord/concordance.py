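"""Inverted-MAPE device agreement, per feature and per subject.

Agreement between the two devices is quantified with the mean absolute
percentage error between matched per-window feature values,

    MAPE = (1/n) * sum_i |y_i - yhat_i| / |y_i|

kept internally as a fraction (percent only at display time), and inverted
so that 1 means perfect agreement:

    concordance = 1 - MAPE.

The reference device provides the "actual" values y, the prototype the
"predicted" yhat.  Pairs whose actual value is numerically zero are excluded
(MAPE is undefined there) and the exclusion count is reported; cells where
MAPE exceeds 1 go negative and are kept unclipped by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConcordanceUndefinedError, DataFormatError
from .features import FEATURE_NAMES

__all__ = [
    "mape",
    "inverted_mape",
    "ConcordanceMatrix",
    "concordance_matrix",
    "ZERO_ACTUAL_EPS",
]

logger = logging.getLogger(__name__)

ZERO_ACTUAL_EPS = 1e-8


def _mape_stats(actual, predicted) -> tuple[float, int, int]:
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 1:
        raise DataFormatError("actual and predicted must be equal-length 1-D, n >= 1")
    keep = np.abs(y) >= ZERO_ACTUAL_EPS
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise ConcordanceUndefinedError(
            "all pairs excluded: every actual value is below "
            f"{ZERO_ACTUAL_EPS} in magnitude"
        )
    err = np.abs(y[keep] - yhat[keep]) / np.abs(y[keep])
    return float(np.mean(err)), int(np.sum(keep)), n_excluded


def mape(actual, predicted) -> float:
    """Mean absolute percentage error as a fraction (0 = identical)."""
    value, _, _ = _mape_stats(actual, predicted)
    return value


def inverted_mape(actual, predicted) -> float:
    """1 - MAPE: 1 means perfect agreement; may go negative when MAPE > 1."""
    value = 1.0 - mape(actual, predicted)
    if value < 0:
        warnings.warn(
            f"inverted MAPE is negative ({value:.3g}): gross disagreement; "
            "reported unclipped"
        )
    return value


@dataclass
class ConcordanceMatrix:
    """Feature x subject grid of 1-MAPE values with marginal and overall means."""

    values: pd.DataFrame  # index = feature names, columns = subject ids
    per_feature_mean: pd.Series
    per_subject_mean: pd.Series
    overall_mean: float
    n_windows_used: pd.DataFrame
    n_excluded: pd.DataFrame
    clipped: bool = False
    skipped_subjects: list = field(default_factory=list)


def concordance_matrix(
    feature_tables: dict,
    clip: bool = False,
    exclude_features: tuple[str, ...] = (),
    drop_cells: set[tuple[str, str]] | frozenset = frozenset(),
) -> ConcordanceMatrix:
    """Build the per-feature, per-subject concordance grid.

    Parameters
    ----------
    feature_tables
        Mapping subject_id -> (reference_table, prototype_table), each a
        DataFrame of matched windows (rows, identically indexed) by the 22
        feature columns.
    clip
        Clip negative cells to 0 for display.
    exclude_features
        Feature names dropped from the grid before aggregation (e.g. "COV"
        when its near-zero-mean instability is unwanted).
    drop_cells
        (feature, subject) cells recorded as missing, e.g. COV cells whose
        windows were flagged for a near-zero mean denominator.  Marginals
        and the overall mean skip missing cells.
    """
    features = [f for f in FEATURE_NAMES if f not in exclude_features]
    cells: dict[str, dict[str, float]] = {}
    used: dict[str, dict[str, int]] = {}
    excluded: dict[str, dict[str, int]] = {}
    skipped: list[str] = []

    for subject, (ref, proto) in feature_tables.items():
        ref = pd.DataFrame(ref)
        proto = pd.DataFrame(proto)
        if len(ref) != len(proto):
            logger.error(
                "subject %s: %d reference vs %d prototype windows; skipped",
                subject, len(ref), len(proto),
            )
            skipped.append(subject)
            continue
        missing = [f for f in features if f not in ref.columns or f not in proto.columns]
        if missing:
            raise DataFormatError(f"subject {subject}: missing feature columns {missing}")
        col_v, col_u, col_e = {}, {}, {}
        for f in features:
            if (f, subject) in drop_cells:
                logger.info("cell (%s, %s) dropped from aggregation", f, subject)
                col_v[f], col_u[f], col_e[f] = np.nan, 0, 0
                continue
            try:
                m, n_used, n_excl = _mape_stats(ref[f].to_numpy(), proto[f].to_numpy())
            except ConcordanceUndefinedError:
                logger.warning("subject %s feature %s: all pairs excluded", subject, f)
                col_v[f], col_u[f], col_e[f] = np.nan, 0, len(ref)
                continue
            col_v[f] = 1.0 - m
            col_u[f] = n_used
            col_e[f] = n_excl
        cells[subject] = col_v
        used[subject] = col_u
        excluded[subject] = col_e

    if not cells:
        raise DataFormatError("no usable subjects")

    values = pd.DataFrame(cells).reindex(index=features)
    if clip:
        values = values.clip(lower=0.0)
    flat = values.to_numpy().ravel()
    overall = float(np.nanmean(flat))
    return ConcordanceMatrix(
        values=values,
        per_feature_mean=values.mean(axis=1, skipna=True),
        per_subject_mean=values.mean(axis=0, skipna=True),
        overall_mean=overall,
        n_windows_used=pd.DataFrame(used).reindex(index=features),
        n_excluded=pd.DataFrame(excluded).reindex(index=features),
        clipped=clip,
        skipped_subjects=skipped,
    )
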