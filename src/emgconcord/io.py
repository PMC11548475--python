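"""Recording and table readers/writers.

Interchange format for a session is a plain CSV with the header
``time_s,reference_emg,prototype_emg,trigger`` (one row per sample) plus an
optional YAML sidecar carrying the simulator config, seed and schedule.
Floats are written with 17 significant digits so a write/read round trip
reproduces the arrays bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError
from .features import FEATURE_NAMES
from .simulate import DualRecording

__all__ = [
    "REQUIRED_COLUMNS",
    "read_recording",
    "write_recording",
    "sidecar_path",
    "config_hash",
    "windows_to_frame",
    "write_feature_table",
    "read_feature_table",
]

REQUIRED_COLUMNS = ("time_s", "reference_emg", "prototype_emg", "trigger")
FLOAT_FORMAT = "%.17g"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_recording(
    recording: DualRecording, path: str | Path, sidecar: bool = True
) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_s": recording.time_s,
            "reference_emg": recording.reference_emg,
            "prototype_emg": recording.prototype_emg,
            "trigger": recording.trigger,
        }
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if sidecar:
        meta = {
            "sampling_rate_hz": float(recording.sampling_rate_hz),
            "schedule": [[float(t), int(m)] for t, m in recording.schedule],
            "metadata": _plain(recording.metadata),
        }
        cfg = recording.metadata.get("config")
        if cfg is not None:
            meta["config_hash"] = config_hash(cfg)
        sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_recording(path: str | Path) -> DualRecording:
    """Load and validate a recording CSV; rate inferred from the time axis."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    for col in REQUIRED_COLUMNS:
        bad = frame.index[frame[col].isna()]
        if len(bad):
            raise DataFormatError(f"{path}: NaN in column {col} at row {bad[0]}")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataFormatError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise DataFormatError(f"{path}: non-monotone time axis at row {row}")
    mean_dt = float(np.mean(dt))
    rel = np.abs(dt - mean_dt) / mean_dt
    if np.max(rel) > 1e-6:
        row = int(np.argmax(rel)) + 1
        raise DataFormatError(
            f"{path}: non-uniform sampling at row {row} "
            f"(relative jitter {np.max(rel):.2e})"
        )
    rate = 1.0 / mean_dt

    schedule: list[tuple[float, int]] = []
    metadata: dict = {"source_file": str(path)}
    side = sidecar_path(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
        rate = float(meta.get("sampling_rate_hz", rate))
        schedule = [(float(t0), int(m)) for t0, m in meta.get("schedule", [])]
        metadata.update(meta.get("metadata", {}))
        if "config_hash" in meta:
            metadata["config_hash"] = meta["config_hash"]
    return DualRecording(
        time_s=t,
        reference_emg=frame["reference_emg"].to_numpy(dtype=float),
        prototype_emg=frame["prototype_emg"].to_numpy(dtype=float),
        trigger=frame["trigger"].to_numpy(dtype=float),
        sampling_rate_hz=rate,
        schedule=schedule,
        metadata=metadata,
    )


def windows_to_frame(windows) -> pd.DataFrame:
    """Long-format frame of epoch windows (one row per sample)."""
    parts = []
    for w in windows:
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": w.subject_id,
                    "trial_index": w.trial_index,
                    "movement_id": w.movement_id,
                    "device": w.device,
                    "sample_index": np.arange(len(w.samples)),
                    "value": w.samples,
                    "rate_hz": w.rate_hz,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "subject_id", "trial_index", "movement_id", "device",
                "sample_index", "value", "rate_hz",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def write_feature_table(
    table: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> Path:
    """Feature table CSV keyed by (subject, trial, movement, device)."""
    path = Path(path)
    keys = ["subject_id", "trial_index", "movement_id", "device"]
    ordered = table[keys + list(FEATURE_NAMES)]
    if ordered.duplicated(subset=keys).any():
        raise DataFormatError("duplicate (subject, trial, movement, device) keys")
    ordered.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if provenance:
        sidecar_path(path).write_text(yaml.safe_dump(_plain(provenance)))
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    keys = ["subject_id", "trial_index", "movement_id", "device"]
    missing = [c for c in keys + list(FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    if table.duplicated(subset=keys).any():
        raise DataFormatError(f"{path}: duplicate keys")
    return table


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
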