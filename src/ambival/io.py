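"""Canonical trial/choice dataset format and run logging.

One CSV row per trial. Urn-type rows (``task`` in {urn, urn_bar... }) carry
observed sample counts and the true composition; motor-type rows carry the
target geometry. ``urn_bar`` denotes the bar-stimulus urn variant, whose
stimulus geometry matches the motor task, so it uses the motor field block.

Columns
-------
subject_id : str
task : {urn, motor, urn_bar}
trial_index : int
is_probe : {0, 1}
info_level : float in [0, 1]   (urn: shown/100; motor: 1 - ambiguity index)
n_red_obs, n_blue_obs : int    (urn rows only)
visible_half_width, occluder_width, endpoint_sd, true_half_width : float (cm,
    motor/urn_bar rows only)
true_red_count : int           (urn rows only; red balls per 100)
utility_condition : {normal, inverse}
choice : {risk, amb}
payoff : {0, -1}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TASKS",
    "URN_TASKS",
    "MOTOR_TASKS",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "split_by_subject",
    "write_run_log",
]

COLUMNS = [
    "subject_id",
    "task",
    "trial_index",
    "is_probe",
    "info_level",
    "n_red_obs",
    "n_blue_obs",
    "visible_half_width",
    "occluder_width",
    "endpoint_sd",
    "true_half_width",
    "true_red_count",
    "utility_condition",
    "choice",
    "payoff",
]

TASKS = frozenset({"urn", "motor", "urn_bar"})
URN_TASKS = frozenset({"urn"})
MOTOR_TASKS = frozenset({"motor", "urn_bar"})
_URN_FIELDS = ["n_red_obs", "n_blue_obs", "true_red_count"]
_MOTOR_FIELDS = [
    "visible_half_width",
    "occluder_width",
    "endpoint_sd",
    "true_half_width",
]


class SchemaError(ValueError):
    """Dataset does not conform to the canonical schema."""


def _fail(row: int, message: str) -> None:
    # rows are numbered 1..n over data rows (header excluded)
    raise SchemaError(f"row {row}: {message}")


def validate_dataset(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial/choice table against the canonical schema.

    Returns the frame with columns in canonical order. Raises
    :class:`SchemaError` naming the first offending data row.
    """
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    frame = frame[COLUMNS].reset_index(drop=True)
    for i in range(len(frame)):
        row = frame.iloc[i]
        rownum = i + 1
        task = row["task"]
        if task not in TASKS:
            _fail(rownum, f"unknown task label {task!r}")
        if row["is_probe"] not in (0, 1):
            _fail(rownum, f"is_probe must be 0 or 1, got {row['is_probe']!r}")
        if row["utility_condition"] not in ("normal", "inverse"):
            _fail(rownum, f"bad utility_condition {row['utility_condition']!r}")
        if row["choice"] not in ("risk", "amb"):
            _fail(rownum, f"choice must be 'risk' or 'amb', got {row['choice']!r}")
        if row["payoff"] not in (0, -1):
            _fail(rownum, f"payoff must be 0 or -1, got {row['payoff']!r}")
        if not (0.0 <= row["info_level"] <= 1.0):
            _fail(rownum, f"info_level outside [0, 1]: {row['info_level']!r}")
        if task in URN_TASKS:
            for c in _URN_FIELDS:
                v = row[c]
                if pd.isna(v) or float(v) != int(v) or v < 0:
                    _fail(rownum, f"urn row needs nonnegative integer {c}, got {v!r}")
            for c in _MOTOR_FIELDS:
                if not pd.isna(row[c]):
                    _fail(rownum, f"urn row must leave motor field {c} empty")
            if row["is_probe"] == 1 and row["n_red_obs"] != row["n_blue_obs"]:
                _fail(rownum, "urn probe trial must show symmetric samples")
        else:
            for c in _MOTOR_FIELDS:
                if pd.isna(row[c]) or row[c] < 0:
                    _fail(rownum, f"motor row needs nonnegative {c}, got {row[c]!r}")
            for c in _URN_FIELDS:
                if not pd.isna(row[c]):
                    _fail(rownum, f"motor row must leave urn field {c} empty")
            if row["endpoint_sd"] <= 0:
                _fail(rownum, "endpoint_sd must be positive")
            lo = row["visible_half_width"]
            hi = lo + row["occluder_width"]
            if not (lo - 1e-9 <= row["true_half_width"] <= hi + 1e-9):
                _fail(rownum, "true_half_width outside [visible, visible+occluder]")
    return frame


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a canonical trial/choice CSV."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    if "choice" in frame.columns:
        bad = frame.index[frame["choice"].isna()]
        if len(bad):
            _fail(int(bad[0]) + 1, "choice column empty")
    return validate_dataset(frame)


def write_dataset(frame: pd.DataFrame, path) -> None:
    """Write a canonical trial/choice CSV (validating first)."""
    frame = validate_dataset(frame)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def split_by_subject(frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        str(sid): sub.reset_index(drop=True)
        for sid, sub in frame.groupby("subject_id", sort=True)
    }


def write_run_log(path, *, seed, config_text: str | None = None, extra=None) -> dict:
    """Write a JSON run log with seed, config hash and package version."""
    from . import __version__

    record = {
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(config_text.encode()).hexdigest() if config_text else None
        ),
        "package_version": __version__,
    }
    if extra:
        record.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return record
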