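"""Trial-table CSV schema and config serialization.

One row per trial; missing responses (deadline missed) are empty fields.

Columns: subject_id (int), session (1/2), trial_index (int, within
session), phase (practice/experimental), condition (IM/WM), n_items (int),
correct (0/1 or empty), confidence (1-4 or empty), rt_decision_s (float s
or empty), rt_confidence_s (float s or empty), staircase_order (int;
per-condition experimental counter within session, 0 for practice).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ExperimentConfig, ObserverParams, RTParams

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "load_config", "save_config"]

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "trial_index",
    "phase",
    "condition",
    "n_items",
    "correct",
    "confidence",
    "rt_decision_s",
    "rt_confidence_s",
    "staircase_order",
]

_INT_COLS = ["subject_id", "session", "trial_index", "n_items", "staircase_order"]


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to CSV with the documented schema."""
    missing = set(TRIAL_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def _fail_rows(mask: pd.Series, what: str) -> None:
    if mask.any():
        rows = (np.flatnonzero(mask) + 2)[:5].tolist()  # 1-based + header line
        raise ValueError(f"{what} at CSV line(s) {rows}")


def read_trials(
    path: str | Path,
    strict: bool = True,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a trial CSV; bad values fail with line numbers.

    ``column_map`` renames externally-named columns (e.g. a deposited
    dataset's layout) onto the documented schema before validation:
    ``{"their_name": "schema_name"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - set(TRIAL_COLUMNS)
    if extra and strict:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {sorted(extra)}")
    df = df[TRIAL_COLUMNS].copy()
    if len(df) == 0:
        return df
    for col in _INT_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        _fail_rows(vals.isna(), f"non-integer {col}")
        df[col] = vals.astype(int)
    for col in ("correct", "confidence", "rt_decision_s", "rt_confidence_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["correct"] = df["correct"].astype("Float64")
    df["confidence"] = df["confidence"].astype("Float64")
    _fail_rows(~df["phase"].isin(["practice", "experimental"]), "bad phase")
    _fail_rows(~df["condition"].isin(["IM", "WM"]), "bad condition")
    _fail_rows(df["n_items"] < 1, "n_items < 1")
    conf = df["confidence"]
    _fail_rows(conf.notna() & (~conf.isin([1, 2, 3, 4])), "confidence outside 1..4")
    corr = df["correct"]
    _fail_rows(corr.notna() & (~corr.isin([0, 1])), "correct outside 0/1")
    _fail_rows(
        conf.notna() & df["rt_confidence_s"].isna(),
        "confidence present without confidence RT",
    )
    return df


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Serialize an experiment config (including the seed) as YAML."""
    d = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(d)), fh, sort_keys=False)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    obs = d.pop("observer", None)
    observer = ObserverParams()
    if obs is not None:
        rtp = obs.pop("rt_params", None)
        rt_params = RTParams(**rtp) if rtp else RTParams()
        if "tau" in obs:
            obs["tau"] = tuple(obs["tau"])
        observer = ObserverParams(**obs, rt_params=rt_params)
    return ExperimentConfig(**d, observer=observer)
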