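"""Trial-table and configuration I/O.

The interchange format is a comma-delimited UTF-8 table with a header row
and columns ``subject_id, session_id, trial_index, sp_mm_per_s,
delta_speed, choice, rewarded, iti_s`` — one row per trial, ``iti_s`` empty
on the first trial of each session. Floating-point values are written with
6 decimal places.

An adapter stub (:func:`read_external_table`) maps externally deposited
layouts onto this schema via a configurable column-name mapping, without
bundling any external data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import TRIAL_COLUMNS

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_external_table",
    "load_config",
    "save_config",
    "TrialTableError",
    "DEFAULT_CONFIG",
]

FLOAT_FORMAT = "%.6f"


class TrialTableError(ValueError):
    """A trial table violates the schema."""


DEFAULT_CONFIG: dict = {
    "stimulus_set": {"lowest_sp": 43.0, "highest_sp": 163.0, "boundary_sp": 103.0},
    "extraction": {"mode": "uniform", "max_category_run": 3},
    "observer": {
        "model_type": "continuous",
        "tau": 30.0,
        "sigma": 1.2,
        "gamma": 0.05,
        "lam": 0.05,
        "mu0": 0.0,
    },
    "iti": {"family": "lognormal", "median_s": 7.6, "dispersion": 0.4},
    "sessions": {"n_sessions": 40, "trials_per_session": 300, "subject_id": "sim01"},
    "analysis": {"n_lags": 8, "n_bins": 2, "outlier_fraction": 0.2},
    "crossval": {"n_rounds": 100, "train_frac": 0.8},
    "seed": 0,
}


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as CSV."""
    _validate(trials)
    trials.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trial_table(path: str | Path, strict_runs: bool = False) -> pd.DataFrame:
    """Read and validate a trial table; rows stay grouped by session, in order.

    With ``strict_runs`` a warning is issued if any rewarded-category run
    exceeds three trials (the task's sequence constraint).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialTableError(f"missing columns: {sorted(missing)}")
    _validate(df)
    if strict_runs:
        _warn_on_long_runs(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    for col in ("choice", "rewarded"):
        vals = df[col].dropna().unique()
        if not set(vals) <= {0, 1}:
            raise TrialTableError(f"column {col!r} must be binary, found {sorted(vals)}")
    for sid, sess in df.groupby("session_id", sort=False):
        ti = sess["trial_index"].to_numpy()
        if np.any(np.diff(ti) <= 0):
            bad = int(np.argmax(np.diff(ti) <= 0)) + 1
            raise TrialTableError(
                f"session {sid!r}: trial_index not strictly increasing at row {bad}"
            )
        itis = sess["iti_s"].to_numpy(dtype=float)
        if len(itis) > 1 and np.any(~(itis[1:] > 0)):
            raise TrialTableError(f"session {sid!r}: non-positive or missing ITI after first trial")


def _warn_on_long_runs(df: pd.DataFrame, max_run: int = 3) -> None:
    import warnings

    for sid, sess in df.groupby("session_id", sort=False):
        cats = np.sign(sess["delta_speed"].to_numpy())
        run = 0
        prev = 0
        for c in cats:
            if c == 0:
                continue  # boundary trials have hidden assigned sides in real logs
            run = run + 1 if c == prev else 1
            prev = c
            if run > max_run:
                warnings.warn(f"session {sid!r}: same-category run longer than {max_run}")
                break


def read_external_table(
    path: str | Path, column_map: dict[str, str], **read_csv_kwargs
) -> pd.DataFrame:
    """Adapter for externally deposited trial logs with different headers.

    ``column_map`` maps external column names onto the canonical schema,
    e.g. ``{"rat": "subject_id", "resp": "choice", ...}``. Columns absent
    from the mapping are dropped; the result is validated as usual.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    df = df.rename(columns=column_map)[
        [c for c in TRIAL_COLUMNS if c in df.rename(columns=column_map).columns]
    ]
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialTableError(f"adapter mapping leaves columns missing: {sorted(missing)}")
    _validate(df)
    return df


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration, filling unspecified keys with defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
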