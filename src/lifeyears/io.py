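"""Delimited-text readers and report writers.

Readers validate rather than coerce: malformed rows are reported with
their line numbers (header = line 1) and reading fails.  Comma is the
default separator; a different one can be passed through ``sep``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregated import AggregatedCohort
from .cohort import Cohort
from .lifetable import LifeTable

__all__ = ["read_cohort", "read_lifetable", "read_aggregated", "write_report"]

log = logging.getLogger("lifeyears")


def _require_columns(df: pd.DataFrame, cols: dict[str, str | None], path) -> None:
    missing = [f"{role} ({name!r})" for role, name in cols.items() if name is not None and name not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, col: str, path, allow_nan=False) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna() if allow_nan else vals.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header line + 1-based
        raise ValueError(f"{path}: non-numeric values in column {col!r} at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_cohort(
    path,
    exit_col: str,
    status_col: str,
    entry_col: str | None = None,
    onset_col: str | None = None,
    censor_label: str = "alive",
    sep: str = ",",
) -> Cohort:
    """Read an individual-level cohort from a delimited text file.

    A missing ``entry_col`` means everyone is followed from birth
    (entry 0).  A numeric 0/1 status column is interpreted as
    alive/dead with a single cause labelled ``"dead"``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, {"exit": exit_col, "status": status_col, "entry": entry_col, "onset": onset_col}, path)

    exit_age = _numeric(df, exit_col, path)
    entry = _numeric(df, entry_col, path) if entry_col else np.zeros(len(df))
    onset = _numeric(df, onset_col, path, allow_nan=True) if onset_col else None

    status = df[status_col]
    if pd.api.types.is_numeric_dtype(status):
        vals = set(status.dropna().unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: numeric status column must be 0/1, got {sorted(vals)}")
        status = np.where(status.to_numpy() == 1, "dead", censor_label)
    else:
        status = status.astype(str).to_numpy()

    bad = np.flatnonzero(exit_age <= entry)
    if bad.size:
        lines = (bad + 2).tolist()[:10]
        raise ValueError(f"{path}: exit age <= entry age at line(s) {lines}")

    cohort = Cohort(entry, exit_age, status, censor_label=censor_label, onset=onset)
    log.info("read %s: %s", path.name, cohort.summary())
    return cohort


def read_lifetable(
    path,
    age_col: str = "age",
    surv_col: str | None = None,
    rate_col: str | None = None,
    sep: str = ",",
) -> LifeTable:
    """Read a standard life table (survivor proportions and/or rates)."""
    path = Path(path)
    if surv_col is None and rate_col is None:
        raise ValueError("pass surv_col and/or rate_col")
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, {"age": age_col, "survivor": surv_col, "rate": rate_col}, path)
    df = df.sort_values(age_col).reset_index(drop=True)
    return LifeTable(
        ages=_numeric(df, age_col, path).astype(int),
        survivor=_numeric(df, surv_col, path) if surv_col else None,
        rate=_numeric(df, rate_col, path) if rate_col else None,
    )


def read_aggregated(
    path,
    age_col: str = "age",
    rate_col: str | None = None,
    surv_col: str | None = None,
    cases_col: str = "new_cases",
    sep: str = ",",
) -> AggregatedCohort:
    """Read an aggregated diseased table: age, rate (or survivor), new cases."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    _require_columns(
        df, {"age": age_col, "rate": rate_col, "survivor": surv_col, "cases": cases_col}, path
    )
    df = df.sort_values(age_col).reset_index(drop=True)
    table = LifeTable(
        ages=_numeric(df, age_col, path).astype(int),
        survivor=_numeric(df, surv_col, path) if surv_col else None,
        rate=_numeric(df, rate_col, path) if rate_col else None,
    )
    return AggregatedCohort(table=table, new_cases=_numeric(df, cases_col, path))


def write_report(results: dict, json_path=None, csv_path=None) -> None:
    """Write a machine-readable JSON report and/or a tabular CSV.

    ``results`` maps names to scalars, dicts, or DataFrames; DataFrames
    go to the CSV (concatenated) and are serialized row-wise in JSON.
    """

    def encode(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.reset_index().to_dict(orient="records")
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    if json_path is not None:
        Path(json_path).parent.mkdir(parents=True, exist_ok=True)
        with open(json_path, "w") as fh:
            json.dump(results, fh, indent=2, default=encode)
    if csv_path is not None:
        frames = [v for v in results.values() if isinstance(v, pd.DataFrame)]
        if frames:
            Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
            pd.concat(frames).to_csv(csv_path)
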