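"""Shared table/report I/O.

All tabular input and output is plain delimited text with a header
(comma or tab, sniffed).  Heteroplasmy columns accept either fractions
or percent; any column whose maximum exceeds 1 is treated as percent and
divided by 100 at the boundary, so everything downstream works in
fractions.  Structured reports are JSON and always embed the seed and
full parameterization of the run that produced them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

__all__ = ["read_table", "read_cells", "read_pairs", "read_sperm",
           "write_report", "write_table"]

log = logging.getLogger(__name__)

_H_COLUMNS = ("h", "mother_h0", "offspring_h")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no header") from None
    if df.empty:
        raise EmptyInputError(f"{path}: header-only file")
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Percent -> fraction conversion, per heteroplasmy column."""
    for c in _H_COLUMNS:
        if c in df.columns and df[c].max() > 1.0:
            df[c] = df[c] / 100.0
    return df


def _drop_bad(df: pd.DataFrame, mask: pd.Series, reason: str) -> pd.DataFrame:
    """Drop rows where ``mask`` is True, logging 1-based data line numbers."""
    if mask.any():
        lines = (df.index[mask] + 2).tolist()  # +2: header + 1-based
        log.warning("rejected %d row(s) (%s) at line(s) %s",
                    int(mask.sum()), reason, lines)
        df = df[~mask]
    return df


def read_cells(path) -> pd.DataFrame:
    """Single-oocyte table: mouse_id, stage, h[, copy_number], mother_h0."""
    df = read_table(path)
    _require(df, ["mouse_id", "stage", "h", "mother_h0"], path)
    df = _fractions(df)
    bad = (df["h"] < 0) | (df["h"] > 1) | df["h"].isna()
    if "copy_number" in df.columns:
        bad |= df["copy_number"] < 0
    df = _drop_bad(df.reset_index(drop=True), bad.reset_index(drop=True),
                   "invalid heteroplasmy or copy number")
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    return df.reset_index(drop=True)


def read_pairs(path) -> pd.DataFrame:
    """Mother-offspring pairs: mother_h0, offspring_h[, maternal_age, ids]."""
    df = read_table(path)
    _require(df, ["mother_h0", "offspring_h"], path)
    df = _fractions(df)
    bad = ((df["mother_h0"] < 0) | (df["mother_h0"] > 1)
           | (df["offspring_h"] < 0) | (df["offspring_h"] > 1)
           | df["mother_h0"].isna() | df["offspring_h"].isna())
    df = _drop_bad(df.reset_index(drop=True), bad.reset_index(drop=True),
                   "heteroplasmy outside [0, 1]")
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    return df.reset_index(drop=True)


def read_sperm(path) -> pd.DataFrame:
    """Male germ-cell table: mouse_id, ploidy, m, w[, age_months]."""
    df = read_table(path)
    _require(df, ["mouse_id", "ploidy", "m", "w"], path)
    bad = (df["m"] < 0) | (df["w"] < 0) | df["m"].isna() | df["w"].isna()
    bad |= ~df["ploidy"].isin(["4N", "2N", "1N"])
    df = _drop_bad(df.reset_index(drop=True), bad.reset_index(drop=True),
                   "negative counts or unknown ploidy")
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows")
    df = df.reset_index(drop=True)
    df["m"] = df["m"].astype(np.int64)
    df["w"] = df["w"].astype(np.int64)
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(results, path) -> None:
    """Write a structured report as JSON (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
        fh.write("\n")


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
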