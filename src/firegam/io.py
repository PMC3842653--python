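"""Typed, validated CSV input/output for the pipeline tables.

All tables are plain CSV with ISO-8601 dates.  Readers validate the schema and
raise :class:`SchemaError` naming the file, row and column of the first
violation; ``write -> read`` round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_counts", "write_counts",
    "read_covariates", "write_covariates",
    "read_demographics", "write_demographics",
    "read_stations", "write_stations",
    "read_zips", "write_zips",
]


class SchemaError(ValueError):
    def __init__(self, file, message, row=None, column=None):
        loc = f" (row {row})" if row is not None else ""
        col = f" column {column!r}" if column else ""
        super().__init__(f"{file}:{col}{loc} {message}")
        self.file, self.row, self.column = str(file), row, column


def _require_columns(df, path, columns):
    for c in columns:
        if c not in df.columns:
            raise SchemaError(path, "missing required column", column=c)


def _parse_dates(df, path):
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        bad = df.index[pd.to_datetime(df["date"], format="ISO8601", errors="coerce").isna()]
        row = int(bad[0]) if len(bad) else None
        raise SchemaError(path, "unparseable ISO-8601 date", row=row, column="date")
    return df


def _no_duplicates(df, path, keys):
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise SchemaError(path, f"duplicate {tuple(keys)} row", row=int(df.index[dup][0]))


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, ["region_id", "date", "visits", "population"])
    df = _parse_dates(df, path)
    _no_duplicates(df, path, ["region_id", "date"])
    for col in ("visits", "population"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(path, "non-numeric value", row=int(df.index[vals.isna()][0]), column=col)
        df[col] = vals
    neg = df.index[df["visits"] < 0]
    if len(neg):
        raise SchemaError(path, "negative count", row=int(neg[0]), column="visits")
    nonpos = df.index[df["population"] <= 0]
    if len(nonpos):
        raise SchemaError(path, "population must be positive", row=int(nonpos[0]), column="population")
    over = df.index[df["visits"] > df["population"]]
    if len(over):
        raise SchemaError(path, "visits exceed population", row=int(over[0]), column="visits")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    out = df[["region_id", "date", "visits", "population"]].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


_COVARIATE_COLS = ["region_id", "date", "fire_pm25", "fire_pm10", "anthro_pm25", "mean_rh", "min_temp"]


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, _COVARIATE_COLS)
    df = _parse_dates(df, path)
    _no_duplicates(df, path, ["region_id", "date"])
    for col in _COVARIATE_COLS[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(path, "non-numeric value", row=int(df.index[vals.isna()][0]), column=col)
        df[col] = vals
    for col in ("fire_pm25", "fire_pm10", "anthro_pm25"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise SchemaError(path, "negative concentration", row=int(neg[0]), column=col)
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    out = df[_COVARIATE_COLS].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, ["region_id", "prop_age_lt24", "prop_income_gt50k"])
    _no_duplicates(df, path, ["region_id"])
    for col in ("prop_age_lt24", "prop_income_gt50k"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals <= 0) | (vals >= 1)]
        if len(bad):
            raise SchemaError(path, "proportion must be in (0,1)", row=int(bad[0]), column=col)
        df[col] = vals
    return df


def write_demographics(df: pd.DataFrame, path) -> None:
    df[["region_id", "prop_age_lt24", "prop_income_gt50k"]].to_csv(path, index=False)


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, ["station_id", "lon", "lat", "date", "mean_rh", "min_temp"])
    df = _parse_dates(df, path)
    _no_duplicates(df, path, ["station_id", "date"])
    return df


def write_stations(df: pd.DataFrame, path) -> None:
    out = df[["station_id", "lon", "lat", "date", "mean_rh", "min_temp"]].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_zips(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, path, ["zip", "lon", "lat", "population", "region_id"])
    _no_duplicates(df, path, ["zip"])
    pops = pd.to_numeric(df["population"], errors="coerce")
    bad = df.index[pops.isna() | (pops <= 0)]
    if len(bad):
        raise SchemaError(path, "population must be positive", row=int(bad[0]), column="population")
    df["population"] = pops
    return df


def write_zips(df: pd.DataFrame, path) -> None:
    df[["zip", "lon", "lat", "population", "region_id"]].to_csv(path, index=False)
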