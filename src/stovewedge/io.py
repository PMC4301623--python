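"""Delimited-text file contracts shared by the pipeline commands.

All tables are comma-delimited with a header row; dates are ISO-8601;
missing values are empty fields; period and interval indices are 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    """A table does not match its file contract."""


PANEL_COLUMNS = ["child_id", "sector_id", "group_id", "period", "x", "y"]
DIARY_COLUMNS = [
    "child_id",
    "date",
    "fever",
    "fast_difficult_breathing",
    "persistent_cough",
    "wheezing",
    "watery_stool",
    "ear_discharge",
]
LOGGER_COLUMNS = ["timestamp", "value", "relative_humidity", "temperature"]
EXAM_COLUMNS = [
    "child_id",
    "exam_date",
    "age_months",
    "respiratory_rate",
    "chest_retractions",
    "unconscious",
    "crackles_any_quadrant",
]


def _require(df: pd.DataFrame, columns: list[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_binary(df: pd.DataFrame, column: str, path: object) -> None:
    bad = df.index[~df[column].isin([0, 1])]
    if len(bad):
        raise SchemaError(
            f"{path}: column {column!r} must be 0/1; first bad row {bad[0] + 2} "
            "(1-based, counting the header)"
        )


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PANEL_COLUMNS, path)
    for col in ("x", "y"):
        _check_binary(df, col, path)
    return df


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, columns=PANEL_COLUMNS, index=False)


def read_diary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"] if "date" in pd.read_csv(path, nrows=0).columns else None)
    _require(df, DIARY_COLUMNS[:4], path)
    return df


def write_diary(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    bool_cols = [c for c in DIARY_COLUMNS[2:] if c in out.columns]
    out[bool_cols] = out[bool_cols].astype("Int64")
    out.to_csv(path, index=False)


def read_logger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, LOGGER_COLUMNS[:2], path)
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise SchemaError(
            f"{path}: negative concentration at row {neg[0] + 2} (1-based with header)"
        )
    return df


def write_logger(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_exams(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["exam_date"])
    _require(df, EXAM_COLUMNS, path)
    return df
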