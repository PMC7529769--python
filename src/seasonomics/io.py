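"""TSV and YAML I/O for the pipeline.

All tables travel as plain TSV. The long analyte format has columns
sample_id, subject_id, day_of_year, year_index, group, bmi, age,
feature_id, ome, value; curve tables have feature_id/day/fit[/bands];
count matrices are samples x taxa with sample_id as the first column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

LONG_COLUMNS = ["sample_id", "subject_id", "day_of_year", "year_index",
                "group", "bmi", "age", "feature_id", "ome", "value"]
VISIT_COLUMNS = ["sample_id", "subject_id", "day_of_year", "year_index",
                 "group", "bmi", "age"]


class DataFormatError(ValueError):
    pass


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as exc:
        # pandas reports the offending line number in its message
        raise DataFormatError(f"{path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise DataFormatError(str(exc)) from exc


def read_long(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    bad = df["day_of_year"].dropna()
    if ((bad < 1) | (bad > 365)).any():
        row = df.index[(df["day_of_year"] < 1) | (df["day_of_year"] > 365)][0]
        raise DataFormatError(f"{path}: day_of_year outside [1, 365] at data line {row + 2}")
    return df


def read_visits(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    return df


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "sample_id":
        raise DataFormatError(f"{path}: first column must be sample_id")
    return df.set_index("sample_id")


def read_curves(path) -> pd.DataFrame:
    """Curves TSV: feature_id, day, fit (long form, 365 days per feature)."""
    df = _read_tsv(path)
    for c in ("feature_id", "day", "fit"):
        if c not in df.columns:
            raise DataFormatError(f"{path}: missing column {c!r}")
    return df


def write_tsv(df: pd.DataFrame, path, *, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataFormatError(f"{path}: config must be a YAML mapping")
    return cfg
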