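"""Readers and writers for the pipeline's plain-text artifacts.

Daily series travel as CSV with ISO-8601 dates, one row per day, gap-free
and duplicate-free; life tables as long CSV (year, sex, age, ex); death
records as CSV (date, age, sex, icd10); model fits and truth surfaces as
JSON sidecars; run configuration as YAML.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .yll import DeathRecord, LifeTableSet

__all__ = [
    "SeriesFormatError",
    "read_daily_series",
    "write_daily_series",
    "read_deaths",
    "read_life_tables",
    "read_config",
    "write_config",
]


class SeriesFormatError(ValueError):
    """Malformed daily-series file: the message names the row or column."""


def validate_daily_series(df: pd.DataFrame) -> pd.DataFrame:
    if "date" not in df.columns:
        raise SeriesFormatError("missing required column 'date'")
    out = df.copy()
    try:
        out["date"] = pd.to_datetime(out["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesFormatError(f"unparseable date: {exc}") from exc
    dup = out["date"][out["date"].duplicated()]
    if len(dup):
        raise SeriesFormatError(
            f"duplicated date(s): {dup.dt.strftime('%Y-%m-%d').tolist()[:5]}")
    out = out.sort_values("date").reset_index(drop=True)
    gaps = out["date"].diff().dt.days.iloc[1:]
    if len(gaps) and (gaps != 1).any():
        first = out["date"].iloc[int(np.argmax((gaps != 1).to_numpy()) + 1)]
        raise SeriesFormatError(
            f"dates are not consecutive around {first.date()}")
    for col in out.columns.drop("date"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[vals.isna() & out[col].notna()]
        if len(bad):
            raise SeriesFormatError(
                f"non-numeric value in column {col!r}, row {int(bad[0])}")
        out[col] = vals
    return out


def read_daily_series(path) -> pd.DataFrame:
    """Read and validate a daily-series CSV (ISO dates, no gaps)."""
    return validate_daily_series(pd.read_csv(path))


def write_daily_series(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_deaths(path) -> list[DeathRecord]:
    """Death records from CSV with columns date, age, sex, icd10."""
    df = pd.read_csv(path)
    missing = {"date", "age", "sex", "icd10"} - set(df.columns)
    if missing:
        raise SeriesFormatError(f"deaths file missing columns: {sorted(missing)}")
    return [DeathRecord(death_date=pd.Timestamp(r.date).date(),
                        age=int(r.age), gender=str(r.sex), icd10=str(r.icd10))
            for r in df.itertuples()]


def write_deaths(records, path) -> None:
    pd.DataFrame(
        {"date": [r.death_date.isoformat() for r in records],
         "age": [r.age for r in records],
         "sex": [r.gender for r in records],
         "icd10": [r.icd10 for r in records]}).to_csv(path, index=False)


def read_life_tables(path) -> LifeTableSet:
    return LifeTableSet.from_csv(path)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SeriesFormatError(f"config file {path} is not a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
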