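"""Years of life lost (YLL) from death records and period life tables.

For one death, YLL is the life-table expected remaining life years at the
decedent's completed age, sex and year of death; daily YLL is the sum over
that day's deaths, stratified by gender, age (<65 / >=65 at death, boundary
assigned to >=65) and cause group:

* non-accidental: ICD-10 chapters A00-R99
* cardiovascular: I00-I99 (a subset of non-accidental)
* respiratory:    J00-J99 (a subset of non-accidental)
* other:          external/injury chapters (S, T, U-Z)

Life-table lookup uses the death year when available, otherwise the latest
earlier available year (e.g. 2016 tables for 2017 deaths when 2017 tables
do not yet exist).  Ages above the table maximum are clamped to the
terminal open age group, so no death is dropped.  No discounting or age
weighting is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "DeathRecord",
    "LifeTableSet",
    "YLLError",
    "classify_cause",
    "yll_for_death",
    "aggregate_daily",
    "STRATA",
]

STRATA = ("all", "male", "female", "nonacc_lt65", "nonacc_ge65",
          "male_ge65", "female_ge65", "resp_ge65", "cv_ge65")

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


class YLLError(ValueError):
    """Invalid death record, cause code or life-table lookup."""


@dataclass(frozen=True)
class DeathRecord:
    """One registered death."""

    death_date: date
    age: int
    gender: str  # "male" | "female"
    icd10: str

    def __post_init__(self):
        if self.age < 0:
            raise YLLError(f"age must be >= 0, got {self.age}")
        if self.gender not in ("male", "female"):
            raise YLLError(f"gender must be male/female, got {self.gender!r}")


def classify_cause(icd10: str) -> frozenset[str]:
    """Cause groups for an ICD-10 code.

    Returns the applicable subset of {non_accidental, cardiovascular,
    respiratory, other}: I-chapter codes are cardiovascular *and*
    non-accidental, J-chapter respiratory *and* non-accidental, any other
    A00-R99 code plain non-accidental, and codes beyond chapter R
    (injuries, external causes) are other.
    """
    m = _ICD10_RE.match(icd10.strip().upper() if isinstance(icd10, str) else "")
    if not m:
        raise YLLError(f"malformed ICD-10 code {icd10!r}")
    letter = m.group(1)
    if letter == "I":
        return frozenset({"non_accidental", "cardiovascular"})
    if letter == "J":
        return frozenset({"non_accidental", "respiratory"})
    if "A" <= letter <= "R":
        return frozenset({"non_accidental"})
    return frozenset({"other"})


class LifeTableSet:
    """Period life tables: (year, sex, age) -> expected remaining life years.

    Stored long: one row per (year, sex, age) with column ``ex`` > 0 and,
    within each (year, sex), strictly decreasing beyond infancy.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"year", "sex", "age", "ex"}
        missing = required - set(table.columns)
        if missing:
            raise YLLError(f"life table missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise YLLError("empty life table")
        if (table["ex"] <= 0).any():
            raise YLLError("life table contains non-positive remaining years")
        t = table.copy()
        t["year"] = t["year"].astype(int)
        t["age"] = t["age"].astype(int)
        self._map = {(int(y), s, int(a)): float(e) for y, s, a, e in
                     zip(t["year"], t["sex"], t["age"], t["ex"])}
        self._max_age = {(y, s): g["age"].max()
                         for (y, s), g in t.groupby(["year", "sex"])}
        self.available_years = sorted(t["year"].unique().tolist())

    @classmethod
    def from_csv(cls, path) -> "LifeTableSet":
        return cls(pd.read_csv(path))

    def lookup_year(self, year: int) -> int:
        """Death year if tabulated, else the latest earlier available year
        (earliest available year for deaths predating all tables)."""
        if year in self.available_years:
            return year
        earlier = [y for y in self.available_years if y < year]
        return max(earlier) if earlier else min(self.available_years)

    def expected_remaining(self, year: int, sex: str, age: int) -> float:
        y = self.lookup_year(year)
        key_max = (y, sex)
        if key_max not in self._max_age:
            raise YLLError(f"life table has no entries for sex {sex!r} in {y}")
        a = min(int(age), int(self._max_age[key_max]))  # terminal open age group
        return self._map[(y, sex, a)]


def yll_for_death(death: DeathRecord, tables: LifeTableSet) -> float:
    """Expected remaining life years at the decedent's age, sex and year."""
    return tables.expected_remaining(death.death_date.year, death.gender,
                                     death.age)


def aggregate_daily(deaths, tables: LifeTableSet,
                    calendar: pd.DatetimeIndex) -> pd.DataFrame:
    """Sum per-death YLL into daily stratified columns over a calendar.

    Days without deaths get zeros; record order never matters.  Raises if
    any death falls outside the calendar, listing the offending records.
    """
    cal = pd.DatetimeIndex(calendar).normalize()
    frame = pd.DataFrame({"date": cal})
    for s in STRATA:
        frame[s] = 0.0
    pos = {d: i for i, d in enumerate(cal)}

    outside = [d for d in deaths if pd.Timestamp(d.death_date) not in pos]
    if outside:
        raise YLLError(
            f"{len(outside)} death(s) outside calendar, e.g. "
            + "; ".join(f"{d.death_date} age={d.age}" for d in outside[:5]))

    cols = {s: frame[s].to_numpy() for s in STRATA}
    for d in deaths:
        y = yll_for_death(d, tables)
        i = pos[pd.Timestamp(d.death_date)]
        groups = classify_cause(d.icd10)
        ge65 = d.age >= 65
        cols["all"][i] += y
        cols[d.gender][i] += y
        if "non_accidental" in groups:
            cols["nonacc_ge65" if ge65 else "nonacc_lt65"][i] += y
        if ge65:
            cols[f"{d.gender}_ge65"][i] += y
            if "respiratory" in groups:
                cols["resp_ge65"][i] += y
            if "cardiovascular" in groups:
                cols["cv_ge65"][i] += y
    for s in STRATA:
        frame[s] = cols[s]
    return frame
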