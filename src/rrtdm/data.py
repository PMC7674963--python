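"""Reading, editing, and fixed-effect classification of test-day data.

A test-day dataset is a tidy table with one daily milk-yield observation per
row.  Before analysis the data are edited with the standard first-lactation
rules (DIM 5-305, yield 5-80 kg, calving age 20-38 months, at least three
surviving tests per cow) and every record is assigned its fixed-effect
classes:

* ``hys_class`` - herd x calving-year x calving-season contemporary group,
  with calving seasons 1 = {Mar, Apr, May, Sep, Oct}, 2 = {Jun, Jul, Aug},
  3 = {Nov, Dec, Jan, Feb};
* ``age_class`` - calving age in months binned 20-23, 24-27, 28-31, >=32;
* ``residual_class`` - one of ten 30-day DIM intervals used for
  heterogeneous residual variances (5-34, 35-64, ..., 275-305).

All editing bounds are inclusive and configurable through
:class:`FilterRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "read_pedigree",
    "read_records",
    "write_records",
    "apply_filters",
    "assign_season",
    "assign_hys_class",
    "assign_age_class",
    "assign_residual_class",
    "classify_records",
]

MISSING_PARENT = "0"

#: Calving-season coding by calendar month.
SEASON_OF_MONTH = {
    3: 1, 4: 1, 5: 1, 9: 1, 10: 1,
    6: 2, 7: 2, 8: 2,
    11: 3, 12: 3, 1: 3, 2: 3,
}

#: Lower bounds of the ten residual-variance DIM classes (closed intervals
#: 5-34, 35-64, ..., 275-305).
RESIDUAL_CLASS_LOWER = np.arange(5, 305, 30)
N_RESIDUAL_CLASSES = 10

#: Upper age bound (months) of fixed-effect age classes 1..3; class 4 is open.
AGE_CLASS_UPPER = (23, 27, 31)

RECORD_COLUMNS = [
    "cow_id", "herd_id", "calving_date", "test_date", "dim",
    "milk_kg", "age_at_calving_months",
]


@dataclass(frozen=True)
class FilterRules:
    """Inclusive editing thresholds for test-day records."""

    min_milk: float = 5.0
    max_milk: float = 80.0
    min_dim: int = 5
    max_dim: int = 305
    min_age: int = 20
    max_age: int = 38
    min_tests: int = 3


def read_pedigree(path, sep=None) -> pd.DataFrame:
    """Read a 3-column pedigree file (animal, sire, dam; 0 = unknown parent).

    Accepts comma- or whitespace-delimited text, with or without a header
    line.  Returns a DataFrame with string columns ``animal_id``,
    ``sire_id``, ``dam_id`` and the sentinel "0" for missing parents.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        header=None,
        dtype=str,
        comment="#",
        skip_blank_lines=True,
    )
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs at least animal, sire, dam columns")
    first = [str(v).lower() for v in df.iloc[0, :3]]
    if any(k in first for k in ("animal", "animal_id", "id")):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3]
    df.columns = ["animal_id", "sire_id", "dam_id"]
    for c in df.columns:
        df[c] = df[c].astype(str).str.strip()
        df.loc[df[c].isin(["", "nan", "NA", ".", "0"]), c] = MISSING_PARENT
    if (df["animal_id"] == MISSING_PARENT).any():
        raise ValueError("animal id 0/blank is reserved for unknown parents")
    dup = df["animal_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate animal id {df.loc[dup, 'animal_id'].iloc[0]!r}")
    self_parent = (df["animal_id"] == df["sire_id"]) | (df["animal_id"] == df["dam_id"])
    if self_parent.any():
        raise ValueError(
            f"animal {df.loc[self_parent, 'animal_id'].iloc[0]!r} listed as its own parent"
        )
    return df


def read_records(path) -> pd.DataFrame:
    """Read a test-day records CSV with header.

    Requires columns ``cow_id, herd_id, calving_date, test_date, milk_kg``;
    ``age_at_calving_months`` and ``dim`` are optional.  Dates are parsed as
    ISO-8601.  DIM is recomputed from the dates; if a ``dim`` column is also
    present and disagrees, the dates win and a warning is issued.
    """
    df = pd.read_csv(path, dtype={"cow_id": str, "herd_id": str})
    required = {"cow_id", "herd_id", "calving_date", "test_date", "milk_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns {sorted(missing)}")
    df["calving_date"] = pd.to_datetime(df["calving_date"], format="ISO8601")
    df["test_date"] = pd.to_datetime(df["test_date"], format="ISO8601")
    dim_from_dates = (df["test_date"] - df["calving_date"]).dt.days
    if "dim" in df.columns:
        bad = (df["dim"].astype(int) != dim_from_dates).sum()
        if bad:
            import warnings

            warnings.warn(
                f"{bad} records have a dim column inconsistent with the dates; "
                "recomputed from dates",
                stacklevel=2,
            )
    df["dim"] = dim_from_dates.astype(int)
    if "age_at_calving_months" not in df.columns:
        df["age_at_calving_months"] = np.nan
    df["age_at_calving_months"] = df["age_at_calving_months"].astype(int)
    return df[RECORD_COLUMNS]


def write_records(df: pd.DataFrame, path) -> None:
    """Write records in the same CSV dialect :func:`read_records` accepts."""
    out = df.copy()
    for c in ("calving_date", "test_date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def apply_filters(records: pd.DataFrame, rules: FilterRules = FilterRules()):
    """Apply the scalar edits, then drop cows with too few surviving tests.

    Returns ``(filtered, audit)`` where ``audit`` counts records removed per
    rule, in application order: milk yield, DIM, calving age (all inclusive
    bounds), then the per-cow minimum-test-count rule on what survives.
    """
    audit: dict[str, int] = {}
    df = records

    keep = df["milk_kg"].between(rules.min_milk, rules.max_milk)
    audit["milk_yield"] = int((~keep).sum())
    df = df[keep]

    keep = df["dim"].between(rules.min_dim, rules.max_dim)
    audit["dim"] = int((~keep).sum())
    df = df[keep]

    keep = df["age_at_calving_months"].between(rules.min_age, rules.max_age)
    audit["calving_age"] = int((~keep).sum())
    df = df[keep]

    counts = df.groupby("cow_id")["milk_kg"].transform("size")
    keep = counts >= rules.min_tests
    audit["min_tests_per_cow"] = int((~keep).sum())
    df = df[keep]

    return df.reset_index(drop=True), audit


def assign_season(month: int) -> int:
    try:
        return SEASON_OF_MONTH[int(month)]
    except KeyError:
        raise ValueError(f"invalid calendar month {month}") from None


def assign_age_class(age_at_calving_months: int) -> int:
    """Calving-age class: 20-23 -> 1, 24-27 -> 2, 28-31 -> 3, >=32 -> 4."""
    age = int(age_at_calving_months)
    if age < 20:
        raise ValueError(
            f"calving age {age} below 20 months; records must be edited first"
        )
    for cls, upper in enumerate(AGE_CLASS_UPPER, start=1):
        if age <= upper:
            return cls
    return 4


def assign_residual_class(dim: int) -> int:
    """Residual-variance DIM class 1..10 (5-34, 35-64, ..., 275-305)."""
    dim = int(dim)
    if dim < 5 or dim > 305:
        raise ValueError(f"DIM {dim} outside [5, 305]")
    return int(np.searchsorted(RESIDUAL_CLASS_LOWER, dim, side="right"))


def assign_hys_class(records: pd.DataFrame) -> pd.Series:
    """Dense 1..K coding of observed (herd, calving year, season) combinations.

    The year and season are taken from the calving date, since seasons are
    defined on calving months.
    """
    cal = pd.to_datetime(records["calving_date"])
    season = cal.dt.month.map(SEASON_OF_MONTH)
    key = pd.DataFrame(
        {"herd": records["herd_id"].values, "year": cal.dt.year.values,
         "season": season.values}
    )
    codes = key.groupby(["herd", "year", "season"], sort=True).ngroup() + 1
    codes.index = records.index
    return codes.astype(int)


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``hys_class``, ``age_class``, ``residual_class`` columns."""
    out = records.copy()
    out["hys_class"] = assign_hys_class(records)
    out["age_class"] = [assign_age_class(a) for a in records["age_at_calving_months"]]
    out["residual_class"] = [assign_residual_class(d) for d in records["dim"]]
    return out
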