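"""Individual-level death records and their CSV serialization.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per deceased patient and the columns of :data:`RECORD_COLUMNS`.  A lightweight
:class:`DeathRecord` dataclass is provided for constructing single rows by
hand (tests, examples); ``records_frame`` converts a list of them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .taxonomy import CauseTaxonomy

#: Column schema of the flat record file, in order.
RECORD_COLUMNS = (
    "diagnosis_year",
    "survival_months",
    "cause",
    "sex",
    "age_group",
    "race",
    "radiotherapy",
    "chemotherapy",
)

SEXES = ("male", "female")
AGE_GROUPS = ("<60", ">=60")
RACES = ("white", "black", "AI/AN/AP")


class RecordParseError(ValueError):
    """A malformed row in a record file (carries the 1-based row number)."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class DeathRecord:
    """One deceased patient.

    ``survival_months`` counts completed months from diagnosis to death;
    ``age_group`` is the binary split used in subgroup analyses.
    """

    diagnosis_year: int
    survival_months: int
    cause: str
    sex: str = "male"
    age_group: str = ">=60"
    race: str = "white"
    radiotherapy: bool = False
    chemotherapy: bool = False

    def __post_init__(self) -> None:
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.race not in RACES:
            raise ValueError(f"race must be one of {RACES}")


def records_frame(records: Iterable[DeathRecord]) -> pd.DataFrame:
    """Build the canonical DataFrame from individual :class:`DeathRecord` s."""
    rows = [asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return _coerce(df)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["diagnosis_year"] = df["diagnosis_year"].astype(int)
    df["survival_months"] = df["survival_months"].astype(int)
    for col in ("cause", "sex", "age_group", "race"):
        df[col] = df[col].astype(str)
    for col in ("radiotherapy", "chemotherapy"):
        df[col] = df[col].astype(bool)
    return df


def validate_records(df: pd.DataFrame, taxonomy: CauseTaxonomy | None = None) -> None:
    """Raise if the record table violates its invariants."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    if len(df) and (df["survival_months"] < 0).any():
        bad = int(df.index[df["survival_months"] < 0][0])
        raise ValueError(f"negative survival_months at index {bad}")
    if taxonomy is not None and len(df):
        unknown = set(df["cause"].unique()) - set(taxonomy.categories)
        if unknown:
            raise ValueError(f"cause labels not in taxonomy: {sorted(unknown)}")


def write_records(records: pd.DataFrame | Sequence[DeathRecord], path: str | Path) -> None:
    """Write records as UTF-8 CSV with the documented header; booleans as 0/1."""
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    validate_records(df)
    out = df.loc[:, list(RECORD_COLUMNS)].copy()
    out["radiotherapy"] = out["radiotherapy"].astype(int)
    out["chemotherapy"] = out["chemotherapy"].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_records(path: str | Path, taxonomy: CauseTaxonomy | None = None) -> pd.DataFrame:
    """Read a record CSV back into the canonical DataFrame.

    Unknown extra columns are preserved in the returned frame but ignored by
    every analysis.  Malformed rows raise :class:`RecordParseError` with the
    1-based data row number; labels outside ``taxonomy`` raise ``ValueError``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise RecordParseError(0, f"header missing columns {missing}")
    df = raw.copy()
    for col, caster in (("diagnosis_year", int), ("survival_months", int)):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            bad = int(df.index[converted.isna()][0])
            raise RecordParseError(bad + 1, f"non-integer {col}: {df[col].iloc[bad]!r}")
        df[col] = converted.astype(int)
    if (df["survival_months"] < 0).any():
        bad = int(df.index[df["survival_months"] < 0][0])
        raise RecordParseError(bad + 1, "survival_months must be >= 0")
    for col in ("radiotherapy", "chemotherapy"):
        ok = df[col].isin(["0", "1", "True", "False"])
        if not ok.all():
            bad = int(df.index[~ok][0])
            raise RecordParseError(bad + 1, f"{col} must be 0/1, got {df[col].iloc[bad]!r}")
        df[col] = df[col].isin(["1", "True"])
    for col, levels in (("sex", SEXES), ("age_group", AGE_GROUPS), ("race", RACES)):
        ok = df[col].isin(levels)
        if not ok.all():
            bad = int(df.index[~ok][0])
            raise RecordParseError(bad + 1, f"{col} must be one of {levels}, got {df[col].iloc[bad]!r}")
    validate_records(df, taxonomy)
    return df
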