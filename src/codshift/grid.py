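"""Aggregation of death records onto the (diagnosis year, survival month) grid.

Each grid cell — one diagnosis year crossed with one completed survival month
— is a "sample dot": the set of patients diagnosed that year who died in that
month, with a total count n_ij and per-cause counts m_ij.  The dots are the
units of the empirical-Bayes smoothing and the pattern clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CountCube", "build_count_cube", "filter_small_dots"]


@dataclass(frozen=True)
class CountCube:
    """Dense death-count grid.

    ``counts``: DataFrame indexed by a (year, month) MultiIndex covering the
    full declared axes (missing cells are zero rows), one integer column per
    cause.  ``n`` (total deaths per dot) is the row sum.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative death counts")

    @property
    def years(self) -> np.ndarray:
        return self.counts.index.get_level_values("year").unique().to_numpy()

    @property
    def months(self) -> np.ndarray:
        return self.counts.index.get_level_values("month").unique().to_numpy()

    @property
    def causes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n(self) -> pd.Series:
        """Total deaths n_ij per (year, month) dot."""
        return self.counts.sum(axis=1)

    def to_long(self) -> pd.DataFrame:
        """Long (year, month, cause, count) table, e.g. for a TSV dump."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["year", "month", "cause", "count"]
        return long

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, lineterminator="\n")


def build_count_cube(
    records: pd.DataFrame,
    month_max: int = 36,
    causes: list[str] | None = None,
    years: list[int] | None = None,
) -> CountCube:
    """Tabulate records into the dense (year x month) x cause count grid.

    Months ``>= month_max`` are dropped (the grid covers completed months
    ``0..month_max-1``).  The cause column order follows ``causes`` when
    given (so the grid can carry taxonomy order and all-zero causes),
    otherwise the sorted labels present in the data.
    """
    if month_max < 1:
        raise ValueError("month_max must be >= 1")
    kept = records.loc[records["survival_months"] < month_max]
    if causes is None:
        causes = sorted(kept["cause"].unique())
    if years is None:
        years = sorted(kept["diagnosis_year"].unique())
    months = list(range(month_max))
    table = (
        kept.groupby(["diagnosis_year", "survival_months", "cause"], observed=True)
        .size()
        .unstack("cause", fill_value=0)
    )
    full_index = pd.MultiIndex.from_product([years, months], names=["year", "month"])
    table = table.reindex(index=full_index, columns=causes, fill_value=0).astype(int)
    table.index.names = ["year", "month"]
    return CountCube(table)


def filter_small_dots(cube: CountCube, min_n: int = 20) -> CountCube:
    """Drop sample dots with fewer than ``min_n`` deaths (pre-processing
    before clustering); the removal is logged with a count."""
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    keep = cube.n >= min_n
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_small_dots: removed %d of %d dots with n < %d", removed, len(keep), min_n)
    return CountCube(cube.counts.loc[keep])
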