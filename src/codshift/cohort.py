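"""Cohort exclusions, follow-up cutoff, and era grouping.

The era comparison contrasts deaths among patients diagnosed in a
pre-immunotherapy window (default 2000-2011) with deaths among patients
diagnosed after checkpoint-inhibitor approval (default 2015-2017).  Years in
between (default 2012-2014, plus 2018 with incomplete 3-year follow-up) are
excluded from grouped analyses, and only deaths within the follow-up cutoff
(default: within three years, i.e. completed survival months 0..35) are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .taxonomy import CauseGroup, CauseTaxonomy, default_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["EraDesign", "EraSplit", "apply_exclusions", "assign_era"]


@dataclass(frozen=True)
class EraDesign:
    """Year windows and follow-up cutoff for the era comparison.

    ``followup_cutoff_months``: deaths with survival_months >= cutoff are
    dropped from both era groups ("died within three years" keeps completed
    months 0..35 under the default 36).
    """

    pre_years: tuple[int, int] = (2000, 2011)
    immuno_years: tuple[int, int] = (2015, 2017)
    excluded_years: frozenset[int] = field(default_factory=lambda: frozenset({2012, 2013, 2014, 2018}))
    followup_cutoff_months: int = 36

    def __post_init__(self) -> None:
        if self.followup_cutoff_months < 1:
            raise ValueError("followup_cutoff_months must be >= 1")
        pre = set(range(self.pre_years[0], self.pre_years[1] + 1))
        imm = set(range(self.immuno_years[0], self.immuno_years[1] + 1))
        if pre & imm or pre & self.excluded_years or imm & self.excluded_years:
            raise ValueError("pre/immuno/excluded year sets must be pairwise disjoint")

    def era_of_year(self, year: int) -> str:
        if self.pre_years[0] <= year <= self.pre_years[1]:
            return "pre"
        if self.immuno_years[0] <= year <= self.immuno_years[1]:
            return "immuno"
        return "excluded"


@dataclass(frozen=True)
class EraSplit:
    """Outcome of era assignment: a partition of the input records."""

    pre: pd.DataFrame
    immuno: pd.DataFrame
    excluded: pd.DataFrame
    cutoff_dropped: pd.DataFrame

    @property
    def total(self) -> int:
        return len(self.pre) + len(self.immuno) + len(self.excluded) + len(self.cutoff_dropped)


def apply_exclusions(
    records: pd.DataFrame, taxonomy: CauseTaxonomy | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (retained, unknown-cause) for statistical analyses.

    Deaths whose cause maps to the UNKNOWN group are removed from every
    statistical analysis but returned so they can be counted and reported
    alongside the cause landscape.  Input row order is preserved.
    """
    taxonomy = taxonomy or default_taxonomy()
    groups = records["cause"].map(taxonomy.group)
    if groups.isna().any():
        bad = records["cause"][groups.isna()].iloc[0]
        raise KeyError(f"cause label not in taxonomy: {bad!r}")
    is_unknown = groups == CauseGroup.UNKNOWN
    retained = records.loc[~is_unknown]
    excluded = records.loc[is_unknown]
    if len(records) and retained.empty:
        warnings.warn("all records have unknown cause; analysis set is empty", stacklevel=2)
    if len(excluded):
        logger.info("excluded %d unknown-cause records (%.2f%%)", len(excluded), 100 * len(excluded) / len(records))
    return retained, excluded


def assign_era(records: pd.DataFrame, design: EraDesign | None = None) -> EraSplit:
    """Partition records into pre-era, immunotherapy-era, excluded-year and
    cutoff-dropped sets based solely on diagnosis year and survival months.

    Every input record lands in exactly one output.  Records surviving past
    the follow-up cutoff are dropped from both era groups; records whose year
    lies outside all configured windows go to ``excluded`` with a log notice.
    """
    design = design or EraDesign()
    era = records["diagnosis_year"].map(design.era_of_year)
    known = set(range(design.pre_years[0], design.pre_years[1] + 1))
    known |= set(range(design.immuno_years[0], design.immuno_years[1] + 1))
    known |= design.excluded_years
    stray = records.loc[(era == "excluded") & ~records["diagnosis_year"].isin(known)]
    if len(stray):
        logger.info(
            "%d records with diagnosis years outside all configured windows assigned to excluded: %s",
            len(stray),
            sorted(stray["diagnosis_year"].unique()),
        )
    past_cutoff = records["survival_months"] >= design.followup_cutoff_months
    in_era = era != "excluded"
    return EraSplit(
        pre=records.loc[(era == "pre") & ~past_cutoff],
        immuno=records.loc[(era == "immuno") & ~past_cutoff],
        excluded=records.loc[~in_era],
        cutoff_dropped=records.loc[in_era & past_cutoff],
    )
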