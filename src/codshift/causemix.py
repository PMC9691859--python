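"""Era-wise cause-of-death mix: proportions, relative risks, excess deaths.

All quantities condition on death: a cause's "risk" is its share among all
deaths in an era group, so denominators are total deaths, not person-time.
The era effect on each cause is estimated as a relative risk (immunotherapy
era vs pre-immunotherapy era) either in closed form (crude) or from a
Poisson log-linear model on the stratified count table with the log of each
stratum's total deaths as exposure offset and indicator terms for era, sex,
age group and race (adjusted).  Excess deaths per 100,000 deaths translate a
proportion difference onto the scale registries report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import EraDesign, EraSplit, apply_exclusions, assign_era
from .taxonomy import CauseGroup, CauseTaxonomy, default_taxonomy

__all__ = [
    "RRResult",
    "cause_proportions",
    "crude_rr",
    "stratify_records",
    "adjusted_rr_poisson",
    "subgroup_rr",
    "excess_deaths_per_100k",
    "CauseShiftModel",
    "CauseShiftResults",
]

ADJUST_AXES_DEFAULT = ("sex", "age_group", "race")


@dataclass(frozen=True)
class RRResult:
    """A cause-specific era relative risk with Wald 95% CI and p-value."""

    cause: str
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    subgroup: tuple[str, str] | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.rr) and not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def cause_proportions(group: pd.DataFrame | Mapping[str, int]) -> pd.DataFrame:
    """Count and proportion of each cause among all deaths in a group.

    Accepts a record table or a precomputed ``cause -> count`` mapping (for
    published count tables).  Proportions sum to 1 over the causes present.
    """
    if isinstance(group, pd.DataFrame):
        counts = group["cause"].value_counts().sort_index()
    else:
        counts = pd.Series(dict(group), dtype=float).astype(int)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty group: no deaths to form proportions")
    out = pd.DataFrame({"count": counts, "proportion": counts / total})
    out.index.name = "cause"
    return out


def crude_rr(count1: int, total1: int, count0: int, total0: int, cause: str = "") -> RRResult:
    """Closed-form risk ratio (count1/total1)/(count0/total0) with Wald CI.

    The log-scale standard error is sqrt(1/count1 - 1/total1 + 1/count0 -
    1/total0).  A zero numerator count triggers a 0.5 continuity correction
    (flagged); both counts zero yields an undefined, flagged result.
    """
    if total1 <= 0 or total0 <= 0:
        raise ValueError("group totals must be positive")
    if count1 < 0 or count0 < 0:
        raise ValueError("counts must be nonnegative")
    flags: list[str] = []
    if count1 == 0 and count0 == 0:
        return RRResult(cause, math.nan, math.nan, math.nan, math.nan, False, flags=("undefined",))
    c1, t1, c0, t0 = float(count1), float(total1), float(count0), float(total0)
    if count1 == 0 or count0 == 0:
        flags.append("continuity-corrected")
        c1 += 0.5
        c0 += 0.5
        t1 += 0.5
        t0 += 0.5
    rr = (c1 / t1) / (c0 / t0)
    se = math.sqrt(1.0 / c1 - 1.0 / t1 + 1.0 / c0 - 1.0 / t0)
    z = stats.norm.ppf(0.975)
    lo, hi = math.exp(math.log(rr) - z * se), math.exp(math.log(rr) + z * se)
    p = 2.0 * stats.norm.sf(abs(math.log(rr)) / se) if se > 0 else 1.0
    return RRResult(cause, rr, lo, hi, float(p), adjusted=False, flags=tuple(flags))


def stratify_records(
    pre: pd.DataFrame,
    immuno: pd.DataFrame,
    cause_labels: Sequence[str],
    adjust_axes: Sequence[str] = ADJUST_AXES_DEFAULT,
) -> pd.DataFrame:
    """Build the (era x adjustment axes) count table for one cause group.

    One row per stratum with columns ``era`` (0 = pre, 1 = immunotherapy),
    the axis levels, ``cause_count`` and ``total``.  Strata with zero total
    deaths are collapsed away.
    """
    frames = []
    for era, df in ((0, pre), (1, immuno)):
        if adjust_axes:
            g = df.groupby(list(adjust_axes), observed=True)
            tab = g.size().rename("total").to_frame()
            tab["cause_count"] = g.apply(
                lambda d: int(d["cause"].isin(cause_labels).sum()), include_groups=False
            )
            tab = tab.reset_index()
        else:
            tab = pd.DataFrame(
                {"total": [len(df)], "cause_count": [int(df["cause"].isin(cause_labels).sum())]}
            )
        tab.insert(0, "era", era)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    return out.loc[out["total"] > 0].reset_index(drop=True)


def adjusted_rr_poisson(
    strata: pd.DataFrame,
    adjust_axes: Sequence[str] = ADJUST_AXES_DEFAULT,
    cause: str = "",
    subgroup: tuple[str, str] | None = None,
) -> RRResult:
    """Era relative risk from a Poisson log-linear model on stratified counts.

    Fits ``cause_count ~ era + adjust_axes`` with ``log(total)`` offset by
    iteratively reweighted least squares; the era coefficient's exponential
    is the adjusted RR, with Wald CI and two-sided p from the observed
    information.  A cause entirely absent from one era (separation) triggers
    a 0.5-per-cell continuity-corrected refit, flagged.
    """
    if (strata["total"] <= 0).any():
        raise ValueError("every stratum must have a positive death total")
    flags: list[str] = []
    y = strata["cause_count"].to_numpy(dtype=float)
    era = strata["era"].to_numpy()
    if y[era == 1].sum() == 0 or y[era == 0].sum() == 0:
        flags.append("continuity-corrected")
        y = y + 0.5
    X = pd.DataFrame({"const": 1.0, "era": strata["era"].astype(float)})
    for axis in adjust_axes:
        dummies = pd.get_dummies(strata[axis], prefix=axis, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    offset = np.log(strata["total"].to_numpy(dtype=float))
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        grad = np.abs(model.score(res.params)).max()
        raise RuntimeError(f"Poisson IRLS did not converge in 100 iterations (|grad|={grad:.3e})")
    beta = float(res.params["era"])
    se = float(res.bse["era"])
    z = stats.norm.ppf(0.975)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 1.0
    return RRResult(
        cause,
        math.exp(beta),
        math.exp(beta - z * se),
        math.exp(beta + z * se),
        float(p),
        adjusted=True,
        subgroup=subgroup,
        flags=tuple(flags),
    )


def subgroup_rr(
    pre: pd.DataFrame,
    immuno: pd.DataFrame,
    axis: str,
    level: str,
    cause_labels: Sequence[str],
    adjust_axes: Sequence[str] = ADJUST_AXES_DEFAULT,
    cause: str = "",
) -> RRResult:
    """Adjusted era RR within one subgroup (e.g. sex = female).

    Restricts both era groups to the subgroup, adjusts for the remaining
    demographic axes, and tags the result with the subgroup.  Treatment
    flags (boolean columns) are accepted as axes with levels "1"/"0".
    """
    def restrict(df: pd.DataFrame) -> pd.DataFrame:
        col = df[axis]
        if col.dtype == bool:
            return df.loc[col == (level in ("1", "True", "true"))]
        return df.loc[col.astype(str) == level]

    sub_pre, sub_imm = restrict(pre), restrict(immuno)
    if sub_pre.empty or sub_imm.empty:
        return RRResult(cause, math.nan, math.nan, math.nan, math.nan, True, (axis, level), ("empty-subgroup",))
    remaining = tuple(a for a in adjust_axes if a != axis)
    strata = stratify_records(sub_pre, sub_imm, cause_labels, remaining)
    return adjusted_rr_poisson(strata, remaining, cause=cause, subgroup=(axis, level))


def excess_deaths_per_100k(count1: int, total1: int, count0: int, total0: int) -> float:
    """(count1/total1 - count0/total0) x 100,000 — signed excess deaths of a
    cause per 100,000 deaths, immunotherapy era minus pre era."""
    if total1 <= 0 or total0 <= 0:
        raise ValueError("group totals must be positive")
    return (count1 / total1 - count0 / total0) * 100_000.0


class CauseShiftModel:
    """Era comparison of the cause-of-death mix over a record table.

    Applies the unknown-cause exclusion and era grouping, then ``fit()``
    estimates, for every cause label and for the three broad cause groups,
    the era proportions, crude and adjusted relative risks, and excess
    deaths per 100,000 deaths.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        taxonomy: CauseTaxonomy | None = None,
        era_design: EraDesign | None = None,
    ):
        self.taxonomy = taxonomy or default_taxonomy()
        self.design = era_design or EraDesign()
        retained, self.unknown_excluded = apply_exclusions(records, self.taxonomy)
        self.split: EraSplit = assign_era(retained, self.design)

    @property
    def pre(self) -> pd.DataFrame:
        return self.split.pre

    @property
    def immuno(self) -> pd.DataFrame:
        return self.split.immuno

    def _targets(self) -> list[tuple[str, tuple[str, ...]]]:
        targets: list[tuple[str, tuple[str, ...]]] = []
        for grp in (CauseGroup.LUNG_CANCER, CauseGroup.NON_LUNG_CANCER, CauseGroup.NON_CANCER):
            targets.append((grp.value, self.taxonomy.labels_in_group(grp)))
        seen = {t for _, labels in targets for t in labels if len(labels) == 1}
        for label in self.taxonomy.categories:
            if self.taxonomy.group(label) is not CauseGroup.UNKNOWN and label not in seen:
                targets.append((label, (label,)))
        return targets

    def fit(self, adjust_axes: Sequence[str] = ADJUST_AXES_DEFAULT) -> "CauseShiftResults":
        if self.pre.empty or self.immuno.empty:
            raise ValueError("both era groups must be non-empty")
        t1, t0 = len(self.immuno), len(self.pre)
        rows = []
        for name, labels in self._targets():
            c1 = int(self.immuno["cause"].isin(labels).sum())
            c0 = int(self.pre["cause"].isin(labels).sum())
            crude = crude_rr(c1, t1, c0, t0, cause=name)
            strata = stratify_records(self.pre, self.immuno, labels, adjust_axes)
            adj = adjusted_rr_poisson(strata, adjust_axes, cause=name)
            rows.append(
                {
                    "cause": name,
                    "count_pre": c0,
                    "count_immuno": c1,
                    "prop_pre": c0 / t0,
                    "prop_immuno": c1 / t1,
                    "crude_rr": crude.rr,
                    "crude_ci_low": crude.ci_low,
                    "crude_ci_high": crude.ci_high,
                    "rr": adj.rr,
                    "ci_low": adj.ci_low,
                    "ci_high": adj.ci_high,
                    "p_value": adj.p_value,
                    "excess_per_100k": excess_deaths_per_100k(c1, t1, c0, t0),
                    "flags": ",".join(adj.flags + crude.flags),
                }
            )
        table = pd.DataFrame(rows).set_index("cause")
        # BH-adjusted p-values are reported alongside but never gate anything
        table["p_bh"] = _benjamini_hochberg(table["p_value"].to_numpy())
        return CauseShiftResults(self, table, tuple(adjust_axes))

    def subgroup(
        self,
        axis: str,
        level: str,
        cause_group: str | CauseGroup,
        adjust_axes: Sequence[str] = ADJUST_AXES_DEFAULT,
    ) -> RRResult:
        labels = self.taxonomy.resolve_cause_group(cause_group)
        name = cause_group.value if isinstance(cause_group, CauseGroup) else str(cause_group)
        return subgroup_rr(self.pre, self.immuno, axis, level, labels, adjust_axes, cause=name)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    ok = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class CauseShiftResults:
    """Per-cause era comparison table with a text summary and TSV export."""

    model: CauseShiftModel
    table: pd.DataFrame
    adjust_axes: tuple[str, ...] = ADJUST_AXES_DEFAULT

    def summary(self) -> str:
        t1, t0 = len(self.model.immuno), len(self.model.pre)
        lines = [
            "Cause-of-death mix: immunotherapy era vs pre-immunotherapy era",
            f"  deaths: pre={t0}  immuno={t1}  (unknown-cause excluded: {len(self.model.unknown_excluded)})",
            f"  adjusted for: {', '.join(self.adjust_axes) or '(none)'}",
            "",
            f"  {'cause':<38}{'pre %':>8}{'imm %':>8}{'RR':>8}{'95% CI':>18}{'p':>10}{'excess/100k':>13}",
        ]
        for cause, r in self.table.iterrows():
            ci = f"[{r.ci_low:.3f}, {r.ci_high:.3f}]"
            lines.append(
                f"  {cause:<38}{100 * r.prop_pre:>8.1f}{100 * r.prop_immuno:>8.1f}"
                f"{r.rr:>8.3f}{ci:>18}{r.p_value:>10.2g}{r.excess_per_100k:>13.1f}"
            )
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_long(self) -> pd.DataFrame:
        """Forest-plot-ready long format (one row per cause and estimate type)."""
        rows = []
        for cause, r in self.table.iterrows():
            rows.append((cause, "crude", r.crude_rr, r.crude_ci_low, r.crude_ci_high, np.nan))
            rows.append((cause, "adjusted", r.rr, r.ci_low, r.ci_high, r.p_value))
        return pd.DataFrame(rows, columns=["cause", "estimate", "rr", "ci_low", "ci_high", "p_value"])
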