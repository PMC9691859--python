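"""Monthly death-risk curves, Lowess smoothing, AUC contrasts, Wilcoxon test.

The monthly death risk (discrete hazard) of a cause group is the number of
deaths from that group during a survival month divided by the patients still
alive at the month's start.  Within a deceased-only cohort truncated at the
follow-up cutoff, "at risk" means "not yet dead" inside the window, so the
all-cause risk obeys the life-table identity: the cumulative product of
(1 - risk) equals the empirical fraction surviving past each month.

Risk curves are smoothed with classical Lowess (locally weighted linear
regression with tricube neighbourhood weights and optional bisquare
robustifying passes); era contrasts are summarized as the percent reduction
in the area under the smoothed curve and tested with the Wilcoxon
matched-pairs signed-rank test on the paired monthly risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import CauseGroup, CauseTaxonomy, default_taxonomy

__all__ = [
    "HazardCurve",
    "monthly_hazard",
    "lowess_smooth",
    "auc_trapezoid",
    "percent_risk_reduction",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "HazardContrast",
    "HazardContrastResults",
]


@dataclass(frozen=True)
class HazardCurve:
    """Per-month death risk of a cause group within one era group.

    ``risk[j] = deaths[j] / at_risk[j]``; months with nobody at risk are
    dropped from the grid.  ``smoothed`` and ``auc`` (trapezoidal area under
    the smoothed curve) are populated by :meth:`smooth`.
    """

    cause_group: str
    months: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    risk: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (np.diff(self.at_risk) > 0).any():
            raise ValueError("at_risk must be nonincreasing")
        if ((self.risk < 0) | (self.risk > 1)).any():
            raise ValueError("risk must lie in [0, 1]")
        if (self.deaths > self.at_risk).any():
            raise ValueError("deaths cannot exceed at_risk")

    @property
    def auc(self) -> float:
        values = self.smoothed if self.smoothed is not None else self.risk
        return auc_trapezoid(self.months, values)

    def smooth(self, frac: float = 0.3, robust_iters: int = 1) -> "HazardCurve":
        fitted = lowess_smooth(self.months.astype(float), self.risk, frac, robust_iters)
        return replace(self, smoothed=fitted)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"month": self.months, "at_risk": self.at_risk, "deaths": self.deaths, "risk": self.risk}
        )
        if self.smoothed is not None:
            out["smoothed"] = self.smoothed
        return out


def monthly_hazard(
    records_group: pd.DataFrame,
    cause_group: str | CauseGroup,
    M: int = 36,
    taxonomy: CauseTaxonomy | None = None,
) -> HazardCurve:
    """Raw monthly death-risk curve of ``cause_group`` over months 0..M-1.

    ``at_risk[j]`` counts group records with survival_months >= j (alive at
    the month's start within the deceased-only window); ``deaths[j]`` counts
    records dying in month j of a cause in the group.  ``cause_group`` may
    be a broad group name or a single taxonomy label.
    """
    if records_group.empty:
        raise ValueError("empty record group")
    taxonomy = taxonomy or default_taxonomy()
    labels = set(taxonomy.resolve_cause_group(cause_group))
    name = cause_group.value if isinstance(cause_group, CauseGroup) else str(cause_group)
    months_all = records_group["survival_months"].to_numpy()
    is_cause = records_group["cause"].isin(labels).to_numpy()
    grid = np.arange(M)
    total_by_month = np.bincount(np.clip(months_all, 0, None), minlength=M)[:M]
    beyond = int((months_all >= M).sum())
    # alive at start of month j = those dying at j or later (incl. past the grid)
    at_risk = total_by_month[::-1].cumsum()[::-1] + beyond
    deaths = np.bincount(months_all[is_cause & (months_all < M)], minlength=M)[:M]
    keep = at_risk > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = np.where(keep, deaths / np.where(keep, at_risk, 1), np.nan)
    return HazardCurve(name, grid[keep], at_risk[keep], deaths[keep], risk[keep])


def lowess_smooth(x, y, frac: float = 0.3, robust_iters: int = 1) -> np.ndarray:
    """Classical Lowess: tricube-weighted local linear fits.

    For each x_i, a weighted least-squares line is fitted over the
    ``ceil(frac * n)`` nearest neighbours (at least 2) with tricube weights
    on the scaled distances, then ``robust_iters`` bisquare reweighting
    passes downweight outlying residuals.  Deterministic; exact on globally
    linear data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must lie in (0, 1]")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values")
    r = max(2, math.ceil(frac * n))
    delta = np.ones(n)  # robustness weights
    fitted = y.copy()
    for iteration in range(robust_iters + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:r]
            dmax = d[idx].max()
            if dmax == 0:
                w = np.ones(len(idx))
            else:
                w = (1.0 - (d[idx] / dmax) ** 3) ** 3
                w = np.clip(w, 0.0, None)
            w = w * delta[idx]
            fitted[i] = _weighted_line_at(x[idx], y[idx], w, x[i])
        if iteration == robust_iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def _weighted_line_at(x, y, w, x0: float) -> float:
    """Evaluate the w-weighted least-squares line through (x, y) at x0."""
    sw = w.sum()
    if sw <= 0:
        return float(np.mean(y))
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * max(1.0, (x ** 2).max()):
        return float(ym)  # degenerate neighbourhood: weighted mean
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


def auc_trapezoid(months, values) -> float:
    """Trapezoidal area under a curve sampled on a strictly increasing grid."""
    months = np.asarray(months, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(months) < 2:
        raise ValueError("need at least 2 points")
    if (np.diff(months) <= 0).any():
        raise ValueError("months must be strictly increasing")
    return float(np.trapezoid(values, months))


def percent_risk_reduction(curve_pre: HazardCurve, curve_immuno: HazardCurve) -> float:
    """100 x (AUC_pre - AUC_immuno) / AUC_pre over a shared month grid.

    Positive values mean the monthly death risk fell in the immunotherapy
    era.  NaN (flagged by the caller) when the reference AUC is zero.
    """
    if not np.array_equal(curve_pre.months, curve_immuno.months):
        raise ValueError("curves must share the same month grid")
    a_pre, a_imm = curve_pre.auc, curve_immuno.auc
    if a_pre == 0:
        return math.nan
    return 100.0 * (a_pre - a_imm) / a_pre


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    method: str
    flags: tuple[str, ...] = ()


def wilcoxon_signed_rank(paired_pre, paired_immuno) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test on paired monthly risks.

    Zero differences are dropped (Wilcoxon's convention), absolute
    differences are ranked with average ranks for ties, and the statistic is
    the smaller of the positive/negative rank sums.  The two-sided p-value
    is exact (full enumeration of the 2^n sign assignments) for n <= 12 and
    a tie-corrected normal approximation with continuity correction above.
    """
    d = np.asarray(paired_pre, dtype=float) - np.asarray(paired_immuno, dtype=float)
    if len(np.asarray(paired_pre)) != len(np.asarray(paired_immuno)):
        raise ValueError("paired sequences must have equal length")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", ("all-differences-zero",))
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    flags: tuple[str, ...] = () if n >= 5 else ("fewer-than-5-nonzero-pairs",)
    if n <= 12:
        total = ranks.sum()
        # enumerate W+ over all sign assignments
        sums = np.zeros(1)
        for rk in ranks:
            sums = np.concatenate([sums, sums + rk])
        count = int(((sums <= w + 1e-12) | (sums >= total - w - 1e-12)).sum())
        p = min(1.0, count / 2 ** n)
        return WilcoxonResult(w, p, n, "exact", flags)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return WilcoxonResult(w, 1.0, n, "normal", flags + ("zero-variance",))
    z = (w - mu + 0.5) / math.sqrt(var)  # continuity correction toward the mean
    p = min(1.0, 2.0 * stats.norm.cdf(z))
    return WilcoxonResult(w, float(p), n, "normal", flags)


class HazardContrast:
    """Era contrast of monthly death-risk curves for chosen cause groups.

    Built from the two era record groups (already exclusion-filtered and
    cutoff-truncated); ``fit()`` computes raw and Lowess-smoothed risk
    curves per cause group, AUC-based percent risk reductions, and the
    signed-rank test on the paired monthly risks.
    """

    DEFAULT_GROUPS = (CauseGroup.LUNG_CANCER, CauseGroup.NON_CANCER, CauseGroup.NON_LUNG_CANCER)

    def __init__(
        self,
        pre: pd.DataFrame,
        immuno: pd.DataFrame,
        taxonomy: CauseTaxonomy | None = None,
        M: int = 36,
    ):
        if pre.empty or immuno.empty:
            raise ValueError("both era groups must be non-empty")
        self.pre = pre
        self.immuno = immuno
        self.taxonomy = taxonomy or default_taxonomy()
        self.M = M

    def fit(
        self,
        cause_groups: Sequence[str | CauseGroup] | None = None,
        frac: float = 0.3,
        robust_iters: int = 1,
        wilcoxon_on_smoothed: bool = False,
    ) -> "HazardContrastResults":
        cause_groups = cause_groups or self.DEFAULT_GROUPS
        curves: dict[str, tuple[HazardCurve, HazardCurve]] = {}
        rows = []
        for cg in cause_groups:
            c_pre = monthly_hazard(self.pre, cg, self.M, self.taxonomy).smooth(frac, robust_iters)
            c_imm = monthly_hazard(self.immuno, cg, self.M, self.taxonomy).smooth(frac, robust_iters)
            shared = np.intersect1d(c_pre.months, c_imm.months)
            c_pre, c_imm = _restrict(c_pre, shared), _restrict(c_imm, shared)
            reduction = percent_risk_reduction(c_pre, c_imm)
            pre_vals = c_pre.smoothed if wilcoxon_on_smoothed else c_pre.risk
            imm_vals = c_imm.smoothed if wilcoxon_on_smoothed else c_imm.risk
            wil = wilcoxon_signed_rank(pre_vals, imm_vals)
            name = c_pre.cause_group
            curves[name] = (c_pre, c_imm)
            rows.append(
                {
                    "cause_group": name,
                    "auc_pre": c_pre.auc,
                    "auc_immuno": c_imm.auc,
                    "percent_reduction": reduction,
                    "wilcoxon_stat": wil.statistic,
                    "wilcoxon_p": wil.p_value,
                    "wilcoxon_method": wil.method,
                    "flags": ",".join(wil.flags) + ("auc-pre-zero" if math.isnan(reduction) else ""),
                }
            )
        return HazardContrastResults(self, curves, pd.DataFrame(rows).set_index("cause_group"))


def _restrict(curve: HazardCurve, months: np.ndarray) -> HazardCurve:
    keep = np.isin(curve.months, months)
    return HazardCurve(
        curve.cause_group,
        curve.months[keep],
        curve.at_risk[keep],
        curve.deaths[keep],
        curve.risk[keep],
        None if curve.smoothed is None else curve.smoothed[keep],
    )


@dataclass
class HazardContrastResults:
    model: HazardContrast
    curves: dict[str, tuple[HazardCurve, HazardCurve]]
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Monthly death-risk contrast (immunotherapy era vs pre-immunotherapy era)",
            f"  months 0..{self.model.M - 1}; deaths: pre={len(self.model.pre)}, immuno={len(self.model.immuno)}",
            "",
            f"  {'cause group':<20}{'AUC pre':>10}{'AUC imm':>10}{'reduction %':>13}{'Wilcoxon p':>12}",
        ]
        for name, r in self.table.iterrows():
            lines.append(
                f"  {name:<20}{r.auc_pre:>10.4f}{r.auc_immuno:>10.4f}"
                f"{r.percent_reduction:>13.1f}{r.wilcoxon_p:>12.3g}"
            )
        return "\n".join(lines)

    def write_tsv(self, directory: str | Path, prefix: str = "hazard") -> None:
        directory = Path(directory)
        self.table.reset_index().to_csv(
            directory / f"{prefix}_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )
        for name, (c_pre, c_imm) in self.curves.items():
            tag = name.replace("/", "_").replace(" ", "_")
            both = pd.concat(
                [c_pre.to_frame().assign(era="pre"), c_imm.to_frame().assign(era="immuno")],
                ignore_index=True,
            )
            both.to_csv(directory / f"{prefix}_{tag}.tsv", sep="\t", index=False, lineterminator="\n")

    def plot(self, cause_group: str, ax=None):
        """Overlay raw and smoothed monthly risk for both eras."""
        import matplotlib.pyplot as plt

        c_pre, c_imm = self.curves[cause_group]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for curve, color, label in ((c_pre, "tab:blue", "pre era"), (c_imm, "tab:red", "immunotherapy era")):
            ax.plot(curve.months, curve.risk, ".", color=color, alpha=0.5)
            ax.plot(curve.months, curve.smoothed, "-", color=color, label=label)
        ax.set_xlabel("survival month")
        ax.set_ylabel("monthly death risk")
        ax.set_title(cause_group)
        ax.legend()
        return ax
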