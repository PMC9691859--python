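"""Empirical-Bayes (Beta-binomial) smoothing of per-dot cause proportions.

For each sample dot (diagnosis year i, survival month j) and cause c, the
probability of dying from c is given a conjugate Beta prior centred on the
year-level cause share Θ_i[c] with prior weight N_j (the mean dot size of
month j across years):

    θ_ijc ~ Beta(N_j Θ_i[c],  N_j − N_j Θ_i[c])

Observing m_ij[c] deaths from cause c out of n_ij deaths in the dot gives the
posterior Beta(N_j Θ_i[c] + m_ij[c], N_j − N_j Θ_i[c] + n_ij − m_ij[c]), whose
mean

    θ̂_ijc = (N_j Θ_i[c] + m_ij[c]) / (N_j + n_ij)

is the smoothed feature.  The shrinkage pulls noisy raw proportions (small
late-month dots) toward the year's overall cause mix, with weight set by how
large a typical dot of that month is — so month-to-month sampling noise is
damped while diagnosis-year structure, the object of interest, is preserved.
Because Σ_c Θ_i[c] = 1, each smoothed row sums to 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CountCube

__all__ = [
    "SmoothingParams",
    "FeatureMatrix",
    "compute_prior_weights",
    "compute_year_proportions",
    "posterior_mean",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Prior weights N_j (per month) and year-level cause shares Θ_i[c].

    ``epsilon`` floors degenerate Beta parameters in any optional
    full-posterior density evaluation; the posterior-mean formula itself
    needs no flooring.
    """

    prior_weights: pd.Series  # index: month j -> N_j
    year_proportions: pd.DataFrame  # index: year i, columns: causes -> Theta_i[c]
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if (self.prior_weights < 0).any():
            raise ValueError("prior weights N_j must be >= 0")
        row_sums = self.year_proportions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            bad = row_sums.index[~np.isclose(row_sums, 1.0, atol=1e-9)][0]
            raise ValueError(f"year proportions for {bad} do not sum to 1")
        if not (0 < self.epsilon <= 1e-3):
            raise ValueError("epsilon must lie in (0, 1e-3]")

    @classmethod
    def from_cube(cls, cube: CountCube, epsilon: float = 1e-6) -> "SmoothingParams":
        return cls(compute_prior_weights(cube), compute_year_proportions(cube), epsilon)


@dataclass(frozen=True)
class FeatureMatrix:
    """Smoothed cause-probability rows θ̂_ij, one per retained sample dot.

    ``theta``: DataFrame indexed by (year, month), one column per cause,
    every value in [0, 1], rows summing to 1.  ``n``: dot sizes n_ij aligned
    with the rows.
    """

    theta: pd.DataFrame
    n: pd.Series = field(repr=False)

    @property
    def years(self) -> np.ndarray:
        return self.theta.index.get_level_values("year").to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.theta.copy()
        out.insert(0, "n", self.n)
        return out.reset_index()

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def compute_prior_weights(cube: CountCube) -> pd.Series:
    """N_j: the arithmetic mean over the cube's years of n_ij, per month j
    (cells absent from the grid count as zero)."""
    if not len(cube.counts):
        raise ValueError("empty count cube")
    n = cube.n
    return n.groupby(level="month").sum() / len(cube.years)


def compute_year_proportions(cube: CountCube) -> pd.DataFrame:
    """Θ_i[c] = Σ_j m_ij[c] / Σ_j n_ij — each year's overall cause shares."""
    totals_by_year = cube.counts.groupby(level="year").sum()
    n_year = totals_by_year.sum(axis=1)
    if (n_year == 0).any():
        bad = n_year.index[n_year == 0].tolist()
        raise ValueError(f"year(s) with zero deaths: {bad}")
    return totals_by_year.div(n_year, axis=0)


def posterior_mean(prior_weight, theta_prior, m, n):
    """Posterior-mean cause probability (N_j θ_prior + m) / (N_j + n).

    Vectorized over numpy inputs.  With no data and no prior weight
    (N_j = n = 0) the prior mean is returned; with N_j = 0 it reduces to the
    raw proportion m/n; with n = 0 it returns the prior mean.
    """
    prior_weight = np.asarray(prior_weight, dtype=float)
    theta_prior = np.asarray(theta_prior, dtype=float)
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if (m > n).any():
        raise ValueError("cause count m exceeds dot total n")
    if (m < 0).any() or (prior_weight < 0).any():
        raise ValueError("counts and prior weights must be nonnegative")
    denom = prior_weight + n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (prior_weight * theta_prior + m) / np.where(denom > 0, denom, 1.0), theta_prior)
    return out if out.ndim else float(out)


def build_feature_matrix(cube: CountCube, params: SmoothingParams) -> FeatureMatrix:
    """Smooth every dot of ``cube`` with ``params``.

    ``cube`` is typically the small-dot-filtered grid while ``params`` come
    from the unfiltered grid (the filter is clustering pre-processing, not
    part of the prior).
    """
    missing = set(cube.causes) - set(params.year_proportions.columns)
    if missing:
        raise KeyError(f"causes absent from smoothing params: {sorted(missing)}")
    idx = cube.counts.index
    years = idx.get_level_values("year")
    months = idx.get_level_values("month")
    if not set(years).issubset(set(params.year_proportions.index)):
        raise KeyError("cube contains years absent from smoothing params")
    if not set(months).issubset(set(params.prior_weights.index)):
        raise KeyError("cube contains months absent from smoothing params")
    N = params.prior_weights.loc[months].to_numpy()
    theta0 = params.year_proportions.loc[years, cube.causes].to_numpy()
    m = cube.counts.to_numpy(dtype=float)
    n = cube.n.to_numpy(dtype=float)
    theta_hat = posterior_mean(N[:, None], theta0, m, n[:, None])
    theta = pd.DataFrame(theta_hat, index=idx, columns=cube.causes)
    return FeatureMatrix(theta=theta, n=cube.n)
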