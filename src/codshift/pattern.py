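"""Unsupervised discovery of death-cause patterns across sample dots.

K-means (squared Euclidean, best of several restarts) on the standardized
smoothed feature matrix partitions the (year, month) dots into death-cause
patterns; each diagnosis year is then assigned the pattern that holds the
majority of its dots.  A seeded UMAP embedding is provided for visualization
only — cluster labels never depend on it.

`DeathPatternModel` wraps the full chain (count grid -> empirical-Bayes
smoothing -> small-dot filter -> k-means) behind a statsmodels-style
``fit()`` returning :class:`DeathPatternResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grid import CountCube, build_count_cube, filter_small_dots
from .smoothing import FeatureMatrix, SmoothingParams, build_feature_matrix
from .taxonomy import CauseTaxonomy, default_taxonomy

__all__ = ["ClusterResult", "cluster_dots", "embed_2d", "DeathPatternModel", "DeathPatternResults"]


@dataclass(frozen=True)
class ClusterResult:
    """K-means partition of the sample dots.

    ``labels``: cluster id per (year, month) row; ``centroids``: per-cluster
    mean feature vectors on the original (unstandardized) scale;
    ``year_pattern``: per year, the majority cluster with its majority
    fraction (cluster id is -1 where the vote is tied); ``inertia``: final
    within-cluster sum of squares on the standardized features.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    year_pattern: pd.DataFrame
    inertia: float
    standardized: bool = True

    @property
    def k(self) -> int:
        return len(self.centroids)

    def year_labels(self) -> pd.Series:
        """Majority cluster id per year (-1 = ambiguous tie)."""
        return self.year_pattern["cluster"]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns carry no information; leave centred at 0
    return (X - mu) / sd


def cluster_dots(
    features: FeatureMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> ClusterResult:
    """K-means on the (optionally z-scored) smoothed features.

    Standardization is on by default: the dominant cause's probability
    (~0.85 for lung cancer) would otherwise swamp the rarer causes that
    carry the era signal.  Deterministic given ``seed``; best of
    ``n_restarts`` initializations by within-cluster sum of squares.
    """
    X_raw = features.theta.to_numpy(dtype=float)
    if not np.isfinite(X_raw).all():
        raise ValueError("non-finite feature values")
    if k > len(X_raw):
        raise ValueError(f"k={k} exceeds number of rows ({len(X_raw)})")
    X = _standardize(X_raw) if standardize else X_raw
    if np.allclose(X, X[0]):
        warnings.warn("all feature rows identical; clustering is degenerate", stacklevel=2)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    lab = km.fit_predict(X)
    labels = pd.Series(lab, index=features.theta.index, name="cluster")
    centroids = features.theta.groupby(labels).mean()
    centroids = centroids.reindex(range(k))
    year_pattern = _year_majority(labels)
    return ClusterResult(labels, centroids, year_pattern, float(km.inertia_), standardize)


def _year_majority(labels: pd.Series) -> pd.DataFrame:
    rows = []
    for year, grp in labels.groupby(level="year"):
        counts = grp.value_counts()
        top = counts.max()
        winners = counts.index[counts == top]
        frac = top / len(grp)
        if len(winners) > 1:
            rows.append((year, -1, frac, True))  # tied vote: ambiguous
        else:
            rows.append((year, int(winners[0]), frac, False))
    return pd.DataFrame(rows, columns=["year", "cluster", "majority_fraction", "ambiguous"]).set_index("year")


def embed_2d(features: FeatureMatrix, seed: int = 0, standardize: bool = True) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of the feature rows, for plotting only."""
    import umap  # deferred: numba compilation is costly at import time

    X = features.theta.to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 rows to embed")
    if standardize:
        X = _standardize(X)
    n_neighbors = min(15, len(X) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
        coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=features.theta.index, columns=["embed_x", "embed_y"])


class DeathPatternModel:
    """Death-cause pattern discovery over a deceased-patient record table.

    Aggregates records onto the (diagnosis year, survival month) grid,
    smooths per-dot cause proportions with the empirical-Bayes procedure
    (priors computed on the unfiltered grid), drops dots with fewer than
    ``min_dot_size`` deaths, and clusters the remaining dots.

    Parameters
    ----------
    records
        Record table (unknown-cause deaths should already be excluded).
    month_max
        Number of survival months on the grid (months ``0..month_max-1``).
    min_dot_size
        Pre-processing filter: dots with fewer deaths are excluded from
        clustering (default 20).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        taxonomy: CauseTaxonomy | None = None,
        month_max: int = 36,
        min_dot_size: int = 20,
    ):
        self.taxonomy = taxonomy or default_taxonomy()
        causes = [c for c in self.taxonomy.categories if c in set(records["cause"])]
        self.cube: CountCube = build_count_cube(records, month_max=month_max, causes=causes)
        self.params: SmoothingParams = SmoothingParams.from_cube(self.cube)
        self.filtered: CountCube = filter_small_dots(self.cube, min_dot_size)
        self.features: FeatureMatrix = build_feature_matrix(self.filtered, self.params)

    def fit(
        self,
        k: int = 2,
        seed: int = 0,
        n_restarts: int = 10,
        standardize: bool = True,
        cluster_on_embedding: bool = False,
    ) -> "DeathPatternResults":
        if cluster_on_embedding:
            coords = embed_2d(self.features, seed=seed, standardize=standardize)
            proxy = FeatureMatrix(theta=coords, n=self.features.n)
            clusters = cluster_dots(proxy, k=k, seed=seed, n_restarts=n_restarts, standardize=False)
            return DeathPatternResults(self, clusters, _embedding=coords)
        clusters = cluster_dots(self.features, k=k, seed=seed, n_restarts=n_restarts, standardize=standardize)
        return DeathPatternResults(self, clusters)


@dataclass
class DeathPatternResults:
    """Fitted pattern partition with plotting and export helpers."""

    model: DeathPatternModel
    clusters: ClusterResult
    _embedding: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def labels(self) -> pd.Series:
        return self.clusters.labels

    @property
    def year_pattern(self) -> pd.DataFrame:
        return self.clusters.year_pattern

    def embedding(self, seed: int = 0) -> pd.DataFrame:
        if self._embedding is None:
            self._embedding = embed_2d(self.model.features, seed=seed)
        return self._embedding

    def to_frame(self, with_embedding: bool = False, seed: int = 0) -> pd.DataFrame:
        out = pd.DataFrame(
            {"n": self.model.features.n, "cluster": self.clusters.labels},
            index=self.clusters.labels.index,
        )
        if with_embedding:
            out = out.join(self.embedding(seed))
        return out.reset_index()

    def summary(self) -> str:
        yp = self.year_pattern
        lines = [
            "Death-cause pattern clustering",
            f"  dots clustered : {len(self.labels)}",
            f"  k              : {self.clusters.k}",
            f"  within-SS      : {self.clusters.inertia:.4f}",
            "  year -> pattern (majority fraction):",
        ]
        for year, row in yp.iterrows():
            tag = "ambiguous" if row["ambiguous"] else f"pattern {int(row['cluster'])}"
            lines.append(f"    {year}: {tag} ({row['majority_fraction']:.2f})")
        return "\n".join(lines)

    def plot_embedding(self, seed: int = 0, ax=None):
        """Scatter of the 2-D embedding colored by cluster label."""
        import matplotlib.pyplot as plt

        coords = self.embedding(seed)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        for cl, grp in coords.groupby(self.labels):
            ax.scatter(grp["embed_x"], grp["embed_y"], s=14, label=f"pattern {cl}")
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.legend()
        return ax
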