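"""Protrusion-enrichment filtering and status clustering of fold-change tables.

Genes are filtered on the reference dataset (protrusion vs. cell body of the
study system) with strict thresholds FC > 1.6 and FDR q < 0.05, then their
log2 fold changes across the external comparison datasets are scaled and
centred and clustered with k-means. The cluster count is combinatorial, not
tuned: each gene can be enriched or depleted in each of D comparison cell
types, giving k = 2**D possible transcript statuses (k = 8 for D = 3). The
"universal" cluster is the one whose centroid is positive in every dataset —
mRNAs targeted to protrusions in all cell types.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterModel",
    "StatusKMeans",
    "bh_fdr",
    "filter_enriched",
    "zscale_columns",
    "kmeans",
    "cluster_foldchanges",
    "identify_universal_cluster",
    "status_cluster_count",
    "log2fc_columns",
]

DEFAULT_FC_HI = 1.6
DEFAULT_FC_LO = 0.625
DEFAULT_Q_MAX = 0.05


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2fc_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-dataset log2 fold-change columns, in table order."""
    return [c for c in table.columns if c.startswith("log2fc_")]


def filter_enriched(
    table: pd.DataFrame,
    ref_dataset: str | None = None,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
    q_max: float = DEFAULT_Q_MAX,
) -> tuple[pd.Index, pd.Index]:
    """Split genes into protrusion-enriched and -depleted sets.

    Enriched: FC > fc_hi and q < q_max on the reference dataset; depleted:
    FC < fc_lo and q < q_max, where FC = 2**log2fc. Inequalities are strict,
    so boundary genes are excluded. Returns (enriched_ids, depleted_ids).
    """
    if not (fc_lo < 1 < fc_hi) or fc_lo <= 0:
        raise ValueError("thresholds must satisfy 0 < fc_lo < 1 < fc_hi")
    if len(table) == 0:
        return pd.Index([]), pd.Index([])
    if ref_dataset is None:
        ref_col = log2fc_columns(table)[0]
    else:
        ref_col = f"log2fc_{ref_dataset}"
    fc = 2.0 ** table[ref_col].to_numpy(dtype=float)
    q = table["q_value"].to_numpy(dtype=float)
    enriched = table.loc[(fc > fc_hi) & (q < q_max), "gene_id"]
    depleted = table.loc[(fc < fc_lo) & (q < q_max), "gene_id"]
    return pd.Index(enriched), pd.Index(depleted)


def zscale_columns(
    matrix: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale and centre each column to mean 0, SD 1 (n-1 denominator).

    Returns ``(standardized, means, sds)``; a zero-variance column is an
    error naming the offending column.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance column(s): {bad.tolist()}")
    return (X - means) / sds, means, sds


@dataclasses.dataclass
class ClusterModel:
    """Fitted k-means state over a filtered gene set."""

    k: int
    centroids: np.ndarray  # k x D, standardized units
    centroids_raw: np.ndarray  # k x D, log2fc units
    assignments: dict  # gene_id -> cluster label (0..k-1)
    column_means: np.ndarray
    column_sds: np.ndarray
    inertia: float
    seed: int
    n_starts: int
    datasets: list[str] = dataclasses.field(default_factory=list)


class StatusKMeans(ClusterMixin, BaseEstimator):
    """Scale-and-centre followed by k-means, as one sklearn estimator.

    Standardisation uses the n-1 SD; clustering is k-means++ Lloyd's with
    ``n_init`` restarts, keeping the solution with the lowest inertia.
    Defaults reflect the three-comparison design: k = 2**3 = 8 statuses.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : centroids in standardized units, shape (k, D).
    cluster_centers_raw_ : centroids back-transformed to log2fc units.
        Universality is judged here: standardisation can flip the sign of a
        column whose values are mostly negative.
    labels_ : cluster label per row.
    column_means_, column_sds_ : the scaling parameters.
    inertia_ : total within-cluster sum of squares (standardized units).
    """

    def __init__(
        self,
        n_clusters: int = 8,
        n_init: int = 20,
        random_state: int = 0,
        max_iter: int = 300,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y=None) -> "StatusKMeans":
        X = np.asarray(X, dtype=float)
        if self.n_clusters < 1 or self.n_clusters > X.shape[0]:
            raise ValueError("n_clusters must be in [1, n_rows]")
        Z, means, sds = zscale_columns(X)
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_init,
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(Z)
        self.cluster_centers_ = km.cluster_centers_
        self.cluster_centers_raw_ = km.cluster_centers_ * sds + means
        self.labels_ = km.labels_
        self.column_means_ = means
        self.column_sds_ = sds
        self.inertia_ = float(km.inertia_)
        self._km = km
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.column_means_) / self.column_sds_
        return self._km.predict(Z)


def kmeans(
    matrix: np.ndarray, k: int = 8, n_starts: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means on an already standardized matrix.

    Returns ``(labels, centroids, inertia)``; thin wrapper over
    :class:`sklearn.cluster.KMeans` with k-means++ seeding and ``n_starts``
    restarts.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 1 or k > X.shape[0]:
        raise ValueError("k must be in [1, n_rows]")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_starts, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def cluster_foldchanges(
    table: pd.DataFrame,
    datasets: Sequence[str],
    k: int = 8,
    n_starts: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """Cluster a gene fold-change table on the named comparison datasets.

    Genes with a missing (NaN) value in any of the datasets are dropped
    before clustering (only genes expressed in all comparison cell types are
    informative about universal targeting).
    """
    cols = [f"log2fc_{d}" for d in datasets]
    sub = table.dropna(subset=cols)
    X = sub[cols].to_numpy(dtype=float)
    est = StatusKMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(X)
    assignments = dict(zip(sub["gene_id"], (int(l) for l in est.labels_)))
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        centroids_raw=est.cluster_centers_raw_,
        assignments=assignments,
        column_means=est.column_means_,
        column_sds=est.column_sds_,
        inertia=est.inertia_,
        seed=seed,
        n_starts=n_starts,
        datasets=list(datasets),
    )


def identify_universal_cluster(model: ClusterModel) -> int | None:
    """Label of the cluster enriched in every comparison dataset, or None.

    Judged on centroids back-transformed to raw log2fc units. If several
    clusters have all-positive centroids, the one with the largest minimum
    coordinate wins (the most uniformly enriched).
    """
    mins = model.centroids_raw.min(axis=1)
    candidates = np.nonzero(np.all(model.centroids_raw > 0, axis=1))[0]
    if candidates.size == 0:
        return None
    return int(candidates[np.argmax(mins[candidates])])


def status_cluster_count(n_datasets: int = 3) -> int:
    """Number of enrichment/depletion status combinations over the
    comparison datasets, obtained by enumeration: 2**D (8 for D = 3)."""
    if n_datasets < 1:
        raise ValueError("need at least one comparison dataset")
    return sum(1 for _ in itertools.product(("enriched", "depleted"), repeat=n_datasets))
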