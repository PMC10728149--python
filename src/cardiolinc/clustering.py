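"""Cell clustering: pairwise dissimilarity, agglomerative trees, and
silhouette-guided selection of the number of clusters.

The number of clusters K is chosen by cutting one hierarchical tree at
each candidate K and keeping the cut with the highest mean silhouette
coefficient, ties resolved toward the smaller K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

METRICS = ("pearson-dissimilarity", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric cell-cell dissimilarities with a zero diagonal."""

    values: np.ndarray
    cell_ids: list[str]
    metric: str = "pearson-dissimilarity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match cell ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        # exact symmetry / zero diagonal for downstream scipy routines
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.values = np.maximum(self.values, 0.0)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterResult:
    """Per-cell labels with the silhouette profile that selected K."""

    labels: pd.Series  # cell_id -> cluster index in 1..K
    k: int
    per_cell_silhouette: pd.Series
    mean_silhouette: float
    linkage: str
    metric: str
    silhouette_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cells_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def pairwise_distance(m: ExpressionMatrix, metric: str = "pearson-dissimilarity") -> DistanceMatrix:
    """Cell-cell dissimilarities over genes.

    ``pearson-dissimilarity`` is 1 - r over genes; a zero-variance cell
    gets r = 0 (distance 1) against every other cell, logged.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    return _pairwise_from_array(m.values.T, list(m.cell_ids), metric)


def _pairwise_from_array(X: np.ndarray, ids: list[str], metric: str) -> DistanceMatrix:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "euclidean":
        d = ssd.squareform(ssd.pdist(X, metric="euclidean"))
    else:
        sd = X.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "%d zero-variance cell(s) under pearson; their correlations set to 0",
                int(degenerate.sum()),
            )
        Xc = X - X.mean(axis=1, keepdims=True)
        denom = np.outer(sd, sd) * X.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ Xc.T) / denom
        r[~np.isfinite(r)] = 0.0
        r = np.clip(r, -1.0, 1.0)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids, metric)


def _linkage(d: DistanceMatrix, linkage: str) -> np.ndarray:
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    condensed = ssd.squareform(d.values, checks=False)
    return sch.linkage(condensed, method=linkage)


def hierarchical_cluster(d: DistanceMatrix, k: int, linkage: str = "average") -> pd.Series:
    """Cut the agglomerative tree into exactly ``k`` groups (labels 1..k)."""
    if not 2 <= k <= d.n_cells:
        raise ValueError(f"K={k} outside [2, n_cells={d.n_cells}]")
    Z = _linkage(d, linkage)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    return _canonical_labels(raw, d.cell_ids)


def _canonical_labels(raw: np.ndarray, cell_ids: list[str]) -> pd.Series:
    """Relabel clusters 1..K in order of first appearance (order-stable)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return pd.Series(out, index=list(cell_ids), name="cluster")


def silhouette_scores(d: DistanceMatrix, labels: pd.Series) -> tuple[pd.Series, float]:
    """Per-cell silhouette s(i) = (b - a)/max(a, b) on precomputed distances.

    Singleton clusters score 0 by convention.
    """
    lab = labels.loc[d.cell_ids].to_numpy()
    n_labels = len(np.unique(lab))
    if n_labels < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if n_labels == len(lab):
        # all-singleton clustering: every s(i) = 0 by the singleton convention
        s = np.zeros(len(lab))
    else:
        s = silhouette_samples(d.values, lab, metric="precomputed")
    per_cell = pd.Series(s, index=list(d.cell_ids), name="silhouette")
    return per_cell, float(per_cell.mean())


def select_k(
    d: DistanceMatrix,
    k_range: range | list[int] | None = None,
    linkage: str = "average",
) -> ClusterResult:
    """Choose K maximizing mean silhouette over ``k_range`` (default 2..10).

    Ties break toward the smaller K; the full silhouette-vs-K table is
    kept on the result for reporting. A single-element k_range forces
    that K regardless of silhouette.
    """
    if k_range is None:
        k_range = range(2, 11)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    ks = [k for k in ks if k <= d.n_cells]
    if not ks:
        raise ValueError("all candidate K exceed the number of cells")
    Z = _linkage(d, linkage)
    rows = []
    best: tuple[float, int, pd.Series, pd.Series] | None = None
    for k in ks:
        raw = sch.fcluster(Z, t=k, criterion="maxclust")
        labels = _canonical_labels(raw, d.cell_ids)
        if labels.nunique() < 2:
            # maxclust could not split (all-zero distances); silhouette undefined
            rows.append((k, np.nan))
            continue
        per_cell, mean_s = silhouette_scores(d, labels)
        rows.append((k, mean_s))
        if best is None or mean_s > best[0] + 1e-12:
            best = (mean_s, k, labels, per_cell)
    if best is None:
        raise ValueError("no candidate K produced at least 2 clusters")
    table = pd.DataFrame(rows, columns=["k", "mean_silhouette"])
    mean_s, k, labels, per_cell = best
    return ClusterResult(
        labels=labels,
        k=k,
        per_cell_silhouette=per_cell,
        mean_silhouette=mean_s,
        linkage=linkage,
        metric=d.metric,
        silhouette_table=table,
    )


class SilhouetteHierarchicalClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering with silhouette-based selection of K.

    scikit-learn style estimator over a cells x genes matrix (or a
    precomputed cell-cell distance matrix with ``metric="precomputed"``).

    Parameters
    ----------
    metric : {"pearson-dissimilarity", "euclidean", "precomputed"}
        Dissimilarity between cells; default 1 - Pearson r over genes.
    linkage : {"average", "complete", "ward"}
    k_min, k_max : int
        Inclusive bounds of the K search (defaults 2..10). Setting
        ``k_min == k_max`` forces that K.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index (1..K) per cell, in input order.
    k_ : int
        Selected number of clusters.
    mean_silhouette_ : float
    silhouette_table_ : DataFrame with columns (k, mean_silhouette).
    per_cell_silhouette_ : ndarray
    """

    def __init__(self, metric: str = "pearson-dissimilarity", linkage: str = "average",
                 k_min: int = 2, k_max: int = 10):
        self.metric = metric
        self.linkage = linkage
        self.k_min = k_min
        self.k_max = k_max

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ids = [f"cell{i}" for i in range(X.shape[0])]
        if self.metric == "precomputed":
            d = DistanceMatrix(X, ids, "precomputed")
        else:
            d = _pairwise_from_array(X, ids, self.metric)
        res = select_k(d, range(self.k_min, self.k_max + 1), self.linkage)
        self.result_ = res
        self.labels_ = res.labels.to_numpy()
        self.k_ = res.k
        self.mean_silhouette_ = res.mean_silhouette
        self.per_cell_silhouette_ = res.per_cell_silhouette.to_numpy()
        self.silhouette_table_ = res.silhouette_table
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
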