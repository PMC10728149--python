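"""Variable-gene detection from the dropout profile, and assignment of
clusters to cell types against a marker database.

The dropout model is Michaelis-Menten shaped: for a gene with mean FPKM
S across cells, the expected fraction of zero observations is
``P = 1 - S/(K_M + S)``. Genes whose gene-wise constant
``K_j = S_j * P_j / (1 - P_j)`` sits significantly above the globally
fitted ``K_M`` drop out more than their mean expression predicts — the
signature of genes expressed in only a subset of cells, i.e. candidate
markers. Cluster-to-cell-type assignment cross-references each cluster's
variable genes with the marker database through a chi-squared
goodness-of-fit (adherence) test; clusters failing it are "Unknown".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from statsmodels.stats.multitest import multipletests

from .io import BIOTYPES, ExpressionMatrix, MarkerDatabase

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dropout statistics and the Michaelis-Menten fit


def dropout_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean FPKM S_j and zero fraction P_j.

    Genes with P_j of exactly 0 or 1 are flagged untestable: the
    gene-wise constant K_j is undefined (or trivially zero) there.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    S = m.values.mean(axis=1)
    P = (m.values == 0).mean(axis=1)
    testable = (P > 0) & (P < 1)
    return pd.DataFrame({"S": S, "P": P, "testable": testable}, index=list(m.gene_ids))


def _mm_dropout(S: np.ndarray, K: float) -> np.ndarray:
    return 1.0 - S / (K + S)


def fit_michaelis_menten(table: pd.DataFrame, min_genes: int = 10) -> tuple[float, float]:
    """Fit the global constant K_M by 1-D nonlinear least squares.

    Minimizes sum_j (P_j - [1 - S_j/(K + S_j)])^2 over K > 0 for the
    testable genes; the standard error comes from the Gauss-Newton
    curvature at the optimum.
    """
    t = table[table["testable"]]
    if len(t) < min_genes:
        raise ValueError(f"only {len(t)} testable genes; need at least {min_genes}")
    S = t["S"].to_numpy()
    P = t["P"].to_numpy()

    def rss(log_k: float) -> float:
        return float(np.sum((P - _mm_dropout(S, np.exp(log_k))) ** 2))

    hi = max(float(S.max()) * 10.0, 1.0)
    res = scipy.optimize.minimize_scalar(
        rss, bounds=(np.log(1e-8), np.log(hi)), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {res.message}")
    k_hat = float(np.exp(res.x))
    # Gauss-Newton SE: J_j = dP_hat/dK = S/(K+S)^2
    J = S / (k_hat + S) ** 2
    jtj = float(np.sum(J**2))
    dof = max(len(t) - 1, 1)
    sigma2 = res.fun / dof
    se = float(np.sqrt(sigma2 / jtj)) if jtj > 0 else np.inf
    return k_hat, se


def variable_genes(
    table: pd.DataFrame,
    k_m: float,
    q_cutoff: float = 0.05,
    n_cells: int | None = None,
) -> pd.DataFrame:
    """Right-tailed test of gene-wise K_j above the fitted K_M.

    ``K_j = S_j P_j / (1 - P_j)``; the binomial variance of P_j,
    ``P(1-P)/n``, is propagated to K_j by the delta method
    (dK/dP = S/(1-P)^2). Returns the dropout table extended with
    K_j / z / p / q columns; callers filter on ``q < q_cutoff``.
    """
    if n_cells is None:
        raise ValueError("n_cells is required for the binomial variance of P_j")
    t = table.copy()
    excluded = int((~t["testable"]).sum())
    if excluded:
        logger.info("excluding %d untestable genes (P in {0,1})", excluded)
    S = t["S"].to_numpy()
    P = t["P"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        K_j = S * P / (1.0 - P)
        var_K = (S / (1.0 - P) ** 2) ** 2 * P * (1.0 - P) / n_cells
        z = (K_j - k_m) / np.sqrt(var_K)
    z[~t["testable"].to_numpy()] = np.nan
    p = scipy.stats.norm.sf(z)
    t["K_j"] = K_j
    t["z"] = z
    t["p"] = p
    mask = t["testable"].to_numpy()
    q = np.full(len(t), np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    t["q"] = q
    t["selected"] = (t["q"] < q_cutoff) & t["testable"]
    return t


class MichaelisMentenFeatureSelector(SelectorMixin, BaseEstimator):
    """Dropout-model feature (variable-gene) selection, scikit-learn style.

    Fits the global Michaelis-Menten constant on a cells x genes FPKM
    matrix and selects genes whose gene-wise constant exceeds it at BH
    FDR ``q_cutoff``.

    Attributes
    ----------
    k_m_ : float
        Fitted global Michaelis-Menten constant (FPKM units).
    k_m_se_ : float
    table_ : DataFrame
        Per-gene S, P, K_j, z, p, q, selected.
    """

    def __init__(self, q_cutoff: float = 0.05):
        self.q_cutoff = q_cutoff

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a cells x genes matrix with >= 2 cells")
        gene_ids = [f"g{j}" for j in range(X.shape[1])]
        m = ExpressionMatrix(X.T, gene_ids, [f"cell{i}" for i in range(X.shape[0])],
                             unit="fpkm")
        table = dropout_stats(m)
        self.k_m_, self.k_m_se_ = fit_michaelis_menten(table)
        self.table_ = variable_genes(table, self.k_m_, self.q_cutoff, n_cells=X.shape[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.table_["selected"].to_numpy()


def select_variable_genes(m: ExpressionMatrix, q_cutoff: float = 0.05) -> pd.DataFrame:
    """Dropout table with selection flags for an FPKM ExpressionMatrix."""
    table = dropout_stats(m)
    k_m, _ = fit_michaelis_menten(table)
    out = variable_genes(table, k_m, q_cutoff, n_cells=m.n_cells)
    out.attrs["k_m"] = k_m
    return out


# ---------------------------------------------------------------------------
# Per-cluster gene lists and cell-type assignment


def cluster_marker_genes(
    m: ExpressionMatrix,
    labels: pd.Series,
    variable: list[str],
    top_n: int = 200,
) -> dict[int, list[str]]:
    """Rank variable genes per cluster by one-vs-rest mean log2 difference.

    ``m`` should be the log2 FPKM matrix; returns the top ``top_n``
    variable genes *elevated* in the cluster (positive one-vs-rest
    difference — a cluster's candidate markers must be up in it).
    """
    variable = [g for g in variable if g in set(m.gene_ids)]
    if not variable:
        return {int(c): [] for c in sorted(labels.unique())}
    sub = m.subset_genes(variable)
    lab = labels.loc[sub.cell_ids].to_numpy()
    out: dict[int, list[str]] = {}
    for c in sorted(np.unique(lab)):
        inside = sub.values[:, lab == c].mean(axis=1)
        outside = sub.values[:, lab != c]
        diff = inside - (outside.mean(axis=1) if outside.shape[1] else 0.0)
        order = np.lexsort((np.array(sub.gene_ids), -diff))
        order = [i for i in order if diff[i] > 0]
        out[int(c)] = [sub.gene_ids[i] for i in order[:top_n]]
    return out


@dataclass
class CellTypeAssignment:
    """Per-cluster outcome of the marker adherence test."""

    cluster: int
    assigned_type: str  # marker-DB type or "Unknown"
    chi2: float
    df: int
    p: float
    q: float
    overlap_counts: dict[str, int]
    cluster_markers: list[str]
    hypergeom_p: dict[str, float] = field(default_factory=dict)
    reason: str = ""


def assign_cell_types(
    cluster_genes: dict[int, list[str]],
    db: MarkerDatabase,
    alpha: float = 0.05,
    min_overlap: int = 2,
    universe_size: int | None = None,
) -> list[CellTypeAssignment]:
    """Assign each cluster a cell type by marker-overlap goodness of fit.

    Observed counts O_t = |cluster genes ∩ markers(t)|; expected counts
    are proportional to marker-set sizes, scaled so sum(E) = sum(O). The
    adherence statistic is the chi-squared goodness of fit with
    df = #types - 1; the cluster is assigned the type with the largest
    standardized residual (O-E)/sqrt(E) when the BH-corrected p across
    clusters is below ``alpha`` and its raw overlap is at least
    ``min_overlap``, otherwise "Unknown". Ties break by larger raw
    overlap, then lexicographic type name. A per-type hypergeometric
    enrichment p-value is reported alongside as a cross-check when
    ``universe_size`` is given.
    """
    if not db.entries:
        raise ValueError("empty marker database")
    types = db.cell_types
    sizes = np.array([len(db.entries[t]) for t in types], dtype=float)
    results: list[CellTypeAssignment] = []
    pvals: list[float] = []
    for cluster in sorted(cluster_genes):
        genes = set(cluster_genes[cluster])
        O = np.array([len(genes & db.entries[t]) for t in types], dtype=float)
        overlap = {t: int(o) for t, o in zip(types, O)}
        if not genes:
            results.append(CellTypeAssignment(cluster, "Unknown", np.nan, len(types) - 1,
                                              np.nan, np.nan, overlap, [],
                                              reason="no variable genes in cluster"))
            pvals.append(np.nan)
            continue
        total = O.sum()
        if total == 0:
            results.append(CellTypeAssignment(cluster, "Unknown", np.nan, len(types) - 1,
                                              np.nan, np.nan, overlap, sorted(genes),
                                              reason="no overlap with any marker set"))
            pvals.append(np.nan)
            continue
        E = total * sizes / sizes.sum()
        chi2 = float(np.sum((O - E) ** 2 / E))
        df = len(types) - 1
        p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else np.nan
        hyper = {}
        if universe_size is not None:
            for t, k in zip(types, O.astype(int)):
                hyper[t] = float(scipy.stats.hypergeom.sf(
                    k - 1, universe_size, len(db.entries[t]), len(genes)))
        resid = (O - E) / np.sqrt(E)
        # argmax standardized residual; ties -> larger raw overlap -> name
        order = sorted(range(len(types)),
                       key=lambda i: (-resid[i], -O[i], types[i]))
        best = order[0]
        driving = sorted(genes & db.entries[types[best]])
        results.append(CellTypeAssignment(cluster, types[best], chi2, df, p, np.nan,
                                          overlap, driving, hyper))
        pvals.append(p)
    # BH across clusters, then apply the assignment criteria
    tested = [i for i, p in enumerate(pvals) if np.isfinite(p)]
    if tested:
        q = multipletests([pvals[i] for i in tested], method="fdr_bh")[1]
        for i, qi in zip(tested, q):
            results[i].q = float(qi)
    for r in results:
        if r.reason:
            r.assigned_type = "Unknown"
            continue
        best_overlap = r.overlap_counts.get(r.assigned_type, 0)
        if not (np.isfinite(r.q) and r.q < alpha):
            r.assigned_type = "Unknown"
            r.reason = "adherence test not significant"
        elif best_overlap < min_overlap:
            r.assigned_type = "Unknown"
            r.reason = f"best overlap {best_overlap} < min_overlap {min_overlap}"
    return results


def assignments_frame(assignments: list[CellTypeAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "cluster": a.cluster,
            "assigned_type": a.assigned_type,
            "chi2": a.chi2,
            "df": a.df,
            "p": a.p,
            "q": a.q,
            "reason": a.reason,
            **{f"overlap_{t}": n for t, n in a.overlap_counts.items()},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biotype stratification and cross-compartment marker comparison


def classify_markers_by_biotype(
    markers: dict[str, list[str]] | dict[str, set[str]],
    ann: pd.DataFrame,
) -> pd.DataFrame:
    """Count markers per biotype class per cell type.

    Returns a DataFrame indexed by cell type with columns coding /
    lncRNA / pcRNA; rows sum to the marker totals.
    """
    rows = {}
    for cell_type, genes in markers.items():
        counts = dict.fromkeys(BIOTYPES, 0)
        for g in genes:
            if g not in ann.index:
                raise KeyError(f"marker {g!r} missing from the annotation")
            counts[ann.loc[g, "biotype"]] += 1
        rows[cell_type] = counts
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(BIOTYPES))
    if out.empty:
        out = pd.DataFrame(columns=list(BIOTYPES))
    return out.fillna(0).astype(int)


def compare_marker_sets(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Inclusion-exclusion (Venn) region counts for 2-4 marker sets.

    Each row is one membership pattern over the compartments (True =
    member of that compartment's set) with the number of genes falling
    exactly in that region.
    """
    names = sorted(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 compartments to compare")
    if len(names) > 4:
        raise ValueError("more than 4 sets; compare pairwise instead")
    rows = []
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        region = None
        for name, member in zip(names, pattern):
            s = sets[name] if member else None
            if member:
                region = set(s) if region is None else region & sets[name]
        for name, member in zip(names, pattern):
            if not member:
                region = region - sets[name]
        rows.append({**dict(zip(names, pattern)), "count": len(region)})
    return pd.DataFrame(rows)
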