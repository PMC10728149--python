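"""Weighted co-expression module discovery with topological overlap.

The approach follows the WGCNA/CEMiTool recipe: pick the smallest soft
power beta making the weighted network approximately scale-free
(R^2 of the log-log degree fit >= 0.8), build the unsigned adjacency
``a_ij = |corr_ij|^beta``, convert to topological-overlap (TOM)
dissimilarity, cluster genes by average linkage and cut the tree at a
fixed height; branches below the minimum size fall into "not assigned".
A dataset can legitimately yield *no* modules — no qualifying beta, or
no branch above the size floor — and that outcome is reported with a
machine-readable reason rather than as an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, GeneSetCollection, InteractionNetwork
from . import genesets

logger = logging.getLogger(__name__)


@dataclass
class ModuleSet:
    """Disjoint gene modules with the network diagnostics that produced them."""

    modules: dict[str, set[str]]
    not_assigned: set[str]
    beta: int | None
    scale_free_r2: float
    hubs: dict[str, list[str]] = field(default_factory=dict)
    status: str = "ok"  # "ok" | "no-modules"
    reason: str = ""

    def __post_init__(self) -> None:
        labels = list(self.modules)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if self.modules[a] & self.modules[b]:
                    raise ValueError(f"modules {a!r} and {b!r} overlap")
        if self.status == "no-modules" and (self.modules or not self.reason):
            raise ValueError("no-modules status requires empty modules and a reason")

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def gene_correlation(m: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between genes over cells (zero-variance genes -> r 0)."""
    X = m.values
    sd = X.std(axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Xc.T) / (np.outer(sd, sd) * X.shape[1])
    r[~np.isfinite(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=m.gene_ids, columns=m.gene_ids)


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10(freq) vs log10(k) linear fit, signed by slope.

    Connectivities are binned into ``n_bins`` equal-width bins on k;
    empty bins are skipped. Returns 0 when fewer than 3 occupied bins
    remain, and the fit's R^2 only when the slope is negative (a
    positive slope is not scale-free and scores 0).
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if len(k) < 3 or k.min() == k.max():
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = scipy.stats.linregress(xs, ys)
    if slope >= 0:
        return 0.0
    return float(r**2)


def select_soft_threshold(
    corr: pd.DataFrame,
    betas: range | list[int] | None = None,
    r2_min: float = 0.8,
    k_min: float = 0.1,
    max_density: float = 0.01,
) -> tuple[int | None, float, pd.DataFrame]:
    """Smallest beta whose weighted network is scale-free at ``r2_min``.

    Besides the scale-free fit, a qualifying beta must leave the network
    informative: mean connectivity at least ``k_min`` (a network whose
    nodes are all essentially disconnected fits a power law trivially)
    and mean adjacency at most ``max_density`` (an unsharpened,
    near-complete network cannot resolve modules). Returns
    (beta or None, its R^2, the full scan table); ``None`` is a
    legitimate outcome, not an error.
    """
    if betas is None:
        betas = range(1, 21)
    A = np.abs(corr.to_numpy())
    n = A.shape[0]
    if n < 50:
        logger.warning("only %d genes; scale-free fit is unreliable below ~50", n)
    rows = []
    chosen: tuple[int, float] | None = None
    for beta in betas:
        W = A**beta
        k = W.sum(axis=0) - np.diag(W)
        r2 = scale_free_fit_r2(k)
        mean_k = float(k.mean())
        density = mean_k / max(n - 1, 1)
        ok = (r2 >= r2_min) and (mean_k >= k_min) and (density <= max_density)
        rows.append({"beta": int(beta), "r2": r2, "mean_k": mean_k,
                     "density": density, "qualifies": ok})
        if chosen is None and ok:
            chosen = (int(beta), r2)
    table = pd.DataFrame(rows)
    if chosen is None:
        return None, float(table["r2"].max()) if len(table) else 0.0, table
    return chosen[0], chosen[1], table


def adjacency_tom(corr: pd.DataFrame, beta: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unsigned adjacency and TOM dissimilarity.

    ``a_ij = |corr_ij|^beta``; ``TOM_ij = (L_ij + a_ij) /
    (min(k_i, k_j) + 1 - a_ij)`` with ``L_ij = sum_u a_iu a_uj`` over
    u != i, j; the dissimilarity is 1 - TOM with a zero diagonal.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = np.abs(corr.to_numpy()) ** beta
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A  # diag(A)=0, so L_ij already excludes the u==i and u==j terms
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    ids = list(corr.index)
    return (pd.DataFrame(A, index=ids, columns=ids),
            pd.DataFrame(dissim, index=ids, columns=ids))


def detect_modules(
    dissim: pd.DataFrame,
    min_size: int = 30,
    cut_height: float | None = None,
    max_cut_height: float = 0.99,
) -> ModuleSet:
    """Average-linkage tree on TOM dissimilarity, cut into module branches.

    With an explicit ``cut_height`` the tree is cut statically at that
    height. By default the cut height is chosen adaptively: every merge
    height up to ``max_cut_height`` is tried and the highest height
    yielding the maximum number of branches of at least ``min_size``
    genes wins (modules keep their peripheral members) — deterministic,
    and robust to how sharply the soft threshold separated the network. Branches smaller than ``min_size``
    go to ``not_assigned``; surviving branches become modules M1, M2,
    ... ordered by decreasing size (ties by smallest member id). If no
    branch ever reaches ``min_size`` the result has status "no-modules".
    """
    ids = list(dissim.index)
    if min_size > len(ids):
        return ModuleSet({}, set(ids), None, 0.0, status="no-modules",
                         reason=f"no branch >= min_size ({min_size} > {len(ids)} genes)")
    condensed = ssd.squareform(dissim.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method="average")
    if cut_height is not None:
        heights = [cut_height]
    else:
        merge_h = np.unique(Z[:, 2])
        merge_h = merge_h[merge_h <= max_cut_height]
        # midpoints just above each merge, coarsened to keep the scan cheap
        heights = list(merge_h + 1e-9)
        if len(heights) > 200:
            idx = np.linspace(0, len(heights) - 1, 200).astype(int)
            heights = [heights[i] for i in idx]
    best: tuple[int, float, np.ndarray] | None = None
    for h in heights:
        raw = sch.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(raw)
        n_mod = int((sizes >= min_size).sum())
        if n_mod > 0 and (best is None or n_mod >= best[0]):
            best = (n_mod, h, raw)
    if best is None:
        return ModuleSet({}, set(ids), None, 0.0, status="no-modules",
                         reason=f"no branch >= min_size ({min_size})")
    _, h_best, raw = best
    groups: dict[int, set[str]] = {}
    for gid, lab in zip(ids, raw):
        groups.setdefault(int(lab), set()).add(gid)
    surviving = [g for g in groups.values() if len(g) >= min_size]
    surviving.sort(key=lambda g: (-len(g), min(g)))
    modules = {f"M{i + 1}": g for i, g in enumerate(surviving)}
    assigned = set().union(*surviving)
    leftover = set(ids) - assigned
    if leftover and modules:
        # adoption stage (dynamic-tree-cut style): a leftover gene joins the
        # closest module when its mean dissimilarity to it is below the cut,
        # repairing linkage-order artifacts that strand peripheral members
        D = dissim.to_numpy()
        pos = {g: i for i, g in enumerate(ids)}
        module_cols = {lab: [pos[g] for g in genes] for lab, genes in modules.items()}
        adopted: dict[str, str] = {}
        for g in sorted(leftover):
            dists = {lab: D[pos[g], cols].mean() for lab, cols in module_cols.items()}
            lab = min(sorted(dists), key=lambda x: dists[x])
            if dists[lab] < h_best:
                adopted[g] = lab
        for g, lab in adopted.items():
            modules[lab].add(g)
            leftover.discard(g)
    return ModuleSet(modules, leftover, None, 0.0)


def hub_genes(adjacency: pd.DataFrame, module: set[str], n: int = 10) -> list[str]:
    """Top-n module genes by intramodular connectivity (lexicographic ties)."""
    members = sorted(module)
    missing = [g for g in members if g not in adjacency.index]
    if missing:
        raise KeyError(f"module genes missing from adjacency: {missing[:5]}")
    sub = adjacency.loc[members, members].to_numpy()
    k_in = sub.sum(axis=0) - np.diag(sub)
    order = np.lexsort((np.array(members), -k_in))
    return [members[i] for i in order[:n]]


class CoexpressionModuleDetector(BaseEstimator):
    """Soft-threshold TOM module discovery, scikit-learn style.

    ``fit(X)`` takes a cells x genes matrix (log2 FPKM); modules are
    discovered over the genes (features). An optional variance
    pre-filter keeps the most variable fraction of genes before network
    construction.

    Parameters
    ----------
    beta_max : int
        Largest soft power scanned (1..beta_max).
    r2_min : float
        Scale-free fit threshold for accepting a beta.
    min_size : int
        Smallest admissible module.
    cut_height : float
        Static tree-cut height on the TOM dissimilarity.
    var_quantile : float
        Drop genes below this variance quantile (0.25 keeps the top 75%).
    n_hubs : int

    Attributes
    ----------
    beta_ : int or None
    scale_free_r2_ : float
    modules_ : dict label -> set of gene ids (empty when no modules)
    hubs_ : dict label -> ranked hub genes
    status_ : {"ok", "no-modules"}; reason_ : str
    """

    def __init__(self, beta_max: int = 20, r2_min: float = 0.8, min_size: int = 30,
                 cut_height: float = 0.97, var_quantile: float = 0.0, n_hubs: int = 10):
        self.beta_max = beta_max
        self.r2_min = r2_min
        self.min_size = min_size
        self.cut_height = cut_height
        self.var_quantile = var_quantile
        self.n_hubs = n_hubs

    def fit(self, X, y=None, gene_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        names = list(gene_names) if gene_names is not None else [
            f"g{j}" for j in range(X.shape[1])]
        variances = X.var(axis=0)
        if self.var_quantile > 0:
            floor = np.quantile(variances, self.var_quantile)
            keep = variances >= floor
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        kept_names = [n for n, k in zip(names, keep) if k]
        m = ExpressionMatrix(X[:, keep].T, kept_names,
                             [f"cell{i}" for i in range(X.shape[0])], unit="log2fpkm")
        corr = gene_correlation(m)
        beta, r2, scan = select_soft_threshold(corr, range(1, self.beta_max + 1),
                                               self.r2_min)
        self.beta_scan_ = scan
        self.scale_free_r2_ = r2
        if beta is None:
            self.beta_ = None
            self.result_ = ModuleSet({}, set(names), None, r2, status="no-modules",
                                     reason="no scale-free fit")
        else:
            self.beta_ = beta
            adjacency, dissim = adjacency_tom(corr, beta)
            self.adjacency_ = adjacency
            ms = detect_modules(dissim, self.min_size, self.cut_height)
            ms.beta = beta
            ms.scale_free_r2 = r2
            ms.not_assigned |= set(names) - set(kept_names)
            if ms.status == "ok":
                ms.hubs = {lab: hub_genes(adjacency, genes, self.n_hubs)
                           for lab, genes in ms.modules.items()}
            self.result_ = ms
        self.modules_ = self.result_.modules
        self.hubs_ = self.result_.hubs
        self.status_ = self.result_.status
        self.reason_ = self.result_.reason
        return self


def find_modules(m: ExpressionMatrix, **params) -> ModuleSet:
    """Functional wrapper over :class:`CoexpressionModuleDetector`."""
    det = CoexpressionModuleDetector(**params)
    det.fit(m.values.T, gene_names=list(m.gene_ids))
    return det.result_


def module_profile(
    ms: ModuleSet,
    m: ExpressionMatrix,
    cell_types: pd.Series,
    sets: GeneSetCollection,
    ann: pd.DataFrame | None = None,
    net: InteractionNetwork | None = None,
    n_perm: int = 200,
    seed: int = 0,
    adjacency: pd.DataFrame | None = None,
    n_edges: int = 50,
) -> dict[str, dict]:
    """Per-module ORA, per-cell-type GSEA, biotype composition and network overlay.

    ``cell_types`` maps cell id -> assigned type; one-vs-rest GSEA is
    run for every type with at least 3 cells on both sides. The
    interaction-network overlay lists user-supplied edges within the
    module merged with the strongest co-expression pairs.
    """
    if ms.status != "ok":
        raise ValueError(f"module set has status {ms.status!r}: {ms.reason}")
    universe = set(m.gene_ids)
    ct = cell_types.loc[m.cell_ids]
    reports: dict[str, dict] = {}
    for label in ms.modules:
        genes = ms.modules[label]
        report: dict = {"genes": sorted(genes)}
        report["ora"] = (genesets.ora(genes & universe, sets, universe)
                         if sets.names() else pd.DataFrame())
        gsea_tables = []
        module_expr = m.subset_genes(sorted(genes & universe))
        single = GeneSetCollection({label: ("module", genes & universe)})
        for cell_type in sorted(ct.unique()):
            mask = (ct == cell_type).to_numpy()
            if mask.sum() < 3 or (~mask).sum() < 3:
                continue
            t = genesets.gsea_permutation(m, mask, single, n_perm=n_perm, seed=seed,
                                          contrast=f"{cell_type}-vs-rest")
            gsea_tables.append(t)
        report["gsea"] = pd.concat(gsea_tables, ignore_index=True) if gsea_tables \
            else pd.DataFrame()
        if ann is not None:
            from .celltyping import classify_markers_by_biotype
            report["biotype_counts"] = classify_markers_by_biotype(
                {label: sorted(genes)}, ann).loc[label].to_dict()
        edges = []
        if adjacency is not None:
            members = sorted(genes & set(adjacency.index))
            sub = adjacency.loc[members, members].to_numpy()
            iu = np.triu_indices(len(members), k=1)
            order = np.argsort(-sub[iu], kind="stable")[:n_edges]
            edges = [(members[iu[0][i]], members[iu[1][i]], float(sub[iu][i]),
                      "coexpression") for i in order]
        if net is not None:
            edges += [(a, b, w, "interaction") for a, b, w in net.edges_within(genes)]
        else:
            logger.info("no interaction network supplied; overlay skipped")
        report["edges"] = edges
        reports[label] = report
    return reports
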