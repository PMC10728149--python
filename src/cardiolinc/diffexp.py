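"""Two-group negative-binomial Wald differential expression.

A deliberately small reimplementation of the median-of-ratios /
NB-Wald workflow ("DESeq2-lite"): median-of-ratios size factors, a
method-of-moments genewise dispersion pooled within groups, and a Wald
test on the log ratio of group means of normalized counts. No
dispersion shrinkage, no outlier refitting.

Also provides volcano-style up/down summarization at fold-change and
significance cut-offs (defaults 1.5 and 0.05), and naming of
cardiomyocyte subpopulations after each group's highest-expressed
coding gene ("<Symbol>-CM").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import BIOTYPES, ExpressionMatrix

logger = logging.getLogger(__name__)

PHI_MIN = 1e-8


def size_factors(counts: np.ndarray | ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors per cell.

    The reference is the genewise geometric mean over cells, computed
    over genes with no zero count; each cell's factor is the median over
    those genes of count/reference. Falls back to total-count scaling
    (normalized to geometric mean 1) when no gene is all-nonzero.
    """
    X = counts.values if isinstance(counts, ExpressionMatrix) else np.asarray(counts, float)
    nonzero = (X > 0).all(axis=1)
    if not nonzero.any():
        logger.warning("no all-nonzero gene; falling back to total-count size factors")
        totals = X.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("cell with zero total counts")
        return totals / np.exp(np.mean(np.log(totals)))
    ref = np.exp(np.mean(np.log(X[nonzero]), axis=1))
    return np.median(X[nonzero] / ref[:, None], axis=0)


def estimate_dispersion(
    counts: np.ndarray,
    groups: np.ndarray,
    sf: np.ndarray,
    phi_min: float = PHI_MIN,
) -> np.ndarray:
    """Per-gene NB dispersion phi (variance = mu + phi mu^2), pooled within groups.

    Method of moments on normalized counts: within each group,
    ``phi_g = (s^2 - mean)/mean^2``; groups are pooled with weights
    (n_g - 1) and the result floored at ``phi_min``.
    """
    X = np.asarray(counts, float) / np.asarray(sf, float)[None, :]
    labels = np.unique(groups)
    num = np.zeros(X.shape[0])
    den = 0.0
    for g in labels:
        sub = X[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            raise ValueError("each group needs at least 2 cells")
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (s2 - mu) / mu**2
        phi_g[~np.isfinite(phi_g)] = 0.0
        num += (n - 1) * phi_g
        den += n - 1
    return np.maximum(num / den, phi_min)


@dataclass
class DEResult:
    """Per-gene differential expression table plus derived names."""

    table: pd.DataFrame  # base_mean, log2fc, se, wald_z, p, q, direction
    n_group1: int
    n_group2: int
    group_names: tuple[str, str] = ("group1", "group2")
    subpop_names: tuple[str, str] | None = None
    excluded: list[str] | None = None


def nb_wald_test(
    counts: ExpressionMatrix,
    groups: pd.Series,
    sf: np.ndarray | None = None,
    phi: np.ndarray | None = None,
) -> DEResult:
    """NB Wald test of group 2 vs group 1 on normalized counts.

    log2fc uses group means with a +0.5 pseudocount on the group total
    (so means shift by 0.5/n), which also keeps the Wald statistic
    finite when one group is all zero; genes with zero counts in both
    groups are excluded. SE comes from the NB delta method:
    ``Var(log mu_hat) ~ sum_c (1/(sf_c mu_hat) + phi) / n^2``.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got unit {counts.unit!r}")
    g = groups.loc[counts.cell_ids]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    grp = g.to_numpy()
    X = counts.values
    if sf is None:
        sf = size_factors(X)
    sf = np.asarray(sf, float)
    if phi is None:
        phi = estimate_dispersion(X, grp, sf)
    phi = np.broadcast_to(np.asarray(phi, float), (X.shape[0],))

    mask1 = grp == labels[0]
    mask2 = grp == labels[1]
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    Y = X / sf[None, :]
    both_zero = (X.sum(axis=1) == 0)
    excluded = [gid for gid, z in zip(counts.gene_ids, both_zero) if z]
    if excluded:
        logger.info("excluding %d genes with zero counts in both groups", len(excluded))

    mu1 = (Y[:, mask1].sum(axis=1) + 0.5) / n1
    mu2 = (Y[:, mask2].sum(axis=1) + 0.5) / n2
    log2fc = np.log2(mu2 / mu1)
    # Var(log mu_hat) per group via the delta method on normalized counts
    inv_sf1 = np.sum(1.0 / sf[mask1])
    inv_sf2 = np.sum(1.0 / sf[mask2])
    var_log1 = (inv_sf1 / mu1 + n1 * phi) / n1**2
    var_log2 = (inv_sf2 / mu2 + n2 * phi) / n2**2
    se_log = np.sqrt(var_log1 + var_log2)  # natural-log scale
    z = np.log(mu2 / mu1) / se_log
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    keep = ~both_zero
    q = np.full(X.shape[0], np.nan)
    if keep.any():
        q[keep] = multipletests(p[keep], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "base_mean": (mu1 * n1 + mu2 * n2) / (n1 + n2),
            "log2fc": log2fc,
            "se": se_log / np.log(2),
            "wald_z": z,
            "p": p,
            "q": q,
            "excluded": both_zero,
        },
        index=list(counts.gene_ids),
    )
    table.loc[both_zero, ["log2fc", "wald_z", "p", "q"]] = np.nan
    return DEResult(table, n1, n2, (str(labels[0]), str(labels[1])), excluded=excluded)


def classify_directions(
    table: pd.DataFrame,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    use_q: bool = True,
) -> pd.Series:
    """up / down / ns per gene at fold-change and significance cut-offs."""
    sig = table["q" if use_q else "p"] < p_cut
    lfc = table["log2fc"]
    thr = np.log2(fc_cut)
    direction = pd.Series("ns", index=table.index)
    direction[sig & (lfc >= thr)] = "up"
    direction[sig & (lfc <= -thr)] = "down"
    direction[table["log2fc"].isna()] = "ns"
    return direction


def volcano_summary(
    result: DEResult,
    ann: pd.DataFrame,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    use_q: bool = True,
) -> pd.DataFrame:
    """Counts of up/down/total DE genes per biotype class."""
    direction = classify_directions(result.table, fc_cut, p_cut, use_q)
    rows = []
    for biotype in BIOTYPES:
        genes = [g for g in result.table.index
                 if g in ann.index and ann.loc[g, "biotype"] == biotype]
        d = direction.loc[genes]
        n_up = int((d == "up").sum())
        n_down = int((d == "down").sum())
        rows.append({"biotype": biotype, "n_up": n_up, "n_down": n_down,
                     "n_total_de": n_up + n_down})
    return pd.DataFrame(rows).set_index("biotype")


def name_subpopulations(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    groups: pd.Series,
    suffix: str = "-CM",
) -> tuple[str, str]:
    """Name two subpopulations after each group's top coding gene.

    Each group is named ``<Symbol>-CM`` using its highest mean-FPKM
    coding gene. If both groups share the same top gene, each group
    instead takes the coding gene maximizing its between-group mean
    difference (in its own direction), with a lexicographic tie-break on
    gene id.
    """
    coding = [g for g in m.gene_ids if g in ann.index and ann.loc[g, "biotype"] == "coding"]
    if not coding:
        raise ValueError("no coding genes available for naming")
    sub = m.subset_genes(coding)
    g = groups.loc[sub.cell_ids]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    means = {}
    for lab in labels:
        means[lab] = sub.values[:, (g == lab).to_numpy()].mean(axis=1)

    def top_gene(values: np.ndarray) -> str:
        order = np.lexsort((np.array(sub.gene_ids), -values))
        return sub.gene_ids[order[0]]

    top1 = top_gene(means[labels[0]])
    top2 = top_gene(means[labels[1]])
    if top1 == top2:
        diff = means[labels[1]] - means[labels[0]]
        top1 = top_gene(-diff)
        top2 = top_gene(diff)
    sym = ann["symbol"]
    return (f"{sym.loc[top1]}{suffix}", f"{sym.loc[top2]}{suffix}")


class NegativeBinomialWaldDE(BaseEstimator):
    """Two-group NB Wald differential expression, scikit-learn style.

    ``fit(X, y)`` takes a cells x genes raw count matrix and a binary
    group label per cell.

    Parameters
    ----------
    fc_cut, p_cut : float
        Volcano cut-offs (fold change 1.5, significance 0.05).
    use_q : bool
        Apply the significance cut-off to BH-adjusted q (default) or
        raw p.

    Attributes
    ----------
    results_ : DataFrame with per-gene base_mean, log2fc, se, wald_z, p,
        q and direction.
    size_factors_, dispersion_ : ndarray
    """

    def __init__(self, fc_cut: float = 1.5, p_cut: float = 0.05, use_q: bool = True):
        self.fc_cut = fc_cut
        self.p_cut = p_cut
        self.use_q = use_q

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X rows (cells) must match y length")
        counts = ExpressionMatrix(X.T, [f"g{j}" for j in range(X.shape[1])],
                                  [f"cell{i}" for i in range(X.shape[0])], unit="counts")
        groups = pd.Series(y, index=counts.cell_ids)
        self.size_factors_ = size_factors(X.T)
        self.dispersion_ = estimate_dispersion(X.T, y, self.size_factors_)
        res = nb_wald_test(counts, groups, self.size_factors_, self.dispersion_)
        res.table["direction"] = classify_directions(
            res.table, self.fc_cut, self.p_cut, self.use_q
        )
        self.results_ = res.table
        self.result_ = res
        return self
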