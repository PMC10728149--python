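"""Over-representation analysis and gene set enrichment analysis.

ORA is the upper-tail hypergeometric test against a stated universe
(all post-filter genes of the dataset, not the genome), reporting the
"gene ratio" observed/expected = k / (n_q * K_s / N). GSEA is the
weighted running-sum enrichment score with a cell-label permutation
null that preserves inter-gene correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Over-representation analysis


def ora(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; p is the
    upper tail P(X >= k), BH-corrected across sets. Rows are sorted by
    q then descending gene ratio. ``q_cut`` only fills the
    ``significant`` flag; all sets are returned.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    restricted = sets.restricted_to(universe)
    N = len(universe)
    n_q = len(query)
    rows = []
    for name in restricted.names():
        genes = restricted.genes(name)
        K_s = len(genes)
        overlap = sorted(query & genes)
        k = len(overlap)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K_s, n_q))
        expected = n_q * K_s / N
        rows.append({
            "set": name, "k": k, "K_s": K_s, "n_q": n_q, "N": N,
            "p": p, "gene_ratio": k / expected if expected > 0 else 0.0,
            "genes": ",".join(overlap),
        })
    df = pd.DataFrame(rows, columns=["set", "k", "K_s", "n_q", "N", "p",
                                     "gene_ratio", "genes"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_cut
        df = df.sort_values(["q", "gene_ratio"], ascending=[True, False],
                            kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# GSEA: ranking statistic, running-sum ES, permutation null


def rank_statistic(
    m: ExpressionMatrix,
    target_mask: np.ndarray,
) -> pd.Series:
    """Signal-to-noise score per gene for target vs rest cells.

    ``(mu_t - mu_r) / (sigma_t + sigma_r + eps)`` with a floor
    ``eps = 0.125 * max(mean(|mu|), 1)`` guarding near-zero standard
    deviations. Returned sorted descending with a lexicographic gene-id
    tie-break.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.sum() < 3 or (~target_mask).sum() < 3:
        raise ValueError("both classes need at least 3 cells")
    Xt = m.values[:, target_mask]
    Xr = m.values[:, ~target_mask]
    mu_t, mu_r = Xt.mean(axis=1), Xr.mean(axis=1)
    sd_t, sd_r = Xt.std(axis=1, ddof=0), Xr.std(axis=1, ddof=0)
    eps = 0.125 * max(float(np.mean(np.abs(m.values))), 1.0)
    score = (mu_t - mu_r) / (sd_t + sd_r + eps)
    order = np.lexsort((np.array(m.gene_ids), -score))
    return pd.Series(score[order], index=[m.gene_ids[i] for i in order], name="score")


def gsea_es(ranked: pd.Series, gene_set: set[str], weight: float = 1.0) -> float:
    """Running-sum enrichment score over a ranked gene list.

    Hits add ``|score|^weight`` normalized by the hit total; misses
    subtract ``1/(N - m)``. The ES is the extremum of the running sum
    with the larger absolute deviation (positive maximum vs negative
    minimum). A set covering the whole list scores 0 by convention.
    """
    in_set = np.fromiter((g in gene_set for g in ranked.index), bool, len(ranked))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    N = len(ranked)
    if n_hits == N:
        return 0.0
    w = np.abs(ranked.to_numpy()) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = in_set.astype(float)
        total = float(n_hits)
    steps = hit_w / total - (~in_set) / (N - n_hits)
    running = np.cumsum(steps)
    hi, lo = float(running.max()), float(running.min())
    return hi if hi >= -lo else lo


@dataclass
class GseaEntry:
    set_name: str
    contrast: str
    es: float
    nes: float
    p_perm: float
    q: float
    n_permutations: int


def gsea_permutation(
    m: ExpressionMatrix,
    target_mask: np.ndarray,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    contrast: str = "target-vs-rest",
) -> pd.DataFrame:
    """GSEA with a cell-label permutation null.

    Labels are permuted ``n_perm`` times (resampling degenerate
    single-class draws); the rank statistic and each set's ES are
    recomputed per permutation. ``p_perm = (1 + #{|ES_perm| >= |ES_obs|,
    same sign}) / (n_same_sign + 1)``; NES divides ES by the mean
    |same-sign permuted ES|; BH across sets. Deterministic in ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    target_mask = np.asarray(target_mask, dtype=bool)
    restricted = sets.restricted_to(set(m.gene_ids))
    names = restricted.names()
    if not names:
        return pd.DataFrame(columns=["set", "contrast", "es", "nes", "p_perm", "q",
                                     "n_permutations"])
    ranked = rank_statistic(m, target_mask)
    obs = {name: gsea_es(ranked, restricted.genes(name), weight) for name in names}

    rng = np.random.default_rng(seed)
    n_cells = m.n_cells
    n_target = int(target_mask.sum())
    perm_es = {name: np.empty(n_perm) for name in names}
    for i in range(n_perm):
        while True:
            perm = np.zeros(n_cells, dtype=bool)
            perm[rng.choice(n_cells, size=n_target, replace=False)] = True
            if 0 < perm.sum() < n_cells:
                break
        ranked_p = rank_statistic(m, perm)
        for name in names:
            perm_es[name][i] = gsea_es(ranked_p, restricted.genes(name), weight)

    rows = []
    for name in names:
        es = obs[name]
        null = perm_es[name]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = len(same)
        n_ge = int(np.sum(np.abs(same) >= abs(es)))
        p = (1 + n_ge) / (n_same + 1)
        denom = float(np.mean(np.abs(same))) if n_same else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append({"set": name, "contrast": contrast, "es": es, "nes": nes,
                     "p_perm": p, "n_permutations": n_perm})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p_perm"], method="fdr_bh")[1]
    return df[["set", "contrast", "es", "nes", "p_perm", "q", "n_permutations"]]


class GseaPermutation(BaseEstimator):
    """Cell-permutation GSEA as a scikit-learn style estimator.

    ``fit(X, y)`` takes a cells x genes matrix and a boolean target
    label per cell; ``results_`` holds the per-set table.
    """

    def __init__(self, sets: GeneSetCollection | None = None, n_perm: int = 1000,
                 seed: int = 0, weight: float = 1.0,
                 gene_names: list[str] | None = None):
        self.sets = sets
        self.n_perm = n_perm
        self.seed = seed
        self.weight = weight
        self.gene_names = gene_names

    def fit(self, X, y):
        if self.sets is None:
            raise ValueError("sets must be provided")
        X = np.asarray(X, dtype=float)
        names = self.gene_names or [f"g{j}" for j in range(X.shape[1])]
        m = ExpressionMatrix(X.T, names,
                             [f"cell{i}" for i in range(X.shape[0])], unit="log2fpkm")
        self.results_ = gsea_permutation(
            m, np.asarray(y, dtype=bool), self.sets,
            n_perm=self.n_perm, seed=self.seed, weight=self.weight,
        )
        return self
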