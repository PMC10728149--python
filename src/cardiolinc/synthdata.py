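"""Synthetic multi-cell-type scRNA-seq datasets with planted ground truth.

The generator emulates the statistical structure the analysis stages
assume: negative-binomial counts (variance = mu + phi mu^2) over a
log-normal spread of per-gene baselines; per-type marker genes with a
log2 mean shift; two cardiomyocyte-like subpopulations sharing the same
marker set but separated by planted fold changes; latent-factor
co-expression modules spanning the three biotype classes; and extra
zeros injected so that a gene expressed at FPKM level S in a cell drops
out with Michaelis-Menten probability ``1 - S/(K + S)``.

Cell "clusters" are the five planted populations; the first two are the
cardiomyocyte subpopulations, so four distinct cell-type names carry
disjoint marker sets. Everything is driven by a single integer seed
through one ``numpy.random.Generator`` stream, so identical
configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MarkerDatabase
from .preprocess import counts_to_fpkm

CELL_TYPE_NAMES = (
    "Cardiomyocyte",
    "Endothelial",
    "Fibroblast and Myofibroblast",
    "Macrophage and Monocyte",
    "T-cell",
    "Mural and Pericyte",
    "Myoblast",
    "Dendritic",
)


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic dataset.

    Defaults are the study conditions used throughout the test suite:
    five planted cell populations of 100 cells (two of them
    cardiomyocyte subpopulations), 2000 genes split 1500/400/100 over
    coding/lncRNA/pcRNA, 20 markers per type shifted by 3 log2 units,
    100 subpopulation DE genes at |log2FC| = 2, NB dispersion 0.1 over
    a log-normal baseline (median 20 counts, log2 sd 2), dropout
    half-point K = 10 FPKM, and three 60-gene modules driven by one
    unit-variance latent factor each.
    """

    n_types: int = 5  # planted populations; the first two share the CM marker set
    cells_per_type: int = 100
    n_coding: int = 1500
    n_lncrna: int = 400
    n_pcrna: int = 100
    markers_per_type: int = 10
    marker_log2_shift: float = 3.0
    # markers are depleted outside their type (real markers are near-silent
    # there); None means half the marker shift, so a null shift nulls this too
    marker_offtype_log2_drop: float | None = None
    subpop_de_count: int = 80
    subpop_log2fc: float = 3.0
    nb_mean_baseline: float = 20.0
    baseline_log2_sd: float = 2.0
    nb_dispersion: float = 0.1
    mm_K: float = 10.0
    module_count: int = 3
    module_size: int = 60
    module_latent_sd: float = 0.85
    # co-expression modules are cell-type-associated (what per-cell-type GSEA
    # detects): each module's latent factor is elevated in one target
    # population, cycling over the non-cardiomyocyte populations
    module_type_log2_shift: float = 1.0
    gene_length_min: int = 500
    gene_length_max: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "cells_per_type", "n_coding", "markers_per_type",
                     "gene_length_min", "gene_length_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_types < 2:
            raise ValueError("need at least 2 planted populations")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.mm_K < 0:
            raise ValueError("mm_K must be >= 0")
        if self.gene_length_max < self.gene_length_min:
            raise ValueError("gene_length_max < gene_length_min")

    @property
    def n_genes(self) -> int:
        return self.n_coding + self.n_lncrna + self.n_pcrna

    @property
    def n_marker_types(self) -> int:
        # populations 1 and 2 are subpopulations of the same cell type
        return self.n_types - 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    cell_type_of: dict[str, str]
    subpop_of: dict[str, str]  # only cardiomyocyte-like cells
    population_of: dict[str, int]  # planted cluster index 1..n_types
    markers_of: dict[str, set[str]]
    de_genes: dict[str, float]  # gene -> planted log2 FC (subpop 2 vs 1)
    modules_of: dict[str, set[str]]
    module_target_of: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi mu^2."""
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(float)


def _nb_zero_prob(mu: np.ndarray, phi: float | None) -> np.ndarray:
    if phi is None or phi <= 0:
        return np.exp(-mu)  # Poisson limit
    return (1.0 + phi * mu) ** (-1.0 / phi)


def apply_dropout(
    counts: np.ndarray,
    fpkm_means: np.ndarray,
    mm_K: float,
    seed: int | np.random.Generator,
    phi: float | None = None,
    count_means: np.ndarray | None = None,
) -> np.ndarray:
    """Inject zeros so total dropout matches the Michaelis-Menten target.

    Each entry is independently zeroed with probability
    ``max(0, p_target - p_nb) / (1 - p_nb)`` where ``p_target = 1 -
    S/(mm_K + S)`` for that entry's expected FPKM S, and ``p_nb`` is the
    sampling-zero probability of the count model (0 when ``count_means``
    is not supplied). With ``mm_K = 0`` no extra dropout is applied.
    The total zero fraction therefore matches ``max(p_nb, p_target)``.
    """
    if mm_K < 0:
        raise ValueError("mm_K must be >= 0")
    counts = np.asarray(counts, dtype=float)
    if mm_K == 0:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = np.asarray(fpkm_means, dtype=float)
    p_target = 1.0 - S / (mm_K + S)
    p_nb = _nb_zero_prob(np.asarray(count_means, float), phi) \
        if count_means is not None else np.zeros_like(p_target)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_extra = np.clip((p_target - p_nb) / (1.0 - p_nb), 0.0, 1.0)
    p_extra[~np.isfinite(p_extra)] = 0.0
    keep = rng.random(counts.shape) >= p_extra
    return counts * keep


def generate_dataset(
    cfg: GeneratorConfig | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, MarkerDatabase, SyntheticTruth]:
    """Generate (counts, fpkm, annotation, marker DB, truth) for one dataset."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- genes and annotation -------------------------------------------------
    gene_ids = ([f"C{i:05d}" for i in range(cfg.n_coding)]
                + [f"L{i:05d}" for i in range(cfg.n_lncrna)]
                + [f"P{i:05d}" for i in range(cfg.n_pcrna)])
    biotypes = (["coding"] * cfg.n_coding + ["lncRNA"] * cfg.n_lncrna
                + ["pcRNA"] * cfg.n_pcrna)
    lengths = rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1,
                           size=cfg.n_genes)
    ann = pd.DataFrame(
        {"symbol": [g.replace("C", "Sym-C").replace("L", "Sym-L").replace("P", "Sym-P")
                    for g in gene_ids],
         "biotype": biotypes,
         "length_bp": lengths},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # --- cells and planted populations ---------------------------------------
    n_cells = cfg.n_types * cfg.cells_per_type
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    population = np.repeat(np.arange(1, cfg.n_types + 1), cfg.cells_per_type)
    type_names = list(CELL_TYPE_NAMES[: cfg.n_marker_types])
    # populations 1 and 2 -> type_names[0] (the cardiomyocyte-like type)
    pop_to_type = {1: type_names[0], 2: type_names[0]}
    for pop in range(3, cfg.n_types + 1):
        pop_to_type[pop] = type_names[pop - 2]

    # --- disjoint reserved gene roles -----------------------------------------
    n_marker_genes = cfg.n_marker_types * cfg.markers_per_type
    n_reserved = n_marker_genes + cfg.subpop_de_count + cfg.module_count * cfg.module_size
    if n_reserved > cfg.n_genes:
        raise ValueError(
            f"marker/DE/module genes ({n_reserved}) exceed total genes ({cfg.n_genes})"
        )
    baseline = cfg.nb_mean_baseline * 2.0 ** rng.normal(0.0, cfg.baseline_log2_sd,
                                                        size=cfg.n_genes)
    # module members come from genes above the median baseline: a module of
    # transcripts too weakly expressed to survive dropout is not observable
    # as co-expression, so planting one would not emulate a real module
    n_module_genes = cfg.module_count * cfg.module_size
    high_expr = np.flatnonzero(baseline >= np.median(baseline))
    if n_module_genes > len(high_expr):
        raise ValueError("module genes exceed the number of well-expressed genes")
    module_pool = rng.choice(high_expr, size=n_module_genes, replace=False)
    rest_pool = np.setdiff1d(np.arange(cfg.n_genes), module_pool)
    other = rng.choice(rest_pool, size=n_marker_genes + cfg.subpop_de_count,
                       replace=False)
    cursor = 0
    markers_of: dict[str, set[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for t in type_names:
        idx = other[cursor:cursor + cfg.markers_per_type]
        cursor += cfg.markers_per_type
        markers_of[t] = {gene_ids[i] for i in idx}
        marker_idx[t] = idx
    de_idx = other[cursor:cursor + cfg.subpop_de_count]
    de_sign = np.where(np.arange(cfg.subpop_de_count) % 2 == 0, 1.0, -1.0)
    de_genes = {gene_ids[i]: float(s * cfg.subpop_log2fc)
                for i, s in zip(de_idx, de_sign)}
    modules_of: dict[str, set[str]] = {}
    module_idx: dict[str, np.ndarray] = {}
    for mlab in range(1, cfg.module_count + 1):
        idx = module_pool[(mlab - 1) * cfg.module_size: mlab * cfg.module_size]
        modules_of[f"M{mlab}"] = {gene_ids[i] for i in idx}
        module_idx[f"M{mlab}"] = idx

    # --- expected count means --------------------------------------------------
    log2_mu = np.tile(np.log2(baseline)[:, None], (1, n_cells))
    offtype_drop = (cfg.marker_log2_shift / 2.0
                    if cfg.marker_offtype_log2_drop is None
                    else cfg.marker_offtype_log2_drop)
    for t in type_names:
        cells_t = np.isin(population, [1, 2]) if t == type_names[0] \
            else population == [p for p, tt in pop_to_type.items() if tt == t][0]
        log2_mu[np.ix_(marker_idx[t], np.flatnonzero(cells_t))] += cfg.marker_log2_shift
        log2_mu[np.ix_(marker_idx[t], np.flatnonzero(~cells_t))] -= offtype_drop
    subpop2 = population == 2
    for i, s in zip(de_idx, de_sign):
        log2_mu[i, subpop2] += s * cfg.subpop_log2fc
    module_target: dict[str, int] = {}
    non_cm_pops = list(range(3, cfg.n_types + 1)) or list(range(1, cfg.n_types + 1))
    for j, (mlab, idx) in enumerate(module_idx.items()):
        target_pop = non_cm_pops[j % len(non_cm_pops)]
        module_target[mlab] = target_pop
        z = rng.normal(0.0, cfg.module_latent_sd, size=n_cells)
        z[population == target_pop] += cfg.module_type_log2_shift
        log2_mu[idx, :] += z[None, :]
    mu = 2.0**log2_mu

    # --- counts, dropout, FPKM --------------------------------------------------
    counts = _nb_sample(rng, mu, cfg.nb_dispersion)
    len_kb = lengths.astype(float) / 1e3
    expected_totals = mu.sum(axis=0)
    fpkm_means = (mu / len_kb[:, None]) / (expected_totals[None, :] / 1e6)
    # Target the *observed* (post-dropout) mean: a gene whose surviving mean
    # FPKM is S drops out at rate 1 - S/(K + S), which is the relation the
    # dropout-model fitter estimates. The anticipated surviving mean for a
    # pre-dropout level s is s - K (entries with s <= K drop out entirely);
    # dropped count mass shrinks each cell's total, inflating surviving FPKM
    # by 1/(1 - dropped fraction), so the target is iterated to anticipate it.
    if cfg.mm_K > 0:
        renorm = np.ones(n_cells)
        for _ in range(3):
            s_eff = fpkm_means * renorm[None, :]
            surviving = np.maximum(s_eff - cfg.mm_K, 0.0)
            p_target = 1.0 - surviving / (cfg.mm_K + surviving)
            dropped_frac = (mu * p_target).sum(axis=0) / expected_totals
            renorm = 1.0 / (1.0 - dropped_frac)
        counts = apply_dropout(counts, surviving, cfg.mm_K, rng,
                               phi=cfg.nb_dispersion, count_means=mu)

    meta = {"compartment": "left ventricle", "stage": "synthetic"}
    counts_m = ExpressionMatrix(counts, gene_ids, cell_ids, "counts", dict(meta))
    fpkm_m = counts_to_fpkm(counts_m, ann)

    db = MarkerDatabase({t: set(markers_of[t]) for t in type_names},
                        {g: "synthetic" for s in markers_of.values() for g in s})
    truth = SyntheticTruth(
        cell_type_of={c: pop_to_type[p] for c, p in zip(cell_ids, population)},
        subpop_of={c: f"CM-{p}" for c, p in zip(cell_ids, population) if p in (1, 2)},
        population_of={c: int(p) for c, p in zip(cell_ids, population)},
        markers_of=markers_of,
        de_genes=de_genes,
        modules_of=modules_of,
        module_target_of={mlab: pop_to_type[p] for mlab, p in module_target.items()},
        params=cfg.to_dict(),
    )
    return counts_m, fpkm_m, ann, db, truth
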