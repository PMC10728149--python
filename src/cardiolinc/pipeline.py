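"""End-to-end orchestration of one dataset's analysis.

Stages run in a fixed order: prevalence filter -> FPKM/log transform ->
silhouette-guided clustering -> dropout-model variable genes ->
marker-database cell typing -> (when two clusters share an assigned
type) subpopulation differential expression with naming and
over-representation analysis -> co-expression modules with per-cell-type
GSEA -> a machine-readable report. Every intermediate table is written
as TSV; identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (ExpressionMatrix, GeneSetCollection, InteractionNetwork,
                 MarkerDatabase, read_expression_matrix, read_gene_annotation,
                 read_gmt, read_interaction_network, read_marker_db)
from .preprocess import counts_to_fpkm, filter_low_prevalence, log_transform
from .clustering import pairwise_distance, select_k
from .celltyping import (assign_cell_types, assignments_frame,
                         classify_markers_by_biotype, cluster_marker_genes,
                         select_variable_genes)
from .diffexp import name_subpopulations, nb_wald_test, volcano_summary, \
    classify_directions
from .genesets import ora
from .comodules import CoexpressionModuleDetector, module_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every knob of the pipeline, loadable from a YAML key-value file.

    Unknown keys in the file are rejected at load time.
    """

    # inputs
    expression_path: str = ""
    expression_format: str = "tsv"  # tsv | mtx-triplet
    expression_unit: str = "counts"
    annotation_path: str = ""
    marker_db_path: str = ""
    gene_sets_path: str = ""  # optional GMT
    network_path: str = ""  # optional edge list
    # preprocess
    min_frac: float = 0.05
    expressed_threshold: float = 0.0
    # clustering
    metric: str = "pearson-dissimilarity"
    linkage: str = "average"
    k_min: int = 2
    k_max: int = 10
    cluster_genes: str = "variable"  # "variable" | "all"
    # cell typing
    q_cutoff: float = 0.05
    alpha: float = 0.05
    min_overlap: int = 2
    top_n: int = 200
    # differential expression
    fc_cut: float = 1.5
    p_cut: float = 0.05
    use_q: bool = True
    # enrichment
    ora_q_cut: float = 0.05
    gsea_n_perm: int = 200
    # modules
    beta_max: int = 20
    r2_min: float = 0.8
    module_min_size: int = 30
    cut_height: float = 0.97
    var_quantile: float = 0.0
    n_hubs: int = 10
    # run
    seed: int = 0
    outdir: str = "cardiolinc_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summary counts, all re-derivable from the stage TSVs."""

    config_hash: str
    version: str
    expressed_by_biotype: dict[str, int] = field(default_factory=dict)
    k: int = 0
    mean_silhouette: float = float("nan")
    n_variable_genes: int = 0
    mm_K: float = float("nan")
    assignments: dict[str, str] = field(default_factory=dict)
    marker_counts_by_biotype: dict[str, dict[str, int]] = field(default_factory=dict)
    de: dict = field(default_factory=dict)  # empty => not applicable
    enrichment: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=float)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(
    cfg: RunConfig,
    counts: ExpressionMatrix | None = None,
    ann: pd.DataFrame | None = None,
    markers: MarkerDatabase | None = None,
    gene_sets: GeneSetCollection | None = None,
    network: InteractionNetwork | None = None,
) -> RunReport:
    """Execute the full analysis; inputs may be passed in memory or by path.

    Returns the report; all stage outputs land under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=cfg.config_hash(), version=__version__)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %r failed; partial outputs kept in %s",
                                 name, outdir)
        return _T()

    with stage("load"):
        if counts is None:
            counts = read_expression_matrix(cfg.expression_path,
                                            cfg.expression_format,
                                            unit=cfg.expression_unit)
        if ann is None:
            ann = read_gene_annotation(cfg.annotation_path)
        if markers is None:
            markers = read_marker_db(cfg.marker_db_path)
        if gene_sets is None and cfg.gene_sets_path:
            gene_sets = read_gmt(cfg.gene_sets_path)
        if network is None and cfg.network_path:
            network = read_interaction_network(cfg.network_path)

    with stage("preprocess"):
        if counts.unit == "counts":
            fpkm = counts_to_fpkm(counts, ann)
        elif counts.unit == "fpkm":
            fpkm = counts
            counts = None
        else:
            raise ValueError(f"input unit {counts.unit!r} not supported")
        fpkm = filter_low_prevalence(fpkm, cfg.min_frac, cfg.expressed_threshold)
        if counts is not None:
            counts = counts.subset_genes(fpkm.gene_ids)
        logm = log_transform(fpkm)
        bio = ann.loc[fpkm.gene_ids, "biotype"].value_counts().to_dict()
        report.expressed_by_biotype = {b: int(bio.get(b, 0))
                                       for b in ("coding", "lncRNA", "pcRNA")}
        _write(logm.to_frame(), outdir / "log2fpkm.tsv", index_label="gene_id")

    with stage("variable_genes"):
        vg_table = select_variable_genes(fpkm, cfg.q_cutoff)
        variable = list(vg_table.index[vg_table["selected"]])
        report.n_variable_genes = len(variable)
        report.mm_K = float(vg_table.attrs["k_m"])
        _write(vg_table, outdir / "dropout_table.tsv", index_label="gene_id")

    with stage("cluster"):
        if cfg.cluster_genes == "variable" and variable:
            cluster_input = logm.subset_genes(variable)
        elif cfg.cluster_genes in ("all", "variable"):
            cluster_input = logm
        else:
            raise ValueError(f"cluster_genes must be 'variable' or 'all', "
                             f"got {cfg.cluster_genes!r}")
        dist = pairwise_distance(cluster_input, cfg.metric)
        clus = select_k(dist, range(cfg.k_min, cfg.k_max + 1), cfg.linkage)
        report.k = clus.k
        report.mean_silhouette = clus.mean_silhouette
        _write(clus.labels.to_frame(), outdir / "clusters.tsv", index_label="cell_id")
        _write(clus.silhouette_table, outdir / "silhouette.tsv", index=False)

    with stage("celltype"):
        per_cluster = cluster_marker_genes(logm, clus.labels, variable, cfg.top_n)
        assignments = assign_cell_types(per_cluster, markers, cfg.alpha,
                                        cfg.min_overlap, universe_size=fpkm.n_genes)
        report.assignments = {str(a.cluster): a.assigned_type for a in assignments}
        _write(assignments_frame(assignments), outdir / "cell_types.tsv", index=False)
        cluster_markers = {f"cluster{a.cluster}": per_cluster[a.cluster]
                           for a in assignments}
        bio_counts = classify_markers_by_biotype(cluster_markers, ann)
        report.marker_counts_by_biotype = {
            k: {b: int(v) for b, v in row.items()}
            for k, row in bio_counts.iterrows()
        }
        _write(bio_counts, outdir / "marker_biotypes.tsv", index_label="cluster")

    with stage("diffexp"):
        subpop_pair = _find_subpopulation_pair(assignments, clus.labels)
        if subpop_pair is None or counts is None:
            report.de = {}
            logger.info("no cell type spans two clusters; DE stage not applicable")
        else:
            shared_type, (c1, c2) = subpop_pair
            cells = [c for c in counts.cell_ids
                     if clus.labels.loc[c] in (c1, c2)]
            sub_counts = counts.subset_cells(cells)
            groups = clus.labels.loc[cells]
            de = nb_wald_test(sub_counts, groups)
            de.table["direction"] = classify_directions(de.table, cfg.fc_cut,
                                                        cfg.p_cut, cfg.use_q)
            names = name_subpopulations(fpkm.subset_cells(cells), ann, groups)
            summary = volcano_summary(de, ann, cfg.fc_cut, cfg.p_cut, cfg.use_q)
            report.de = {
                "type": shared_type,
                "clusters": [int(c1), int(c2)],
                "subpop_names": list(names),
                "counts_by_biotype": {b: {k: int(v) for k, v in row.items()}
                                      for b, row in summary.iterrows()},
            }
            _write(de.table, outdir / "de.tsv", index_label="gene_id")
            _write(summary, outdir / "volcano_summary.tsv", index_label="biotype")

    with stage("ora"):
        report.enrichment = {}
        if gene_sets is not None and report.de:
            universe = set(fpkm.gene_ids)
            direction = de.table["direction"]
            for dirn in ("up", "down"):
                query = set(direction.index[direction == dirn])
                if not query:
                    continue
                tab = ora(query, gene_sets, universe, cfg.ora_q_cut)
                _write(tab, outdir / f"ora_{dirn}.tsv", index=False)
                report.enrichment[dirn] = int(tab["significant"].sum()) if len(tab) else 0

    with stage("modules"):
        det = CoexpressionModuleDetector(
            beta_max=cfg.beta_max, r2_min=cfg.r2_min, min_size=cfg.module_min_size,
            cut_height=cfg.cut_height, var_quantile=cfg.var_quantile,
            n_hubs=cfg.n_hubs,
        )
        det.fit(logm.values.T, gene_names=list(logm.gene_ids))
        ms = det.result_
        report.modules = {
            "status": ms.status,
            "reason": ms.reason,
            "beta": ms.beta,
            "scale_free_r2": ms.scale_free_r2,
            "n_modules": ms.n_modules,
            "sizes": {lab: len(g) for lab, g in ms.modules.items()},
        }
        rows = [(lab, g) for lab, genes in sorted(ms.modules.items())
                for g in sorted(genes)]
        _write(pd.DataFrame(rows, columns=["module", "gene_id"]),
               outdir / "modules.tsv", index=False)
        if ms.status == "ok":
            _write(pd.DataFrame(
                [(lab, i + 1, g) for lab, hubs in sorted(ms.hubs.items())
                 for i, g in enumerate(hubs)],
                columns=["module", "rank", "gene_id"]),
                outdir / "hubs.tsv", index=False)
            cell_types = clus.labels.map(
                {int(k): v for k, v in report.assignments.items()})
            profiles = module_profile(
                ms, logm, cell_types,
                gene_sets if gene_sets is not None else GeneSetCollection({}),
                ann=ann, net=network, n_perm=cfg.gsea_n_perm, seed=cfg.seed,
                adjacency=det.adjacency_,
            )
            gsea_all = [p["gsea"].assign(module=lab)
                        for lab, p in profiles.items() if len(p["gsea"])]
            if gsea_all:
                _write(pd.concat(gsea_all, ignore_index=True),
                       outdir / "module_gsea.tsv", index=False)
            report.modules["biotype_counts"] = {
                lab: profiles[lab].get("biotype_counts", {}) for lab in profiles}

    report.timings = timings
    (outdir / "report.json").write_text(report.to_json() + "\n")
    cfg.to_yaml(outdir / "config.yaml")
    return report


def _find_subpopulation_pair(assignments, labels: pd.Series):
    """Two clusters sharing one assigned (non-Unknown) type, largest first."""
    by_type: dict[str, list[int]] = {}
    for a in assignments:
        if a.assigned_type != "Unknown":
            by_type.setdefault(a.assigned_type, []).append(a.cluster)
    shared = {t: cs for t, cs in by_type.items() if len(cs) >= 2}
    if not shared:
        return None
    # prefer the type whose two largest clusters cover the most cells
    sizes = labels.value_counts()
    best_type = max(sorted(shared),
                    key=lambda t: sum(sorted((sizes.get(c, 0) for c in shared[t]),
                                             reverse=True)[:2]))
    cs = sorted(shared[best_type], key=lambda c: (-sizes.get(c, 0), c))[:2]
    return best_type, (min(cs), max(cs))


def build_report(outdir: str | Path) -> dict:
    """Tabulate the run summary from the stage TSVs (no recomputation).

    Tallies cluster sizes, assignments, marker-biotype counts and — when
    the DE stage ran — the volcano counts, directly from the files a run
    leaves behind. Raises if a required stage output is missing.
    """
    outdir = Path(outdir)
    out: dict = {}
    for required in ("clusters.tsv", "cell_types.tsv", "marker_biotypes.tsv"):
        if not (outdir / required).exists():
            raise FileNotFoundError(f"missing stage output: {outdir / required}")
    clusters = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    out["n_cells"] = int(len(clusters))
    out["cluster_sizes"] = {int(k): int(v)
                            for k, v in clusters["cluster"].value_counts().items()}
    out["k"] = int(clusters["cluster"].nunique())
    types = pd.read_csv(outdir / "cell_types.tsv", sep="\t")
    out["assignments"] = dict(zip(types["cluster"].astype(str),
                                  types["assigned_type"]))
    bio = pd.read_csv(outdir / "marker_biotypes.tsv", sep="\t", index_col=0)
    out["marker_counts_by_biotype"] = {
        str(k): {b: int(v) for b, v in row.items()} for k, row in bio.iterrows()}
    out["marker_totals"] = {str(k): int(sum(row.values()))
                            for k, row in bio.to_dict("index").items()}
    volcano = outdir / "volcano_summary.tsv"
    if volcano.exists():
        vs = pd.read_csv(volcano, sep="\t", index_col=0)
        out["de_counts_by_biotype"] = {
            str(b): {k: int(v) for k, v in row.items()} for b, row in vs.iterrows()}
    else:
        out["de"] = "not-applicable"
    report_path = outdir / "report.json"
    if report_path.exists():
        out["report"] = json.loads(report_path.read_text())
    return out
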