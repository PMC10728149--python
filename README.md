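# cardiolinc

Single-cell expression analysis of coding, lncRNA, and positionally
conserved lncRNA (pcRNA) transcripts across heart development, built as
a reusable, tested Python pipeline. It is aimed at computational
biologists who have a gene × cell FPKM (or raw-count) matrix per heart
compartment and developmental stage and want to go from that matrix to
annotated cell types, cardiomyocyte subpopulations, and co-expression
modules — or who want to validate such a workflow end-to-end on
synthetic data with planted ground truth.

## What it computes

Given an expression matrix, a gene annotation (biotype ∈ {coding,
lncRNA, pcRNA}, transcript length), and a cell-type marker database,
the pipeline runs:

1. **Prevalence filter and normalization.** Transcripts must be
   expressed in at least 5% of cells (boundary inclusive); counts are
   converted to FPKM, `FPKM = counts / (length_kb · total_counts/10⁶)`,
   and log₂(FPKM+1)-transformed.
2. **Dropout-model variable genes.** The zero fraction *P* of a gene
   with mean FPKM *S* follows a Michaelis–Menten curve
   `P = 1 − S/(K_M + S)`. A global `K_M` is fitted by 1-D nonlinear
   least squares; genes whose gene-wise constant
   `K_j = S_j P_j/(1−P_j)` lies significantly above `K_M` (delta-method
   normal test, Benjamini–Hochberg FDR) drop out in excess of their
   mean — the signature of genes expressed in a subset of cells.
3. **Clustering and K selection.** Hierarchical (average-linkage)
   clustering on 1 − Pearson-r dissimilarity over the variable genes;
   the number of clusters maximizes the mean silhouette
   `s(i) = (b−a)/max(a,b)` over K = 2…10.
4. **Cell-type assignment.** Each cluster's elevated variable genes are
   cross-referenced with the marker database through a chi-squared
   goodness-of-fit (adherence) test of observed marker overlaps against
   size-proportional expectations; clusters failing it are "Unknown".
   Marker counts are stratified by biotype, and marker sets can be
   compared across compartments (Venn region counts).
5. **Cardiomyocyte subpopulations.** When two clusters receive the same
   cell type, a negative-binomial Wald test ("DESeq2-lite":
   median-of-ratios size factors, method-of-moments dispersion with
   variance `μ + φμ²`) contrasts them; up/down counts are reported per
   biotype at fold-change/significance cut-offs 1.5/0.05, and each
   subpopulation is named `<TopCodingGene>-CM` after its
   highest-expressed coding gene.
6. **Enrichment.** Over-representation analysis is the hypergeometric
   upper tail against the post-filter universe, with the gene ratio
   reported as observed/expected = `k/(n_q·K_s/N)`; GSEA uses the
   weighted running-sum enrichment score with a cell-label permutation
   null.
7. **Co-expression modules.** WGCNA/CEMiTool-style: smallest soft power
   β with a scale-free degree fit (R² ≥ 0.8, with connectivity guards),
   unsigned adjacency `|r|^β`, topological-overlap (TOM) dissimilarity,
   average-linkage tree cut into modules with hub genes ranked by
   intramodular connectivity, per-module ORA and per-cell-type GSEA.
   "No modules found" is a first-class outcome with a recorded reason.

A synthetic-data generator (`cardiolinc.synthdata`) emulates the
statistical structure this analysis assumes — negative-binomial counts,
Michaelis–Menten dropout, per-type markers, two cardiomyocyte
subpopulations with planted fold changes, and cell-type-associated
co-expression modules — and returns the planted truth so every stage is
testable without any external download.

## Worked example

```python
from cardiolinc import GeneratorConfig, generate_dataset, RunConfig, run_pipeline

counts, fpkm, annotation, markers, truth = generate_dataset(GeneratorConfig(seed=1))
cfg = RunConfig(seed=1, outdir="example_out")
report = run_pipeline(cfg, counts=counts, ann=annotation, markers=markers)

print("clusters (K):", report.k)
print("fitted dropout constant K_M (FPKM):", round(report.mm_K, 2))
print("cluster assignments:", report.assignments)
print("subpopulations:", report.de["subpop_names"])
print("DE counts by biotype:", report.de["counts_by_biotype"])
```

prints

```
clusters (K): 5
fitted dropout constant K_M (FPKM): 11.1
cluster assignments: {'1': 'Cardiomyocyte', '2': 'Cardiomyocyte', '3': 'Endothelial', '4': 'Fibroblast and Myofibroblast', '5': 'Macrophage and Monocyte'}
subpopulations: ['Sym-C00428-CM', 'Sym-C00967-CM']
DE counts by biotype: {'coding': {'n_up': 30, 'n_down': 41, 'n_total_de': 71}, 'lncRNA': {'n_up': 6, 'n_down': 6, 'n_total_de': 12}, 'pcRNA': {'n_up': 4, 'n_down': 1, 'n_total_de': 5}}
```

Five clusters are found; two of them match the cardiomyocyte marker set,
which triggers the subpopulation contrast. The 88 differentially
expressed transcripts (71 coding + 12 lncRNA + 5 pcRNA at fold change
≥ 1.5 and q < 0.05) recover the 80 planted subpopulation genes, and the
fitted dropout constant sits near the planted K = 10 FPKM. Every stage
writes its table (clusters, silhouette profile, dropout statistics,
assignments, DE, modules, hubs) as TSV under `outdir`, plus a
machine-readable `report.json`; re-running with the same config and
seed reproduces the files byte for byte.

The scikit-learn-style estimators behind the stages —
`SilhouetteHierarchicalClustering`, `MichaelisMentenFeatureSelector`,
`NegativeBinomialWaldDE`, `GseaPermutation`, and
`CoexpressionModuleDetector` — can also be used directly on
cells × genes arrays and compose with sklearn model selection.

A CLI mirrors the stages:

```bash
cardiolinc simulate --seed 4 --outdir sim/
cardiolinc run --config run.yaml
cardiolinc preprocess|cluster|celltype|de|ora|modules ...
```

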