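# Methods

This note documents the statistical models behind each stage, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Expression units and preprocessing

The pipeline works on FPKM,
`FPKM_gc = counts_gc / ((length_g/10³)·(total_c/10⁶))`, so per-cell
FPKM·length_kb mass is 10⁶ by construction. "Expressed" means strictly
above a threshold (default 0 FPKM); a transcript is retained when it is
expressed in at least `min_frac` of cells (default 0.05, boundary
inclusive — "at least 5%" is read literally). Distances and
correlations are computed on log₂(FPKM+1); the pseudocount of 1 FPKM
keeps zeros at zero.

## Dropout model and variable genes

The zero fraction of a gene is modelled as a Michaelis–Menten function
of its mean expression: `P = 1 − S/(K_M + S)`, i.e. the dropout
half-point is at `S = K_M` (FPKM units). The global constant is fitted
by bounded 1-D nonlinear least squares on (S_j, P_j) over all testable
genes (0 < P_j < 1), with a Gauss–Newton standard error from the
curvature at the optimum. Each gene's own constant
`K_j = S_j·P_j/(1−P_j)` is tested right-tailed against `K_M` with the
binomial variance of P_j, `P(1−P)/n`, propagated by the delta method
(`dK/dP = S/(1−P)²`), and Benjamini–Hochberg correction at q < 0.05.
Genes expressed in only a subset of cells have convexly inflated
dropout (Jensen: `E[P(s)] ≥ P(E[s])`), which is exactly what the test
detects; under the no-structure generator the selection rate stays at
the nominal level (checked in the acceptance suite).

## Clustering and K selection

Cells are clustered by average-linkage agglomeration (scipy) on
1 − Pearson r over genes; Euclidean distance and complete/ward linkage
are available. Zero-variance cells get r = 0 against everything. By
default the distance is computed **on the dropout-selected variable
genes**: with a realistic log-normal spread of gene baselines, all-gene
correlation between cells is dominated by the shared mean-expression
profile, which buries the cell-type signal; restricting to variable
genes is standard practice in marker-driven workflows and is what makes
silhouette-based K selection informative here (`cluster_genes: all`
restores the all-gene behaviour). K is chosen over 2..10 as the cut
maximizing mean silhouette, ties toward the smaller K; the full
silhouette-versus-K table is retained. Singleton clusters score 0 by
the usual convention, and an all-singleton cut scores 0 overall.

## Marker-based cell typing

Per cluster, variable genes elevated in the cluster (positive
one-vs-rest mean log₂ difference, top 200) are intersected with each
marker set. Observed overlaps O_t are tested against expectations
proportional to marker-set sizes (ΣE = ΣO) with the chi-squared
goodness-of-fit statistic, df = #types − 1, BH-corrected across
clusters. The cluster is assigned the type with the largest
standardized residual `(O−E)/√E` when q < 0.05 and the winning overlap
is at least `min_overlap = 2` (no single-gene assignments); otherwise
"Unknown", with the reason recorded. A per-type hypergeometric
enrichment p-value is reported alongside as a cross-check when the
universe size is supplied; assignment uses the joint test. Requiring
positive one-vs-rest difference matters when few variable genes exist:
without it every cluster would receive the same gene list and the test
would not discriminate.

## Differential expression ("DESeq2-lite")

Two-group NB Wald test on raw counts: median-of-ratios size factors
(genewise geometric-mean reference over all-nonzero genes, total-count
fallback when none exists); per-gene dispersion φ (variance = μ + φμ²)
by method of moments on normalized counts pooled within groups, floored
at 10⁻⁸; Wald z on the log ratio of group means with
`Var(log μ̂) ≈ (Σ_c 1/(sf_c μ̂) + nφ)/n²`. A 0.5 pseudocount is added to
each group's total — it keeps the statistic defined when one group is
all zero and shifts means by only 0.5/n otherwise. Genes zero in both
groups are excluded. No dispersion shrinkage, no outlier refitting.
Volcano summarization counts up/down genes per biotype at fold-change
1.5 and q < 0.05 (a `--raw-p` switch applies the cut-off to raw p).
Subpopulations are named `<Symbol>-CM` after each group's
highest-mean-FPKM coding gene; if both groups share the top gene, each
takes the coding gene maximizing its own direction of the between-group
difference, with lexicographic gene-id tie-breaks.

## Enrichment

ORA is the hypergeometric upper tail `P(X ≥ k)` against the post-filter
gene universe (prevalence filtering biases any wider background); the
gene ratio is observed/expected, `k/(n_q·K_s/N)`. GSEA ranks genes by
the signal-to-noise score `(μ_t−μ_r)/(σ_t+σ_r+ε)` with
`ε = 0.125·max(mean|x|, 1)`, and walks the ranking with hit increments
`|score|^p / Σ_hits|score|^p` (p = 1) and miss decrements `1/(N−m)`;
the ES is the extremum of larger absolute deviation. The null permutes
cell labels (preserving inter-gene correlation), default 1000
permutations; `p = (1 + #{|ES_perm| ≥ |ES|, same sign})/(n_same + 1)`
(so the attainable floor is 1/(n_same+1)), and NES divides by the mean
same-sign |permuted ES|.

## Co-expression modules

Unsigned weighted network on Pearson correlation of log₂ FPKM:
adjacency `a = |r|^β`, TOM
`(L + a)/(min(k_i,k_j) + 1 − a)` with `L = Σ_u a_iu a_uj`,
dissimilarity 1 − TOM. β is the smallest power whose degree
distribution fits a power law (R² ≥ 0.8 of the log-log
frequency-vs-degree fit with negative slope, ten equal-width degree
bins) **and** whose network remains informative: mean connectivity
≥ 0.1 and mean adjacency ≤ 0.01. The two guards follow WGCNA practice;
without them a structureless network qualifies trivially — at high β
because an all-disconnected degree sequence fits any power law, at β=1
because a near-complete network does — and module resolution fails.
`β = none` is a valid outcome ("no scale-free fit").

Modules are branches of the average-linkage tree on TOM dissimilarity.
The cut height is chosen adaptively by default: every merge height up
to 0.99 is scanned and the highest height yielding the maximum number
of branches ≥ `min_size` (default 30 genes) wins, followed by a
dynamic-tree-cut-style adoption pass that attaches stranded peripheral
genes to the module they are closest to (mean dissimilarity below the
cut). A static `cut_height` remains available; the adaptive default was
adopted because a fixed height is brittle against the auto-selected β.
Hubs are ranked by intramodular connectivity with lexicographic ties.
"No modules" (no qualifying β, or no branch reaching `min_size`) is
reported with a machine-readable reason, mirroring datasets on which
guilt-by-association finds no modular pattern. A variance pre-filter is
available (`var_quantile`) but defaults to off: on dropout-heavy data
the bimodal zero/nonzero genes dominate the variance ranking and the
filter preferentially removes genuine module members.

## Synthetic data: what it emulates, and what it does not

The generator plants five cell populations of 100 cells over 2000 genes
(1500 coding, 400 lncRNA, 100 pcRNA; lengths uniform on 500–5000 bp).
Counts are negative binomial with variance μ + φμ² (φ = 0.1) around
per-gene log-normal baselines (median 20 counts, log₂ sd 2 — roughly
four orders of magnitude of FPKM). Populations 1 and 2 are
cardiomyocyte subpopulations sharing one marker set; populations 3–5
carry their own disjoint sets (10 markers per type, +3 log₂ in-type and
−1.5 log₂ off-type; real markers are near-silent outside their type).
Eighty genes distinguish the two subpopulations at ±3 log₂ — strong,
switch-like subpopulation markers, so the five populations are
comparably separated and silhouette can resolve them. Three 60-gene
modules are driven by one latent factor each (within sd 0.85 log₂,
+1 log₂ in one target population — co-expression modules in this tissue
are cell-type-associated, which is what per-cell-type GSEA reads out);
module members are drawn from genes above the median baseline, because
a module planted on transcripts too weak to survive dropout is not
observable as co-expression.

Dropout targets the **observed** relation: for an entry with expected
pre-dropout FPKM s, the target rate uses the anticipated surviving mean
(s − K, with a renormalization factor for the count mass the cell
loses), so that the realized mean-dropout relation is Michaelis–Menten
with the planted K (default 10 FPKM) — targeting pre-dropout means
instead shrinks observed means and biases the fitted constant downward.
Entries already zero under the count model are not double-counted
(`p_extra = max(0, p_target − p_nb)/(1 − p_nb)`). Genes below K are
lost entirely, as undetectably low transcripts are in practice.

All randomness flows through one `numpy.random.Generator` stream, so a
configuration and seed reproduce bit-identical matrices. Not modelled:
UMI chemistry, batch effects, doublets, gene-length bias in capture,
ambient RNA, or continuous (trajectory-like) population structure.
Passing tests on this generator shows the pipeline recovers the
structure its own models describe; it does not certify performance on
real data whose dropout or dispersion departs from these forms.

## Problem sizes and numerical conventions

The test and acceptance experiments use the default conditions
(2000 genes × 500 cells) with 3–20 replicate seeds per claim, 10⁴ null
genes for type-I calibration, 200 null sets × 200 permutations for GSEA
calibration, and a 15-dataset panel (two structureless) for module
yield. Cluster labels are renumbered 1..K in order of first appearance,
all rankings break ties lexicographically on gene id, BH correction is
`statsmodels.multipletests(method="fdr_bh")`, and every stage writes
TSVs with `%.10g` floats so identical runs are byte-identical. The
pipeline's config (YAML mirroring `RunConfig` field-for-field) rejects
unknown keys and records a SHA-256 hash of its canonical dump in the
report.

## Known limitations

- The silhouette criterion prefers coarse partitions; when
  subpopulation separation is much weaker (or much stronger) than
  type separation, the selected K can miss the planted value on a few
  percent of seeds.
- The global Michaelis–Menten fit includes heterogeneously expressed
  genes, whose convex dropout excess inflates the constant by roughly
  10% under the default planted structure; the fit is unbiased on
  structure-free data.
- The NB Wald test has no dispersion shrinkage, so its power at small
  group sizes is below a full DESeq2-style analysis.
- The adherence test assumes marker sets of comparable specificity;
  heavily overlapping marker sets weaken the size-proportional
  expectation it tests against.
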