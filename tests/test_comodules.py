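import numpy as np
import pandas as pd
import pytest

from cardiolinc.comodules import (CoexpressionModuleDetector, ModuleSet,
                                  adjacency_tom, detect_modules,
                                  gene_correlation, hub_genes,
                                  scale_free_fit_r2, select_soft_threshold)
from cardiolinc.io import ExpressionMatrix


def _corr(matrix, ids=None):
    matrix = np.asarray(matrix, float)
    ids = ids or [f"g{i}" for i in range(matrix.shape[0])]
    return pd.DataFrame(matrix, index=ids, columns=ids)


class TestScaleFreeFit:
    def test_exact_power_law_fits_perfectly(self):
        # ten degree values 1..10 (one per bin) with counts 2520/k: the
        # binned log-log points lie exactly on a slope -1 line
        k = np.concatenate([[v] * (2520 // v) for v in range(1, 11)])
        assert scale_free_fit_r2(k) == pytest.approx(1.0, abs=1e-12)

    def test_positive_slope_scores_zero(self):
        k = np.concatenate([[v] * v for v in range(1, 11)])  # rising freq
        assert scale_free_fit_r2(k) == 0.0

    def test_degenerate_inputs(self):
        assert scale_free_fit_r2(np.array([1.0, 1.0, 1.0])) == 0.0
        assert scale_free_fit_r2(np.array([0.0, 0.0])) == 0.0


class TestSoftThreshold:
    def test_returned_beta_is_smallest_qualifying(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 60)) + 10.0
        X[:60] += rng.normal(size=(1, 60)) * 1.5  # one correlated block
        m = ExpressionMatrix(X, [f"g{i}" for i in range(300)],
                             [f"c{j}" for j in range(60)], "log2fpkm")
        corr = gene_correlation(m)
        beta, r2, table = select_soft_threshold(corr)
        if beta is not None:
            qualifying = table.loc[table["qualifies"], "beta"]
            assert beta == qualifying.min()
            assert r2 >= 0.8
        else:
            assert not table["qualifies"].any()

    def test_iid_noise_returns_none(self):
        """Structureless genes do not yield a usable soft threshold."""
        nones = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 100))
            m = ExpressionMatrix(X + 10, [f"g{i}" for i in range(400)],
                                 [f"c{j}" for j in range(100)], "log2fpkm")
            beta, _, _ = select_soft_threshold(gene_correlation(m))
            nones += beta is None
        assert nones >= 8


class TestTom:
    def test_isolated_perfect_pair(self):
        corr = _corr([[1.0, 1.0], [1.0, 1.0]])
        _, dissim = adjacency_tom(corr, beta=1)
        assert dissim.iloc[0, 1] == pytest.approx(0.0)  # (0+1)/(1+1-1) = 1

    def test_no_adjacency_gives_unit_dissimilarity(self):
        corr = _corr(np.eye(3))
        _, dissim = adjacency_tom(corr, beta=2)
        off = dissim.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_range_on_random_matrices(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 25))
            corr = gene_correlation(
                ExpressionMatrix(X + 8, [f"g{i}" for i in range(40)],
                                 [f"c{j}" for j in range(25)], "log2fpkm"))
            _, dissim = adjacency_tom(corr, beta=int(rng.integers(1, 8)))
            vals = dissim.to_numpy()
            assert vals.min() >= 0.0 and vals.max() <= 1.0
            np.testing.assert_allclose(np.diag(vals), 0.0)

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError):
            adjacency_tom(_corr(np.eye(2)), beta=0)


class TestDetectModules:
    def test_min_size_above_gene_count(self):
        dissim = _corr(1 - np.eye(5))
        ms = detect_modules(dissim, min_size=10)
        assert ms.status == "no-modules"
        assert "min_size" in ms.reason

    def test_raising_min_size_never_adds_modules(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.8, 1.0, size=(60, 60))
        base[:20, :20] = rng.uniform(0.0, 0.2, size=(20, 20))
        base[20:45, 20:45] = rng.uniform(0.0, 0.3, size=(25, 25))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        dissim = _corr(d)
        counts = [detect_modules(dissim, min_size=s).n_modules
                  for s in (10, 20, 26, 40)]
        assert counts == sorted(counts, reverse=True)

    def test_no_modules_requires_reason(self):
        with pytest.raises(ValueError):
            ModuleSet({}, set(), None, 0.0, status="no-modules", reason="")


class TestHubs:
    def test_star_center_is_top_hub(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 0.9
        adjacency = _corr(a)
        hubs = hub_genes(adjacency, {"g0", "g1", "g2", "g3", "g4"}, n=3)
        assert hubs[0] == "g0"

    def test_equal_weights_tie_break_lexicographic(self):
        a = np.full((4, 4), 0.5)
        np.fill_diagonal(a, 0)
        adjacency = _corr(a, ids=["gb", "ga", "gd", "gc"])
        assert hub_genes(adjacency, {"gb", "ga", "gd", "gc"}, n=4) == \
            ["ga", "gb", "gc", "gd"]

    def test_rank_invariant_under_reordering(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        ids = [f"g{i}" for i in range(6)]
        adjacency = _corr(a, ids=ids)
        perm = list(rng.permutation(ids))
        shuffled = adjacency.loc[perm, perm]
        assert hub_genes(adjacency, set(ids)) == hub_genes(shuffled, set(ids))


class TestDetectorEndToEnd:
    def test_planted_modules_recovered(self, default_dataset):
        from cardiolinc.preprocess import filter_low_prevalence, log_transform
        from sklearn.metrics import adjusted_rand_score
        _, fpkm, _, _, truth = default_dataset
        logm = log_transform(filter_low_prevalence(fpkm))
        det = CoexpressionModuleDetector()
        det.fit(logm.values.T, gene_names=list(logm.gene_ids))
        assert det.status_ == "ok"
        planted = {g: lab for lab, gs in truth.modules_of.items()
                   for g in gs if g in set(logm.gene_ids)}
        detected = {g: lab for lab, gs in det.modules_.items() for g in gs}
        genes = sorted(planted)
        ari = adjusted_rand_score([planted[g] for g in genes],
                                  [detected.get(g, "NA") for g in genes])
        assert ari >= 0.8

    def test_gene_order_invariance(self, default_dataset):
        from cardiolinc.preprocess import filter_low_prevalence, log_transform
        _, fpkm, _, _, _ = default_dataset
        logm = log_transform(filter_low_prevalence(fpkm))
        rng = np.random.default_rng(0)
        sub = [logm.gene_ids[i] for i in rng.choice(logm.n_genes, 400,
                                                    replace=False)]
        m1 = logm.subset_genes(sorted(sub))
        m2 = logm.subset_genes(sorted(sub, reverse=True))
        d1 = CoexpressionModuleDetector().fit(m1.values.T,
                                              gene_names=list(m1.gene_ids))
        d2 = CoexpressionModuleDetector().fit(m2.values.T,
                                              gene_names=list(m2.gene_ids))
        assert {frozenset(v) for v in d1.modules_.values()} == \
               {frozenset(v) for v in d2.modules_.values()}

    def test_null_generator_yields_no_modules(self, null_dataset):
        from cardiolinc.preprocess import filter_low_prevalence, log_transform
        _, fpkm, _, _, _ = null_dataset
        logm = log_transform(filter_low_prevalence(fpkm))
        det = CoexpressionModuleDetector()
        det.fit(logm.values.T, gene_names=list(logm.gene_ids))
        assert det.status_ == "no-modules"
        assert det.reason_


def test_module_profile_reports(default_dataset):
    from cardiolinc.preprocess import filter_low_prevalence, log_transform
    from cardiolinc.comodules import module_profile
    from cardiolinc.io import GeneSetCollection, InteractionNetwork
    _, fpkm, ann, _, truth = default_dataset
    logm = log_transform(filter_low_prevalence(fpkm))
    det = CoexpressionModuleDetector()
    det.fit(logm.values.T, gene_names=list(logm.gene_ids))
    sets = GeneSetCollection({lab: ("planted", set(g))
                              for lab, g in truth.modules_of.items()})
    cell_types = pd.Series({c: truth.cell_type_of[c] for c in logm.cell_ids})
    some = sorted(next(iter(det.modules_.values())))[:3]
    net = InteractionNetwork([(some[0], some[1], 1.0)])
    reports = module_profile(det.result_, logm, cell_types, sets, ann=ann,
                             net=net, n_perm=100, seed=0,
                             adjacency=det.adjacency_, n_edges=10)
    # each planted module's GSEA minimum-p contrast is its target cell type
    for lab, rep in reports.items():
        genes = det.modules_[lab]
        best_truth = max(truth.modules_of,
                         key=lambda m: len(genes & truth.modules_of[m]))
        if len(genes & truth.modules_of[best_truth]) < 30:
            continue  # not a planted module (cell-type-axis module)
        gsea = rep["gsea"].set_index("contrast")
        target = truth.module_target_of[best_truth]
        # the planted target type is the most (positively) enriched contrast
        assert gsea["es"].idxmax() == f"{target}-vs-rest"
        assert gsea.loc[f"{target}-vs-rest", "p_perm"] <= 0.05
        counts = rep["biotype_counts"]
        assert sum(counts.values()) == len(genes)
        assert rep["edges"]  # co-expression pairs (plus any interaction edges)
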