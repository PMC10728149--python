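import numpy as np
import pandas as pd
import pytest

from cardiolinc.diffexp import (PHI_MIN, NegativeBinomialWaldDE,
                                classify_directions, estimate_dispersion,
                                name_subpopulations, nb_wald_test, size_factors,
                                volcano_summary)
from cardiolinc.io import ExpressionMatrix


def _counts(values):
    values = np.asarray(values, float)
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])], "counts")


class TestSizeFactors:
    def test_doubled_cell_fixture(self):
        X = np.array([[10.0, 20.0], [4.0, 8.0], [100.0, 200.0]])
        sf = size_factors(X)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-9)

    def test_identical_cells_give_unity(self):
        X = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 4))
        np.testing.assert_allclose(size_factors(X), 1.0)

    def test_gene_reordering_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 100, size=(20, 5)).astype(float)
        perm = rng.permutation(20)
        np.testing.assert_allclose(size_factors(X), size_factors(X[perm]))

    def test_total_count_fallback(self, caplog):
        X = np.array([[0.0, 4.0], [6.0, 0.0]])
        sf = size_factors(X)
        np.testing.assert_allclose(sf, [np.sqrt(6 / 4), np.sqrt(4 / 6)])


class TestDispersion:
    def test_constant_gene_floors(self):
        X = np.full((1, 8), 5.0)
        phi = estimate_dispersion(X, np.array(["A"] * 4 + ["B"] * 4), np.ones(8))
        assert phi[0] == PHI_MIN

    def test_poisson_data_near_floor(self):
        rng = np.random.default_rng(1)
        mu = 30 * 2 ** rng.normal(0, 1, 500)
        X = rng.poisson(mu[:, None], size=(500, 300)).astype(float)
        groups = np.array(["A"] * 150 + ["B"] * 150)
        phi = estimate_dispersion(X, groups, size_factors(X))
        assert np.median(phi) < 1e-3

    def test_nb_phi_half_recovered(self):
        rng = np.random.default_rng(2)
        mu = 30 * 2 ** rng.normal(0, 1, 1000)
        r = 2.0  # phi = 0.5
        X = rng.negative_binomial(r, r / (r + mu[:, None]),
                                  size=(1000, 400)).astype(float)
        groups = np.array(["A"] * 200 + ["B"] * 200)
        phi = estimate_dispersion(X, groups, size_factors(X))
        assert 0.35 <= np.median(phi) <= 0.65


class TestWald:
    def test_identical_groups_are_null(self):
        X = np.tile(np.array([[10.0], [20.0]]), (1, 8))
        m = _counts(X)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=m.cell_ids)
        res = nb_wald_test(m, groups)
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["wald_z"], 0.0, atol=1e-12)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 60, size=(50, 20)).astype(float)
        X[0] += 1
        m = _counts(X)
        g1 = pd.Series(["A"] * 10 + ["B"] * 10, index=m.cell_ids)
        g2 = pd.Series(["B"] * 10 + ["A"] * 10, index=m.cell_ids)
        r1 = nb_wald_test(m, g1)
        r2 = nb_wald_test(m, g2)
        np.testing.assert_allclose(r1.table["log2fc"], -r2.table["log2fc"],
                                   atol=1e-10)
        np.testing.assert_allclose(r1.table["p"], r2.table["p"], atol=1e-10)

    def test_all_zero_gene_excluded(self):
        X = np.array([[0.0] * 8, [5.0] * 8])
        m = _counts(X)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=m.cell_ids)
        res = nb_wald_test(m, groups)
        assert res.excluded == ["g0"]
        assert np.isnan(res.table.loc["g0", "p"])

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        X = rng.negative_binomial(5, 0.3, size=(300, 40)).astype(float)
        m = _counts(X)
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=m.cell_ids)
        t = nb_wald_test(m, groups).table.dropna(subset=["p"]).sort_values("p")
        assert t["q"].is_monotonic_increasing
        assert t["q"].iloc[-1] == pytest.approx(t["p"].iloc[-1])


class TestVolcano:
    def _table(self):
        return pd.DataFrame({
            "log2fc": [1.0, np.log2(1.4), np.log2(3.0)],
            "q": [0.01, 0.001, 0.2],
            "p": [0.005, 0.0005, 0.15],
        }, index=["g1", "g2", "g3"])

    def test_direction_logic_at_cutoffs(self):
        d = classify_directions(self._table(), fc_cut=1.5, p_cut=0.05)
        assert d["g1"] == "up"        # fc 2, q 0.01
        assert d["g2"] == "ns"        # fc 1.4 below the fold cut
        assert d["g3"] == "ns"        # fails significance
        down = self._table().assign(log2fc=lambda t: -t["log2fc"])
        assert classify_directions(down)["g1"] == "down"

    def test_counts_monotone_in_cutoffs(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"log2fc": rng.normal(0, 2, 500),
                          "q": rng.uniform(0, 1, 500),
                          "p": rng.uniform(0, 1, 500)})
        n = lambda fc, p: (classify_directions(t, fc, p) != "ns").sum()
        assert n(1.5, 0.05) >= n(2.0, 0.05) >= n(2.0, 0.01)

    def test_biotype_split(self, annotation):
        res_table = pd.DataFrame({"log2fc": [2.0, 2.0, -2.0],
                                  "q": [0.01, 0.01, 0.01],
                                  "p": [0.001] * 3}, index=["g1", "g3", "g4"])

        class R:  # minimal DEResult stand-in
            table = res_table

        out = volcano_summary(R(), annotation)
        assert out.loc["coding", "n_up"] == 1
        assert out.loc["lncRNA", "n_up"] == 1
        assert out.loc["pcRNA", "n_down"] == 1
        assert (out["n_total_de"] == out["n_up"] + out["n_down"]).all()


class TestNaming:
    def _fixture(self, sym_top1, sym_top2):
        ann = pd.DataFrame(
            {"symbol": [sym_top1, sym_top2, "Other", "Lnc"],
             "biotype": ["coding", "coding", "coding", "lncRNA"],
             "length_bp": [1000] * 4},
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"))
        # group A: g1 top; group B: g2 top; g4 (lncRNA) highest overall
        values = np.array([[100.0, 100, 5, 5],
                           [5, 5, 120, 120],
                           [10, 10, 10, 10],
                           [500, 500, 500, 500]])
        m = ExpressionMatrix(values, ["g1", "g2", "g3", "g4"],
                             ["c1", "c2", "c3", "c4"], "fpkm")
        groups = pd.Series(["A", "A", "B", "B"], index=m.cell_ids)
        return m, ann, groups

    @pytest.mark.parametrize("tops", [("Pln", "Tpm1"), ("Myh6", "Sln")])
    def test_highest_coding_gene_names(self, tops):
        m, ann, groups = self._fixture(*tops)
        assert name_subpopulations(m, ann, groups) == \
            (f"{tops[0]}-CM", f"{tops[1]}-CM")

    def test_swap_symmetry(self):
        m, ann, groups = self._fixture("Pln", "Tpm1")
        swapped = groups.map({"A": "Z", "B": "A"})  # reverses sorted order
        assert name_subpopulations(m, ann, swapped) == ("Tpm1-CM", "Pln-CM")

    def test_shared_top_gene_falls_back_to_distinguishing(self):
        ann = pd.DataFrame({"symbol": ["Top", "DiffA", "DiffB"],
                            "biotype": ["coding"] * 3, "length_bp": [1000] * 3},
                           index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        values = np.array([[900.0, 900, 900, 900],
                           [50, 50, 5, 5],
                           [5, 5, 60, 60]])
        m = ExpressionMatrix(values, ["g1", "g2", "g3"],
                             ["c1", "c2", "c3", "c4"], "fpkm")
        groups = pd.Series(["A", "A", "B", "B"], index=m.cell_ids)
        assert name_subpopulations(m, ann, groups) == ("DiffA-CM", "DiffB-CM")

    def test_no_coding_genes_is_error(self):
        ann = pd.DataFrame({"symbol": ["L"], "biotype": ["lncRNA"],
                            "length_bp": [500]},
                           index=pd.Index(["g1"], name="gene_id"))
        m = ExpressionMatrix(np.ones((1, 4)), ["g1"],
                             ["c1", "c2", "c3", "c4"], "fpkm")
        groups = pd.Series(["A", "A", "B", "B"], index=m.cell_ids)
        with pytest.raises(ValueError, match="coding"):
            name_subpopulations(m, ann, groups)


def test_estimator_fits_and_classifies():
    rng = np.random.default_rng(6)
    X = rng.negative_binomial(5, 0.3, size=(200, 40)).astype(float).T
    y = np.array(["A"] * 20 + ["B"] * 20)
    est = NegativeBinomialWaldDE().fit(X, y)
    assert set(est.results_["direction"].unique()) <= {"up", "down", "ns"}
    assert est.size_factors_.shape == (40,)
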