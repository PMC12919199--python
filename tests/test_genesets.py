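"""Specificity scores, set construction, validation and overlap."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.stats import rankdata

from funbat.genesets import (
    GeneSetCollection,
    assign_top_n,
    overlap_matrix,
    read_gmt,
    score_ee,
    score_ep,
    score_wilcoxon,
    score_zscore,
    validate_discrimination,
    window_discrimination,
    write_gmt,
)
from funbat.specificity import compute_auc, label_clusters


def make_adata(X, clusters):
    X = np.asarray(X, dtype=float)
    obs = pd.DataFrame({"cell_type": clusters, "epoch": "E1"},
                       index=[f"c{i}" for i in range(X.shape[0])])
    var = pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])])
    return ad.AnnData(X=X, obs=obs, var=var)


def lab(adata):
    return label_clusters(adata.obs, min_cells=0)


class TestZscore:
    def test_hand_arithmetic_population_sd(self):
        # one cell per cluster -> cluster means are the raw values [2, 4, 6]
        adata = make_adata([[2], [4], [6]], ["A", "B", "C"])
        z = score_zscore(adata, lab(adata), layer=None).values
        expect = (np.array([2, 4, 6]) - 4) / np.std([2, 4, 6])
        assert z.loc["g0"].to_numpy() == pytest.approx(expect, abs=1e-4)
        assert z.loc["g0"].to_numpy() == pytest.approx([-1.2247, 0, 1.2247], abs=1e-4)

    def test_constant_gene_scores_zero_and_is_flagged(self):
        adata = make_adata([[1, 3], [1, 5], [1, 1]], ["A", "B", "C"])
        s = score_zscore(adata, lab(adata), layer=None)
        assert (s.values.loc["g0"] == 0).all()
        assert s.flagged_genes == ["g0"]

    def test_per_gene_mean_zero_across_clusters(self):
        rng = np.random.default_rng(1)
        adata = make_adata(rng.poisson(3, (30, 8)), list("ABC") * 10)
        z = score_zscore(adata, lab(adata), layer=None).values
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)

    def test_marker_argmax_is_home_cluster(self, expr_data):
        adata, labeling, truth = expr_data
        z = score_zscore(adata, labeling).values
        hits = sum(z.loc[g].idxmax() == home for g, home in truth.marker_assignment.items())
        assert hits / len(truth.marker_assignment) >= 0.99


class TestEp:
    def test_direct_ratio(self):
        adata = make_adata([[1], [1], [2]], ["A", "B", "C"])
        ep = score_ep(adata, lab(adata), layer=None).values
        assert ep.loc["g0"].to_numpy() == pytest.approx([0.25, 0.25, 0.5])

    def test_single_cluster_is_one(self):
        adata = make_adata([[3], [5]], ["A", "A"])
        ep = score_ep(adata, lab(adata), layer=None).values
        assert ep.loc["g0", "A|E1"] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        adata = make_adata(rng.poisson(2, (40, 10)) + 1, list("ABCD") * 10)
        ep = score_ep(adata, lab(adata), layer=None).values
        assert np.allclose(ep.sum(axis=1), 1, atol=1e-12)

    def test_all_zero_gene_excluded(self):
        adata = make_adata([[0, 1], [0, 2]], ["A", "B"])
        s = score_ep(adata, lab(adata), layer=None)
        assert "g0" in s.flagged_genes and "g0" not in s.values.index


class TestEe:
    def test_uniform_gene_scores_one(self):
        # equal expression everywhere and equal cluster totals -> EE = 1
        adata = make_adata([[2, 2], [2, 2], [2, 2], [2, 2]], ["A", "A", "B", "B"])
        ee = score_ee(adata, lab(adata), layer=None).values
        assert np.allclose(ee.to_numpy(), 1.0)

    def test_direct_formula(self):
        # cluster totals s = [100, 300]; gene with EP_1 = 0.25 -> EE_1 = 1.0
        adata = make_adata([[25, 75], [75, 225]], ["A", "B"])
        ee = score_ee(adata, lab(adata), layer=None).values
        assert ee.loc["g0", "A|E1"] == pytest.approx(0.25 * (400 / 100))

    def test_weighted_sum_identity(self):
        rng = np.random.default_rng(3)
        adata = make_adata(rng.poisson(3, (30, 6)) + 1, list("ABC") * 10)
        labeling = lab(adata)
        ee = score_ee(adata, labeling, layer=None).values
        means = pd.DataFrame(
            {c: np.asarray(adata[labeling.cells_of(c)].X).mean(axis=0)
             for c in labeling.clusters}, index=adata.var_names)
        s = means.sum(axis=0)
        share = s / s.sum()
        assert np.allclose((ee * share).sum(axis=1), 1.0, atol=1e-12)


class TestWilcoxon:
    def test_small_instance_matches_textbook_formula(self):
        x_in = np.array([5.0, 7, 7, 9, 11])
        x_out = np.array([1.0, 2, 7, 3, 4])
        adata = make_adata(np.r_[x_in, x_out][:, None], ["A"] * 5 + ["B"] * 5)
        z = score_wilcoxon(adata, lab(adata), layer=None).values.loc["g0", "A|E1"]
        # independent tie-corrected rank-sum computation
        pooled = np.r_[x_in, x_out]
        r = rankdata(pooled)
        n1 = n2 = 5
        N = 10
        u = r[:5].sum() - n1 * (n1 + 1) / 2
        _, cnt = np.unique(pooled, return_counts=True)
        var = n1 * n2 / 12 * ((N + 1) - ((cnt ** 3 - cnt).sum()) / (N * (N - 1)))
        expect = (u - n1 * n2 / 2) / np.sqrt(var)
        assert z == pytest.approx(expect, abs=1e-12)

    def test_perfect_separation_is_maximal(self):
        adata = make_adata(np.r_[[10.0] * 5, [0.0] * 5][:, None], ["A"] * 5 + ["B"] * 5)
        s = score_wilcoxon(adata, lab(adata), layer=None).values
        assert s.loc["g0", "A|E1"] > 2.5
        assert s.loc["g0", "A|E1"] == pytest.approx(-s.loc["g0", "B|E1"])

    def test_all_ties_score_zero(self):
        adata = make_adata(np.full((8, 1), 4.0), ["A"] * 4 + ["B"] * 4)
        s = score_wilcoxon(adata, lab(adata), layer=None).values
        assert s.loc["g0", "A|E1"] == 0.0

    def test_matches_scanpy_implementation(self):
        """Cross-check against the scanpy rank-sum z on a random matrix."""
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(4)
        X = rng.poisson(2.0, (60, 15)).astype(float)
        adata = make_adata(X, ["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        ours = score_wilcoxon(adata, lab(adata), layer=None).values
        ref = adata.copy()
        ref.obs["grp"] = ref.obs["cell_type"].astype("category")
        sc.tl.rank_genes_groups(ref, "grp", method="wilcoxon", tie_correct=True)
        for cluster, grp in (("A|E1", "A"), ("B|E1", "B")):
            names = ref.uns["rank_genes_groups"]["names"][grp]
            scores = ref.uns["rank_genes_groups"]["scores"][grp]
            ref_z = pd.Series(scores, index=names)
            assert np.allclose(ours[cluster].loc[ref_z.index], ref_z.to_numpy(), atol=1e-6)


class TestAssignTopN:
    def scores(self):
        vals = pd.DataFrame({"X": [3.0, 2.0, 2.0, 1.0]},
                            index=["g3", "g1", "g0", "g2"])
        from funbat.genesets import ScoreMatrix
        return ScoreMatrix(values=vals, method="zscore")

    def test_ties_broken_by_gene_id(self):
        coll = assign_top_n(self.scores(), n=2)
        assert coll["X"] == ["g3", "g0"]            # g0 beats g1 on id at equal score

    def test_n_larger_than_universe(self):
        coll = assign_top_n(self.scores(), n=100)
        assert len(coll["X"]) == 4

    def test_loeuf_exclusion_is_strict(self):
        loeuf = pd.Series({"g3": 0.7, "g0": 0.6, "g1": 0.2, "g2": 0.1})
        coll = assign_top_n(self.scores(), n=3, loeuf=loeuf, loeuf_cutoff=0.6)
        # top-3 are g3, g0, g1; g3 (0.7) is excluded, g0 at exactly 0.6 is kept
        assert coll["X"] == ["g0", "g1"]
        assert coll.metadata["loeuf_filter"] is True

    def test_missing_loeuf_treated_as_unconstrained(self):
        loeuf = pd.Series({"g3": 0.1})
        with pytest.warns(UserWarning, match="lacked a LOEUF"):
            coll = assign_top_n(self.scores(), n=2, loeuf=loeuf)
        assert coll["X"] == ["g3"]

    def test_marker_recovery_on_synthetic_matrix(self, expr_data):
        adata, labeling, truth = expr_data
        z = score_zscore(adata, labeling)
        coll = assign_top_n(z, n=100)               # markers_per_cluster x 5
        hits = sum(g in coll[home] for g, home in truth.marker_assignment.items())
        assert hits / len(truth.marker_assignment) >= 0.95


class TestValidateDiscrimination:
    def test_perfect_markers_give_auc_one(self):
        X = np.zeros((40, 4))
        X[:20, :2] = 5.0                            # two genes exclusive to cluster A
        adata = make_adata(X, ["A"] * 20 + ["B"] * 20)
        auc = validate_discrimination(adata, ["g0", "g1"], "A|E1", lab(adata), layer=None)
        assert auc == 1.0

    def test_random_genes_give_auc_near_half(self):
        rng = np.random.default_rng(6)
        adata = make_adata(rng.poisson(2, (400, 30)), ["A"] * 200 + ["B"] * 200)
        auc = validate_discrimination(adata, list(adata.var_names), "A|E1",
                                      lab(adata), layer=None)
        assert 0.5 <= auc <= 0.57

    def test_single_gene_window_rejected(self):
        adata = make_adata(np.ones((4, 2)), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="at least 2"):
            validate_discrimination(adata, ["g0"], "A|E1", lab(adata), layer=None)

    def test_agrees_with_specificity_auc_for_dominant_gene(self):
        """PC1 of (informative gene, constant gene) reduces to the gene itself."""
        rng = np.random.default_rng(8)
        counts = rng.poisson([4.0, 1.0], size=(60, 2)).astype(float)
        counts[:, 1] = 7.0                          # constant companion gene
        # equal library sizes so raw counts and any monotone transform share ranks
        adata = make_adata(counts, ["A"] * 30 + ["B"] * 30)
        labeling = lab(adata)
        pca_auc = validate_discrimination(adata, ["g0", "g1"], "A|E1", labeling, layer=None)
        prof = compute_auc(adata, labeling)
        direct = max(prof.auc("g0", "A|E1"), 1 - prof.auc("g0", "A|E1"))
        assert pca_auc == pytest.approx(direct, abs=1e-12)

    def test_windows_decay_with_specificity_rank(self, expr_data):
        """Less specific windows discriminate no better than the top window."""
        adata, labeling, _ = expr_data
        z = score_zscore(adata, labeling)
        table = window_discrimination(adata, z, labeling, window=20, n_windows=3)
        top = table[table["window"] == 1]["auc"].mean()
        last = table[table["window"] == 3]["auc"].mean()
        assert top > last


class TestOverlap:
    def test_identical_and_disjoint(self):
        coll = GeneSetCollection(sets={"a": ["x", "y"], "b": ["x", "y"], "c": ["z"]})
        J = overlap_matrix(coll)
        assert J.loc["a", "b"] == 1.0
        assert J.loc["a", "c"] == 0.0
        assert np.allclose(np.diag(J), 1.0)

    def test_direct_formula(self):
        a = [f"a{i}" for i in range(570)] + [f"s{i}" for i in range(30)]
        b = [f"b{i}" for i in range(570)] + [f"s{i}" for i in range(30)]
        J = overlap_matrix(GeneSetCollection(sets={"A": a, "B": b}))
        assert J.loc["A", "B"] == pytest.approx(30 / 1170)

    def test_symmetry_invariant_under_reordering(self):
        rng = np.random.default_rng(10)
        sets = {f"s{i}": list(rng.choice(200, 40, replace=False).astype(str))
                for i in range(4)}
        J1 = overlap_matrix(GeneSetCollection(sets=sets))
        J2 = overlap_matrix(GeneSetCollection(sets=dict(reversed(sets.items()))))
        assert np.allclose(J1.to_numpy(), J1.to_numpy().T)
        assert np.allclose(J1.loc[J2.index, J2.columns].to_numpy(), J2.to_numpy())

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSetCollection(sets={"a": ["x", "x"]})


def test_gmt_round_trip(tmp_path):
    sets = {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path, description="demo")
    assert read_gmt(path) == sets
    coll = GeneSetCollection(sets=sets, metadata={"description": "demo"})
    coll.to_gmt(path)
    assert GeneSetCollection.from_gmt(path).sets == sets
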