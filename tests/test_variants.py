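"""QC cascades, CNV-gene intersection, collapsing and de novo calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_qc_table
from funbat.variants import (
    annotate_cnv_genes,
    batch_heterogeneity_filter,
    call_de_novo,
    collapse_by_gene,
    filter_cnvs,
    qc_filter_short_variants,
)


class TestShortVariantQc:
    def test_toy_table_exact_attrition(self):
        """Six records, five single failures: one survivor and a hand tally."""
        kept, attr = qc_filter_short_variants(toy_qc_table())
        assert len(kept) == 1 and kept["variant_id"].iloc[0] == "v0"
        assert attr == {
            "dp": 1, "gq": 1, "allele_ratio": 1, "maf_cohort": 1, "maf_reference": 0,
            "class_score": 1, "missing_class_score": 0, "input": 6, "retained": 1,
        }

    def test_retained_example(self):
        row = toy_qc_table().iloc[[0]]
        kept, _ = qc_filter_short_variants(row)
        assert len(kept) == 1

    def test_allele_ratio_bounds(self):
        t = toy_qc_table().iloc[[0]].assign(allele_ratio=0.1)
        kept, attr = qc_filter_short_variants(t)
        assert len(kept) == 0 and attr["allele_ratio"] == 1
        t = toy_qc_table().iloc[[0]].assign(allele_ratio=0.2)
        assert len(qc_filter_short_variants(t)[0]) == 1

    def test_class_rules(self):
        base = toy_qc_table().iloc[0].to_dict()
        rows = [
            {**base, "consequence": "stop_gained", "loftee_hc": True, "alphamissense": np.nan},
            {**base, "consequence": "stop_gained", "loftee_hc": False, "alphamissense": np.nan},
            {**base, "consequence": "splice", "spliceai_delta": 0.85, "alphamissense": np.nan},
            {**base, "consequence": "splice", "spliceai_delta": 0.5, "alphamissense": np.nan},
            {**base, "consequence": "synonymous", "alphamissense": np.nan},
            {**base, "consequence": "missense", "alphamissense": np.nan},   # missing score
        ]
        kept, attr = qc_filter_short_variants(pd.DataFrame(rows))
        assert list(kept["consequence"]) == ["stop_gained", "splice", "synonymous"]
        assert attr["missing_class_score"] == 1

    def test_order_invariance(self):
        """Conjunctive predicates: shuffling rows never changes the retained set."""
        t = toy_qc_table()
        kept1, _ = qc_filter_short_variants(t)
        kept2, _ = qc_filter_short_variants(t.sample(frac=1, random_state=0))
        assert set(kept1["variant_id"]) == set(kept2["variant_id"])


class TestCnvFilters:
    def cnvs(self):
        return pd.DataFrame({
            "cnv_id": ["c1", "c2", "c3", "c4"],
            "individual_id": ["I1"] * 4,
            "chrom": ["chr1"] * 4,
            "start": [0, 0, 0, 0],
            "end": [40_000, 60_000, 60_000, 80_000],
            "copy_number": [1, 1, 3, 2],
            "likelihood_score": [50.0, 50.0, 31.0, 90.0],
            "batch": ["b1"] * 4,
        })

    def test_thresholds_and_classification(self):
        kept, attr = filter_cnvs(self.cnvs())
        assert list(kept["cnv_id"]) == ["c2", "c3"]
        assert list(kept["cnv_type"]) == ["deletion", "duplication"]
        assert attr["size"] == 1 and attr["copy_number_2"] == 1

    def test_low_score_removed(self):
        t = self.cnvs().assign(likelihood_score=[50, 20, 31, 90])
        kept, _ = filter_cnvs(t)
        assert "c2" not in set(kept["cnv_id"])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            filter_cnvs(self.cnvs().assign(end=[0, 60_000, 60_000, 80_000]))


class TestBatchHeterogeneity:
    def make(self, counts_by_batch, n_parents_per_batch=50):
        """One distinct deletion carried by given parent counts per batch."""
        rows = []
        batches = {}
        for b, (batch, k) in enumerate(counts_by_batch.items()):
            for i in range(n_parents_per_batch):
                ind = f"{batch}_p{i}"
                batches[ind] = batch
                if i < k:
                    rows.append({"cnv_id": f"c{b}_{i}", "individual_id": ind,
                                 "chrom": "chr1", "start": 100, "end": 200_000,
                                 "copy_number": 1, "likelihood_score": 50.0,
                                 "cnv_type": "deletion", "batch": batch})
        return pd.DataFrame(rows), batches

    def test_homogeneous_cnv_retained(self):
        cnvs, batches = self.make({"b1": 5, "b2": 5})
        kept, res = batch_heterogeneity_filter(cnvs, batches)
        assert len(kept) == len(cnvs)

    def test_single_batch_cnv_removed(self):
        cnvs, batches = self.make({"b1": 30, "b2": 0})
        kept, res = batch_heterogeneity_filter(cnvs, batches)
        assert len(kept) == 0 and (res["q"] < 0.05).all()
        # oracle: 2x2 chi-square on [[30, 0], [20, 50]]
        from scipy.stats import chi2_contingency
        assert res["p"].iloc[0] == pytest.approx(
            chi2_contingency([[30, 0], [20, 50]])[1])

    def test_single_batch_input_is_noop(self):
        cnvs, batches = self.make({"b1": 5})
        kept, res = batch_heterogeneity_filter(cnvs, batches)
        assert len(kept) == len(cnvs) and res.empty


class TestAnnotateCnvGenes:
    def genes(self):
        return pd.DataFrame({
            "gene": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [150, 300, 450, 0],
            "end": [300, 400, 600, 100],
        })

    def cnv(self, start, end, chrom="chr1"):
        return pd.DataFrame({
            "cnv_id": ["c1"], "individual_id": ["I1"], "chrom": [chrom],
            "start": [start], "end": [end], "copy_number": [1],
            "likelihood_score": [50.0], "cnv_type": ["deletion"],
        })

    def test_overlap_and_half_open_boundary(self):
        recs, _ = annotate_cnv_genes(self.cnv(100, 200), self.genes())
        assert list(recs["gene"]) == ["gA"]
        recs, _ = annotate_cnv_genes(self.cnv(100, 150), self.genes())
        assert recs.empty                           # half-open: [100,150) vs [150,300)

    def test_multigenic_cnv_emits_one_record_per_gene(self):
        recs, _ = annotate_cnv_genes(self.cnv(100, 500), self.genes())
        assert sorted(recs["gene"]) == ["gA", "gB", "gC"]
        assert recs["cnv_id"].nunique() == 1

    def test_unknown_contig_skipped(self):
        recs, skipped = annotate_cnv_genes(self.cnv(0, 100, chrom="chrX"), self.genes())
        assert recs.empty and skipped == 1

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(12)
        genes = pd.DataFrame({
            "gene": [f"g{i}" for i in range(200)],
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "start": rng.integers(0, 10_000, 200),
        })
        genes["end"] = genes["start"] + rng.integers(1, 500, 200)
        starts = rng.integers(0, 10_000, 100)
        cnvs = pd.DataFrame({
            "cnv_id": [f"c{i}" for i in range(100)],
            "individual_id": "I1",
            "chrom": rng.choice(["chr1", "chr2"], 100),
            "start": starts,
            "end": starts + rng.integers(1, 2_000, 100),
            "copy_number": 1,
            "likelihood_score": 50.0,
            "cnv_type": "deletion",
        })
        recs, _ = annotate_cnv_genes(cnvs, genes)
        got = set(zip(recs["cnv_id"], recs["gene"]))
        expect = {
            (c.cnv_id, g.gene)
            for c in cnvs.itertuples() for g in genes.itertuples()
            if c.chrom == g.chrom and c.start < g.end and g.start < c.end
        }
        assert got == expect


class TestCollapse:
    def test_multiple_variants_single_flag(self):
        v = pd.DataFrame({
            "individual_id": ["I1"] * 3,
            "gene": ["gA", "gA", "gB"],
            "consequence": ["missense"] * 3,
        })
        c = collapse_by_gene(v)
        assert len(c.triples) == 2
        assert c.is_disrupted("I1", "gA", "missense")

    def test_classes_collapse_independently(self):
        v = pd.DataFrame({
            "individual_id": ["I1", "I1"],
            "gene": ["gA", "gA"],
            "consequence": ["stop_gained", "missense"],
        })
        c = collapse_by_gene(v)
        assert c.is_disrupted("I1", "gA", "stop_gained")
        assert c.is_disrupted("I1", "gA", "missense")

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(13)
        v = pd.DataFrame({
            "individual_id": rng.choice(["I1", "I2", "I3"], 50),
            "gene": rng.choice(["gA", "gB"], 50),
            "consequence": rng.choice(["missense", "synonymous"], 50),
        })
        once = collapse_by_gene(v).triples
        twice = collapse_by_gene(once.rename(columns={"vclass": "consequence"})).triples
        assert once.sort_values(list(once.columns)).reset_index(drop=True).equals(
            twice.sort_values(list(twice.columns)).reset_index(drop=True))
        more = collapse_by_gene(pd.concat([v, v.iloc[:10]])).triples
        assert len(more) == len(once)

    def test_matches_existence_scan_oracle(self):
        rng = np.random.default_rng(14)
        v = pd.DataFrame({
            "individual_id": rng.choice([f"I{i}" for i in range(5)], 200),
            "gene": rng.choice([f"g{i}" for i in range(8)], 200),
            "consequence": rng.choice(["missense", "splice", "synonymous"], 200),
        })
        c = collapse_by_gene(v)
        expect = set(map(tuple, v.to_numpy()))
        got = set(map(tuple, c.triples[["individual_id", "gene", "vclass"]].to_numpy()))
        assert got == expect


class TestDeNovo:
    def ped(self):
        return pd.DataFrame({
            "family_id": ["F1"] * 3 + ["F2"],
            "individual_id": ["F1_fa", "F1_mo", "F1_c1", "F2_s1"],
            "father_id": ["", "", "F1_fa", ""],
            "mother_id": ["", "", "F1_mo", ""],
            "sex": [1, 2, 1, 2],
        })

    def var(self, vid, ind, gene, cls, fa, mo):
        return {"variant_id": vid, "individual_id": ind, "gene": gene,
                "consequence": cls, "father_carrier": fa, "mother_carrier": mo}

    def test_de_novo_vs_inherited(self):
        v = pd.DataFrame([
            self.var("v1", "F1_c1", "gA", "missense", False, False),
            self.var("v2", "F1_c1", "gB", "missense", True, False),
        ])
        res = call_de_novo(v, self.ped())
        assert list(res.calls["variant_id"]) == ["v1"]

    def test_severity_selection_within_gene(self):
        v = pd.DataFrame([
            self.var("v1", "F1_c1", "gA", "synonymous", False, False),
            self.var("v2", "F1_c1", "gA", "frameshift", False, False),
        ])
        res = call_de_novo(v, self.ped())
        assert list(res.calls["consequence"]) == ["frameshift"]

    def test_synonymous_outlier_removed(self):
        rows = [self.var(f"v{i}", "F1_c1", f"g{i}", "synonymous", False, False)
                for i in range(11)]
        res = call_de_novo(pd.DataFrame(rows), self.ped())
        assert res.removed_offspring == ["F1_c1"] and res.calls.empty

    def test_missing_parents_excluded(self):
        v = pd.DataFrame([self.var("v1", "F2_s1", "gA", "missense", np.nan, np.nan)])
        res = call_de_novo(v, self.ped())
        assert res.calls.empty and res.unknown_parentage == 1

    def test_ground_truth_concordance_on_trios(self, effect_cohort):
        """Recovered de novo flags equal the simulator's labels exactly."""
        res = call_de_novo(effect_cohort.variants, effect_cohort.pedigree)
        # compare at the call level, before the one-per-gene reduction
        v = effect_cohort.variants
        complete = v["father_carrier"].notna()
        flagged = set(v.loc[complete
                            & ~v["father_carrier"].astype("boolean").fillna(True)
                            & ~v["mother_carrier"].astype("boolean").fillna(True),
                            "variant_id"])
        assert flagged == effect_cohort.truth.de_novo_variant_ids
        assert set(res.calls["variant_id"]) <= flagged
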