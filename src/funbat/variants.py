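"""Rare-variant and CNV quality control, gene collapsing and de novo calling.

Short variants survive QC when every conjunctive predicate holds: read depth
DP >= 20, genotype quality GQ >= 30, alternate-allele ratio in [0.2, 0.8],
cohort and reference allele frequencies <= 1e-3, plus a class-specific rule
(LoFtee high-confidence for stop-gained/frameshift, AlphaMissense >= 0.9 for
missense, SpliceAI max delta >= 0.8 for splice; synonymous has no extra
rule).  CNVs need a calling likelihood score >= 30 and size >= 50 kb; copy
number below 2 is a deletion, above 2 a duplication.

After filtering, variants are collapsed to binary (individual, gene, class)
disruption flags — the unit the burden model sums over gene sets.  De novo
calling follows trio logic: a variant is de novo when neither parent shows
any evidence of it, one variant per gene is kept by consequence severity, and
offspring with an excess of de novo synonymous genes are removed as likely
sample-quality outliers.

All genomic intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SEVERITY_ORDER",
    "qc_filter_short_variants",
    "filter_cnvs",
    "batch_heterogeneity_filter",
    "annotate_cnv_genes",
    "collapse_by_gene",
    "CollapsedGenotypes",
    "call_de_novo",
    "DeNovoResult",
]

# most severe first (Ensembl-style consequence ranking)
SEVERITY_ORDER = ("stop_gained", "frameshift", "splice", "missense", "synonymous")
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

QC_THRESHOLDS = {
    "min_dp": 20,
    "min_gq": 30,
    "allele_ratio": (0.2, 0.8),
    "max_maf": 1e-3,
    "min_alphamissense": 0.9,
    "min_spliceai": 0.8,
}


def qc_filter_short_variants(table: pd.DataFrame, thresholds: dict | None = None):
    """Apply the QC cascade; returns (retained table, per-filter attrition).

    All predicates are conjunctive per record, so the cascade is
    order-invariant; attrition counts how many input records fail each
    predicate (a record may fail several).  Records of a score-gated class
    with the score missing are dropped and counted under
    ``missing_class_score``.
    """
    t = dict(QC_THRESHOLDS, **(thresholds or {}))
    v = table
    cls = v["consequence"].to_numpy()

    fails = {
        "dp": (v["DP"] < t["min_dp"]).to_numpy(),
        "gq": (v["GQ"] < t["min_gq"]).to_numpy(),
        "allele_ratio": (
            (v["allele_ratio"] < t["allele_ratio"][0])
            | (v["allele_ratio"] > t["allele_ratio"][1])
        ).to_numpy(),
        "maf_cohort": (v["maf_cohort"] > t["max_maf"]).to_numpy(),
        "maf_reference": (v["maf_reference"] > t["max_maf"]).to_numpy(),
    }
    lof = np.isin(cls, ("stop_gained", "frameshift"))
    mis = cls == "missense"
    spl = cls == "splice"
    missing = np.zeros(len(v), dtype=bool)
    missing[lof] = v.loc[lof, "loftee_hc"].isna().to_numpy()
    missing[mis] = v.loc[mis, "alphamissense"].isna().to_numpy()
    missing[spl] = v.loc[spl, "spliceai_delta"].isna().to_numpy()

    class_fail = np.zeros(len(v), dtype=bool)
    class_fail[lof] = ~v.loc[lof, "loftee_hc"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    class_fail[mis] = ~(v.loc[mis, "alphamissense"] >= t["min_alphamissense"]).to_numpy()
    class_fail[spl] = ~(v.loc[spl, "spliceai_delta"] >= t["min_spliceai"]).to_numpy()
    class_fail &= ~missing
    fails["class_score"] = class_fail
    fails["missing_class_score"] = missing

    any_fail = np.zeros(len(v), dtype=bool)
    for m in fails.values():
        any_fail |= m
    attrition = {name: int(m.sum()) for name, m in fails.items()}
    attrition["input"] = len(v)
    attrition["retained"] = int((~any_fail).sum())
    return v[~any_fail].copy(), attrition


def filter_cnvs(table: pd.DataFrame, min_size: int = 50_000, min_score: float = 30.0):
    """Retain CNVs meeting size and likelihood thresholds; classify del/dup.

    Records with copy number exactly 2 are not CNVs and are dropped (counted
    in the attrition dict).  Adds a ``cnv_type`` column.
    """
    v = table
    if (v["end"] <= v["start"]).any():
        raise ValueError("invalid CNV interval (end <= start)")
    size_ok = (v["end"] - v["start"]) >= min_size
    score_ok = v["likelihood_score"] >= min_score
    non_cnv = v["copy_number"] == 2
    keep = size_ok & score_ok & ~non_cnv
    out = v[keep].copy()
    out["cnv_type"] = np.where(out["copy_number"] < 2, "deletion", "duplication")
    attrition = {
        "input": len(v),
        "size": int((~size_ok).sum()),
        "score": int((~score_ok).sum()),
        "copy_number_2": int(non_cnv.sum()),
        "retained": len(out),
    }
    return out, attrition


def batch_heterogeneity_filter(cnvs: pd.DataFrame, batches: dict | pd.Series,
                               parents=None, alpha: float = 0.05):
    """Remove CNVs whose parent carrier frequency is heterogeneous across batches.

    ``batches`` maps individual -> batch for every individual that should
    enter the denominators; ``parents`` optionally restricts frequencies to
    parents (maximizing independence).  Each distinct CNV (chrom, start, end,
    del/dup) is tested by a carriers-vs-non-carriers x batch chi-square;
    CNVs significant after BH FDR at ``alpha`` are removed.
    """
    batches = pd.Series(batches)
    if parents is not None:
        batches = batches[batches.index.isin(set(parents))]
    batch_levels = sorted(batches.unique())
    if len(batch_levels) < 2:
        return cnvs.copy(), pd.DataFrame(columns=["key", "p", "q"])
    denom = batches.value_counts()
    empty = [b for b in batch_levels if denom.get(b, 0) == 0]
    batch_levels = [b for b in batch_levels if b not in empty]

    key_cols = ["chrom", "start", "end", "cnv_type"] if "cnv_type" in cnvs else [
        "chrom", "start", "end", "copy_number"]
    work = cnvs[cnvs["individual_id"].isin(batches.index)].copy()
    work["_batch"] = work["individual_id"].map(batches)

    results = []
    for key, grp in work.groupby(key_cols, sort=False):
        carriers = grp.groupby("_batch")["individual_id"].nunique()
        tbl = np.array([
            [carriers.get(b, 0) for b in batch_levels],
            [denom[b] - carriers.get(b, 0) for b in batch_levels],
        ])
        if tbl[0].sum() == 0 or (tbl.sum(axis=0) == 0).any():
            p = 1.0
        else:
            with np.errstate(all="ignore"):
                p = chi2_contingency(tbl[:, tbl.sum(axis=0) > 0])[1]
        results.append({"key": key, "p": float(p)})
    res = pd.DataFrame(results)
    if res.empty:
        return cnvs.copy(), res
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    bad_keys = set(res.loc[res["q"] < alpha, "key"])
    keys = list(zip(*[cnvs[c] for c in key_cols]))
    keep = ~pd.Series(keys, index=cnvs.index).isin(bad_keys)
    return cnvs[keep].copy(), res


def annotate_cnv_genes(cnvs: pd.DataFrame, gene_intervals: pd.DataFrame):
    """Emit one (individual, gene, deletion|duplication) record per gene a CNV overlaps.

    Overlap is any shared base on 0-based half-open intervals; multigenic CNVs
    emit several records sharing the CNV id.  CNVs on contigs absent from the
    gene annotation are skipped and counted.
    """
    trees = {}
    for chrom, grp in gene_intervals.groupby("chrom"):
        tree = IntervalTree()
        for r in grp.itertuples():
            tree[r.start:r.end] = r.gene
        trees[chrom] = tree
    if "cnv_type" not in cnvs:
        cnvs = cnvs.assign(
            cnv_type=np.where(cnvs["copy_number"] < 2, "deletion", "duplication")
        )
    rows, skipped = [], 0
    for r in cnvs.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            skipped += 1
            continue
        for hit in tree[r.start:r.end]:
            rows.append((r.cnv_id, r.individual_id, hit.data, r.cnv_type))
    out = pd.DataFrame(rows, columns=["cnv_id", "individual_id", "gene", "vclass"])
    return out, skipped


@dataclass
class CollapsedGenotypes:
    """Binary (individual, gene, class) disruption flags as a sparse triple list."""

    triples: pd.DataFrame              # individual_id, gene, vclass (unique rows)
    individuals: list = field(default_factory=list)   # cohort universe incl. non-carriers

    def __post_init__(self):
        if not self.individuals:
            self.individuals = sorted(self.triples["individual_id"].unique())

    def is_disrupted(self, individual, gene, vclass):
        t = self.triples
        return bool(
            ((t["individual_id"] == individual) & (t["gene"] == gene)
             & (t["vclass"] == vclass)).any()
        )

    def classes(self):
        return sorted(self.triples["vclass"].unique())


def collapse_by_gene(short_variants: pd.DataFrame | None = None,
                     cnv_gene_records: pd.DataFrame | None = None,
                     individuals=None) -> CollapsedGenotypes:
    """Collapse QC-passing variants to binary gene x individual x class flags.

    Any number of variants of one class in one gene yields a single flag
    (idempotent, monotone).  ``individuals`` fixes the cohort universe so
    individuals without any variant still get zero burdens downstream.
    """
    parts = []
    if short_variants is not None and len(short_variants):
        parts.append(
            short_variants.rename(columns={"consequence": "vclass"})[
                ["individual_id", "gene", "vclass"]
            ]
        )
    if cnv_gene_records is not None and len(cnv_gene_records):
        parts.append(cnv_gene_records[["individual_id", "gene", "vclass"]])
    triples = (
        pd.concat(parts, ignore_index=True).drop_duplicates()
        if parts else pd.DataFrame(columns=["individual_id", "gene", "vclass"])
    )
    return CollapsedGenotypes(
        triples=triples.reset_index(drop=True),
        individuals=list(individuals) if individuals is not None else [],
    )


@dataclass
class DeNovoResult:
    calls: pd.DataFrame                # one kept de novo variant per (offspring, gene)
    removed_offspring: list            # synonymous-excess outliers
    unknown_parentage: int             # variant calls whose de novo status is unknown


def call_de_novo(variants: pd.DataFrame, pedigree: pd.DataFrame,
                 max_synonymous_genes: int = 10) -> DeNovoResult:
    """Trio-based de novo calling with severity selection and outlier removal.

    A variant is de novo iff both parental-carrier flags are False (any read
    evidence in a parent marks it inherited).  Offspring lacking either
    parent have unknown status and are excluded.  Per offspring and gene only
    the most severe de novo variant is kept (stop_gained > frameshift >
    splice > missense > synonymous); offspring with more than
    ``max_synonymous_genes`` genes carrying a de novo synonymous variant are
    removed entirely.
    """
    ped = pedigree.set_index("individual_id")
    has_both = (ped["father_id"].astype(str) != "") & (ped["mother_id"].astype(str) != "")
    complete = set(ped.index[has_both])

    v = variants.copy()
    known = (
        v["individual_id"].isin(complete)
        & v["father_carrier"].notna() & v["mother_carrier"].notna()
    )
    unknown = int((~known & v["individual_id"].isin(set(ped.index[~has_both]) | complete)).sum())
    v = v[known]
    dn = v[(~v["father_carrier"].astype(bool)) & (~v["mother_carrier"].astype(bool))].copy()

    # outliers: too many genes with a de novo synonymous variant
    syn_genes = (
        dn[dn["consequence"] == "synonymous"]
        .groupby("individual_id")["gene"].nunique()
    )
    removed = sorted(syn_genes.index[syn_genes > max_synonymous_genes])
    dn = dn[~dn["individual_id"].isin(removed)]

    dn["severity"] = dn["consequence"].map(_SEVERITY_RANK)
    dn = (
        dn.sort_values(["individual_id", "gene", "severity", "variant_id"])
        .groupby(["individual_id", "gene"], as_index=False)
        .first()
        .drop(columns=["severity"])
    )
    return DeNovoResult(calls=dn, removed_offspring=removed, unknown_parentage=unknown)
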