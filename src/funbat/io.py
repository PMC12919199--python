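"""Readers and writers for the package's on-disk formats.

Expression matrices travel as Matrix Market (cells x genes) plus two
tab-delimited annotation tables; pedigrees as PED-like tab-delimited tables
(PC columns appended); variants, CNVs, gene annotations and result tables as
plain TSV; ground truth as JSON.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import pandas as pd
from scipy import io as scio
from scipy import sparse


def write_expression(adata, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(adata.X))
    adata.obs.rename_axis("cell_id").reset_index().to_csv(
        outdir / "cells.tsv", sep="\t", index=False)
    adata.var.rename_axis("gene").reset_index().to_csv(
        outdir / "genes.tsv", sep="\t", index=False)


def read_expression(outdir):
    outdir = Path(outdir)
    X = sparse.csr_matrix(scio.mmread(outdir / "matrix.mtx"))
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t").set_index("cell_id")
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t").set_index("gene")
    return ad.AnnData(X=X, obs=cells, var=genes)


def write_pedigree(pedigree: pd.DataFrame, path):
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path):
    ped = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str})
    for col in ("father_id", "mother_id"):
        ped[col] = ped[col].fillna("").astype(str)
    return ped


def write_table(df: pd.DataFrame, path, index=False):
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kw):
    return pd.read_csv(path, sep="\t", **kw)


def write_cohort(cohort, outdir):
    """Write every table of a SimulatedCohort plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(cohort.pedigree, outdir / "pedigree.tsv")
    write_table(cohort.variants, outdir / "variants.tsv")
    write_table(cohort.cnvs, outdir / "cnvs.tsv")
    write_table(cohort.gene_annotation, outdir / "genes.tsv")
    cohort.truth.to_json(outdir / "ground_truth.json")
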