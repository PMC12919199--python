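"""Per-gene, per-cluster expression sensitivity, specificity and ROC/AUC.

A gene's *sensitivity* for a cluster is the fraction of in-cluster cells
expressing it (raw read count >= 1); its *specificity* is the fraction of
out-of-cluster cells not expressing it.  Sweeping the detection threshold
over all observed count values traces a ROC curve whose area equals the
rank-based (Mann-Whitney) probability that a random in-cluster cell has a
higher count than a random out-of-cluster cell, ties counted half.  AUC is
computed on raw counts; the log-CPM layer added by :func:`normalize_cpm_log`
is used downstream for assignment scores only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

__all__ = [
    "normalize_cpm_log",
    "label_clusters",
    "ClusterLabeling",
    "sensitivity_specificity",
    "compute_auc",
    "GeneSpecificityProfile",
    "filter_low_detection",
]

LOG_CPM_LAYER = "log_cpm"


def normalize_cpm_log(adata, inplace=True):
    """Add a log-CPM layer: ``log(1 + 1e6 * count / cell_total)`` (natural log).

    Cells with zero total count cannot be normalized and are excluded with a
    warning.  The raw count matrix is preserved in ``X``.
    """
    if not inplace:
        adata = adata.copy()
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        n_bad = int((totals == 0).sum())
        warnings.warn(f"excluding {n_bad} cells with zero total count")
        adata = adata[totals > 0].copy()
        X = adata.X
        totals = np.asarray(X.sum(axis=1)).ravel()
    if sparse.issparse(X):
        cpm = X.multiply(1e6 / totals[:, None]).tocsr()
        cpm.data = np.log1p(cpm.data)
        adata.layers[LOG_CPM_LAYER] = cpm
    else:
        adata.layers[LOG_CPM_LAYER] = np.log1p(X * (1e6 / totals[:, None]))
    return adata


@dataclass
class ClusterLabeling:
    """Cell -> cluster assignment with small clusters excluded.

    A cluster is a (cell type, developmental epoch) pair, identified as
    ``"<cell_type>|<epoch>"``; clusters under ``min_cells`` members are listed
    in ``excluded`` and their cells dropped from specificity computation.
    """

    assignments: pd.Series            # retained cells only
    excluded: list = field(default_factory=list)
    min_cells: int = 50

    @property
    def clusters(self):
        return sorted(self.assignments.unique())

    def cells_of(self, cluster):
        return self.assignments.index[self.assignments == cluster]


def label_clusters(cell_annotations: pd.DataFrame, min_cells: int = 50,
                   celltype_col="cell_type", epoch_col="epoch",
                   pool_epochs=False) -> ClusterLabeling:
    """Form cell type x epoch clusters and drop those under ``min_cells``.

    With ``pool_epochs=True`` clusters are cell types pooled across epochs.
    """
    if pool_epochs:
        labels = cell_annotations[celltype_col].astype(str)
    else:
        labels = (
            cell_annotations[celltype_col].astype(str)
            + "|" + cell_annotations[epoch_col].astype(str)
        )
    sizes = labels.value_counts()
    excluded = sorted(sizes.index[sizes < min_cells])
    kept = labels[~labels.isin(excluded)]
    if kept.empty:
        raise ValueError("no clusters meet the minimum cell count")
    return ClusterLabeling(assignments=kept, excluded=excluded, min_cells=min_cells)


def _dense_counts(adata, labeling):
    sub = adata[labeling.assignments.index]
    X = sub.X
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def sensitivity_specificity(adata, labeling: ClusterLabeling, gene, cluster,
                            threshold: int = 1):
    """(sensitivity, specificity) of ``gene`` for ``cluster`` at count >= threshold."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} absent from matrix")
    if cluster not in labeling.clusters:
        raise KeyError(f"cluster {cluster!r} not in labeling")
    cells = labeling.assignments.index
    col = adata[cells, gene].X
    col = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()
    inside = (labeling.assignments == cluster).to_numpy()
    if inside.sum() == 0:
        raise ValueError(f"cluster {cluster!r} is empty")
    sens = float((col[inside] >= threshold).mean())
    spec = float((col[~inside] < threshold).mean()) if (~inside).any() else 1.0
    return sens, spec


@dataclass
class GeneSpecificityProfile:
    """Long-format per (gene, cluster) metrics plus per-gene maxima."""

    table: pd.DataFrame               # gene, cluster, sensitivity, specificity, auc
    summary: pd.DataFrame             # index gene: auc_max, sensitivity_max, specificity_max

    def auc(self, gene, cluster):
        row = self.table[(self.table["gene"] == gene) & (self.table["cluster"] == cluster)]
        if row.empty:
            raise KeyError((gene, cluster))
        return float(row["auc"].iloc[0])


def compute_auc(adata, labeling: ClusterLabeling, genes=None,
                chunk_size=2000) -> GeneSpecificityProfile:
    """Per gene x cluster AUC, sensitivity and specificity on raw counts.

    The AUC is the normalized Mann-Whitney statistic computed from average
    ranks, identical to the area under the threshold-sweep ROC with
    trapezoidal (half-credit) tie handling.  All-zero genes have every cell
    tied and score exactly 0.5.
    """
    genes = list(adata.var_names) if genes is None else list(genes)
    missing = set(genes) - set(adata.var_names)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:3]}")
    clusters = labeling.clusters
    lab = labeling.assignments.to_numpy()
    masks = {c: lab == c for c in clusters}
    n_cells = len(lab)

    sub = adata[labeling.assignments.index, genes]
    records = []
    summaries = []
    for lo in range(0, len(genes), chunk_size):
        block_genes = genes[lo:lo + chunk_size]
        X = sub[:, block_genes].X
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
        ranks = rankdata(X, axis=0)                      # average ranks, per gene
        detected = X >= 1
        zero = X == 0
        for c in clusters:
            m = masks[c]
            n_in = int(m.sum())
            n_out = n_cells - n_in
            r_in = ranks[m].sum(axis=0)
            auc = (r_in - n_in * (n_in + 1) / 2) / (n_in * n_out)
            sens = detected[m].mean(axis=0)
            spec = zero[~m].mean(axis=0)
            records.append(pd.DataFrame({
                "gene": block_genes, "cluster": c,
                "sensitivity": sens, "specificity": spec, "auc": auc,
            }))
    table = pd.concat(records, ignore_index=True)
    summary = table.groupby("gene").agg(
        auc_max=("auc", "max"),
        sensitivity_max=("sensitivity", "max"),
        specificity_max=("specificity", "max"),
    ).loc[genes]
    return GeneSpecificityProfile(table=table, summary=summary)


def filter_low_detection(profile: GeneSpecificityProfile, threshold: float = 0.10):
    """Genes kept for gene-set construction: sensitivity_max >= threshold."""
    keep = profile.summary.index[profile.summary["sensitivity_max"] >= threshold]
    return list(keep)
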