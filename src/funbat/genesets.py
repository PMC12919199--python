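"""Cell-type gene-set construction, validation and overlap.

Four specificity scores assign genes to clusters from per-cluster mean
log-CPM expression ``x_i``:

* z-score: ``(x_i - mu) / sigma`` with mu/sigma the mean and population SD of
  the gene's per-cluster means;
* EP (expression proportion): ``x_i / sum_j x_j`` — sums to 1 over clusters;
* EE (expression enrichment): EP divided by the cluster's share of total
  expression ``s_i / sum_j s_j``, so a uniformly expressed gene scores 1;
* Wilcoxon: tie-corrected rank-sum z of in-cluster vs out-of-cluster
  per-cell expression.

Fixed-size sets (default 600 genes per cluster) are built from the top-ranked
genes, optionally restricted to constrained genes (LOEUF <= cutoff), and
validated by the AUC of the first principal component of each 100-gene
specificity window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .specificity import LOG_CPM_LAYER, ClusterLabeling

__all__ = [
    "ScoreMatrix",
    "GeneSetCollection",
    "cluster_means",
    "score_zscore",
    "score_ep",
    "score_ee",
    "score_wilcoxon",
    "assign_top_n",
    "validate_discrimination",
    "window_discrimination",
    "overlap_matrix",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ScoreMatrix:
    """Gene x cluster specificity scores from one method."""

    values: pd.DataFrame              # index gene, columns cluster
    method: str
    flagged_genes: list = field(default_factory=list)

    def top_genes(self, cluster, n):
        """Top-n genes for a cluster; ties broken by (score desc, gene id asc)."""
        s = self.values[cluster]
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return order[:n]


@dataclass
class GeneSetCollection:
    """Named ordered gene sets with construction metadata; GMT-serializable."""

    sets: dict                         # set id -> list of genes (ordered, unique)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate genes in set {name!r}")

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def names(self):
        return list(self.sets)

    def to_gmt(self, path):
        write_gmt(self.sets, path, description=self.metadata.get("description", ""))

    @classmethod
    def from_gmt(cls, path):
        return cls(sets=read_gmt(path))


def write_gmt(sets: dict, path, description=""):
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description or name, *members]) + "\n")


def read_gmt(path):
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# --------------------------------------------------------------------------- #
# scores
# --------------------------------------------------------------------------- #
def _layer(adata, layer):
    X = adata.layers[layer] if layer is not None else adata.X
    return X


def cluster_means(adata, labeling: ClusterLabeling, layer=LOG_CPM_LAYER):
    """Per-cluster mean expression; clusters x genes DataFrame."""
    rows = {}
    for c in labeling.clusters:
        cells = labeling.cells_of(c)
        X = _layer(adata[cells], layer)
        rows[c] = np.asarray(X.mean(axis=0)).ravel()
    return pd.DataFrame(rows, index=adata.var_names).T


def score_zscore(adata, labeling, layer=LOG_CPM_LAYER) -> ScoreMatrix:
    """Standardize each gene's per-cluster means (population SD).

    Genes whose per-cluster means are constant (sigma = 0) score 0 everywhere
    and are flagged.
    """
    m = cluster_means(adata, labeling, layer)
    if m.shape[0] < 2:
        raise ValueError("z-score requires at least 2 clusters")
    mu = m.mean(axis=0)
    sigma = m.std(axis=0, ddof=0)
    flagged = list(sigma.index[sigma == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mu) / sigma
    z[sigma.index[sigma == 0]] = 0.0
    return ScoreMatrix(values=z.T, method="zscore", flagged_genes=flagged)


def score_ep(adata, labeling, layer=LOG_CPM_LAYER) -> ScoreMatrix:
    """Expression proportion: fraction of a gene's summed per-cluster means per cluster.

    All-zero genes have no defined proportion and are excluded (flagged).
    """
    m = cluster_means(adata, labeling, layer)
    totals = m.sum(axis=0)
    flagged = list(totals.index[totals == 0])
    ep = (m / totals).T.drop(index=flagged)
    return ScoreMatrix(values=ep, method="ep", flagged_genes=flagged)


def score_ee(adata, labeling, layer=LOG_CPM_LAYER) -> ScoreMatrix:
    """Expression enrichment: EP over the cluster's share of total expression.

    ``EE_i = EP_i * (sum_j s_j / s_i)`` with ``s_i`` the total expression of
    cluster i; a gene expressed uniformly (relative to cluster totals) scores
    1 in every cluster, and the weighted sum ``sum_i (s_i/sum s) EE_i`` is 1.
    """
    m = cluster_means(adata, labeling, layer)
    s = m.sum(axis=1)                      # total expression per cluster
    if (s == 0).any():
        raise ValueError("cluster with zero total expression")
    totals = m.sum(axis=0)
    flagged = list(totals.index[totals == 0])
    ep = (m / totals).T.drop(index=flagged)
    share = s / s.sum()
    ee = ep / share
    return ScoreMatrix(values=ee, method="ee", flagged_genes=flagged)


def score_wilcoxon(adata, labeling, layer=LOG_CPM_LAYER, chunk_size=2000) -> ScoreMatrix:
    """Tie-corrected rank-sum z of in-cluster vs out-of-cluster cells, per gene.

    Positive z means the gene is higher inside the cluster; degenerate genes
    (all cells tied) score 0.
    """
    cells = labeling.assignments.index
    lab = labeling.assignments.to_numpy()
    clusters = labeling.clusters
    genes = list(adata.var_names)
    N = len(lab)
    out = np.zeros((len(genes), len(clusters)))
    for lo in range(0, len(genes), chunk_size):
        block = genes[lo:lo + chunk_size]
        X = _layer(adata[cells, block], layer)
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
        ranks = rankdata(X, axis=0)
        # tie correction term per gene: sum over tie groups of (t^3 - t)
        tie_term = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            _, counts = np.unique(X[:, j], return_counts=True)
            tie_term[j] = (counts.astype(float) ** 3 - counts).sum()
        for ci, c in enumerate(clusters):
            m = lab == c
            n1 = int(m.sum())
            n2 = N - n1
            if n1 < 2 or n2 < 2:
                raise ValueError(f"cluster {c!r} needs >=2 cells inside and outside")
            u = ranks[m].sum(axis=0) - n1 * (n1 + 1) / 2
            mean_u = n1 * n2 / 2
            var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (u - mean_u) / np.sqrt(var_u)
            out[lo:lo + len(block), ci] = np.where(var_u > 0, z, 0.0)
    return ScoreMatrix(
        values=pd.DataFrame(out, index=genes, columns=clusters), method="wilcoxon"
    )


# --------------------------------------------------------------------------- #
# set construction and validation
# --------------------------------------------------------------------------- #
def assign_top_n(scores: ScoreMatrix, n: int = 600, loeuf: pd.Series | None = None,
                 loeuf_cutoff: float = 0.6, retained_genes=None) -> GeneSetCollection:
    """Build one fixed-size gene set per cluster from the top-scoring genes.

    ``retained_genes`` restricts the candidate universe (typically the output
    of the low-detection filter).  When a LOEUF table is given, genes with
    LOEUF strictly above the cutoff are removed *after* the top-n selection,
    so constrained sets may be smaller than n; genes missing from the table
    are treated as unconstrained (removed) and flagged in the metadata.
    """
    values = scores.values
    if retained_genes is not None:
        values = values.loc[values.index.intersection(retained_genes)]
    sets, n_missing_loeuf = {}, 0
    for cluster in values.columns:
        s = values[cluster]
        top = sorted(s.index, key=lambda g: (-s[g], g))[:n]
        if loeuf is not None:
            kept = []
            for g in top:
                lv = loeuf.get(g, np.nan)
                if np.isnan(lv):
                    n_missing_loeuf += 1
                    continue
                if lv <= loeuf_cutoff:
                    kept.append(g)
            top = kept
        sets[str(cluster)] = top
    meta = {
        "method": scores.method,
        "target_size": n,
        "loeuf_filter": loeuf is not None,
        "loeuf_cutoff": loeuf_cutoff if loeuf is not None else None,
        "n_missing_loeuf": n_missing_loeuf,
    }
    if n_missing_loeuf:
        warnings.warn(f"{n_missing_loeuf} top-ranked genes lacked a LOEUF value "
                      "and were treated as unconstrained")
    return GeneSetCollection(sets=sets, metadata=meta)


def validate_discrimination(adata, genes, cluster, labeling: ClusterLabeling,
                            layer=LOG_CPM_LAYER) -> float:
    """AUC of the first principal component of a gene window for one cluster.

    Cells are projected on PC1 of the window genes' expression (centered per
    gene, unscaled); the returned AUC is oriented to be >= 0.5.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("window must contain at least 2 genes")
    cells = labeling.assignments.index
    X = _layer(adata[cells, genes], layer)
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    # project explicitly (not fit_transform's U*S) so identical cells tie exactly
    pc1 = Xc @ PCA(n_components=1, svd_solver="full").fit(Xc).components_[0]
    inside = (labeling.assignments == cluster).to_numpy()
    n_in, n_out = int(inside.sum()), int((~inside).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("cluster must have cells both inside and outside")
    r = rankdata(pc1)
    auc = (r[inside].sum() - n_in * (n_in + 1) / 2) / (n_in * n_out)
    return float(max(auc, 1 - auc))


def window_discrimination(adata, scores: ScoreMatrix, labeling, window=100,
                          n_windows=15, layer=LOG_CPM_LAYER) -> pd.DataFrame:
    """PC1 AUC for consecutive specificity-rank windows of each cluster.

    Window w covers ranks ``[w*window, (w+1)*window)`` of the cluster's score
    ordering — the sweep used to check how discrimination decays as less
    specific genes are included.
    """
    rows = []
    for cluster in scores.values.columns:
        ranked = scores.top_genes(cluster, window * n_windows)
        for w in range(n_windows):
            win = ranked[w * window:(w + 1) * window]
            if len(win) < 2:
                break
            rows.append({
                "cluster": cluster, "window": w + 1,
                "rank_start": w * window + 1, "rank_end": w * window + len(win),
                "auc": validate_discrimination(adata, win, cluster, labeling, layer),
            })
    return pd.DataFrame(rows)


def overlap_matrix(collection: GeneSetCollection) -> pd.DataFrame:
    """Pairwise Jaccard index between gene sets (symmetric, unit diagonal)."""
    names = collection.names()
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    members = {n: set(collection[n]) for n in names}
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            union = len(members[a] | members[b])
            j = len(members[a] & members[b]) / union if union else 0.0
            J.loc[a, b] = J.loc[b, a] = j
    return J
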