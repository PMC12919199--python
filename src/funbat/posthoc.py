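"""Post-hoc analyses on burden association results.

* gene prioritization by gene-set downsampling: re-test many random sub-gene
  sets, then ask (Fisher exact) which genes are enriched among the
  FDR-significant subsets;
* Fisher-exact gene-list enrichment over a declared reference universe;
* de novo vs inherited enrichment per gene set, against all cortically
  expressed genes or cases vs unaffected siblings;
* effect-size normalization against random gene sets of matched size, since
  burden estimates shrink as sets grow;
* permutation tests for liability differences between case subgroups (sex,
  diagnosis age), sharing the controls and permuting only the case subgroup
  labels at the observed proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .burden import BurdenAssociationModel
from .variants import CollapsedGenotypes

__all__ = [
    "prioritize_genes",
    "PrioritizationResult",
    "fisher_enrichment",
    "de_novo_enrichment",
    "build_null_effect_distribution",
    "NullEffectDistribution",
    "normalize_effect_size",
    "subgroup_permutation_test",
    "SubgroupBiasResult",
]


def _fit_beta_p(collapsed, genes, vclass, covariates, **kw):
    res = BurdenAssociationModel.from_cohort(collapsed, genes, vclass, covariates, **kw).fit()
    return res.beta, res.p


@dataclass
class PrioritizationResult:
    table: pd.DataFrame                # per gene: counts, OR, p, q, prioritized
    n_significant_subsets: int
    n_subsets: int

    def prioritized(self):
        return list(self.table.index[self.table["prioritized"]])


def prioritize_genes(gene_set, collapsed: CollapsedGenotypes, covariates, vclass,
                     n_subsets: int = 1000, subset_size: int = 100, seed: int = 0,
                     alpha: float = 0.05, **fit_kw) -> PrioritizationResult:
    """Prioritize genes driving a significant burden association.

    ``n_subsets`` random subsets of ``subset_size`` genes are drawn without
    replacement from the set; each is burden-tested and subsets with BH
    q < alpha (family = the subsets) are called significant.  Each gene then
    gets a two-sided Fisher exact test on the 2x2 of (subset significant?) x
    (subset contains gene?), with a second BH family over genes; a gene is
    prioritized when q < alpha and OR > 1.
    """
    gene_set = list(gene_set)
    if subset_size >= len(gene_set):
        raise ValueError("subset_size must be smaller than the gene set")
    if n_subsets < 1:
        raise ValueError("n_subsets must be positive")
    rng = np.random.default_rng(seed)
    members = np.zeros((n_subsets, len(gene_set)), dtype=bool)
    pvals = np.full(n_subsets, np.nan)
    for s in range(n_subsets):
        idx = rng.choice(len(gene_set), size=subset_size, replace=False)
        members[s, idx] = True
        _, pvals[s] = _fit_beta_p(collapsed, [gene_set[i] for i in idx], vclass,
                                  covariates, **fit_kw)
    ok = np.isfinite(pvals)
    sig = np.zeros(n_subsets, dtype=bool)
    if ok.any():
        sig[ok] = multipletests(pvals[ok], method="fdr_bh")[1] < alpha
    n_sig = int(sig.sum())

    rows = []
    for j, gene in enumerate(gene_set):
        a = int((sig & members[:, j]).sum())          # significant, contains
        b = int((sig & ~members[:, j]).sum())
        c = int((~sig & members[:, j]).sum())
        d = int((~sig & ~members[:, j]).sum())
        orr, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if 0 in (a, b, c, d):
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append({"gene": gene, "n_sig_subsets_with_gene": a,
                     "n_subsets_with_gene": a + c, "odds_ratio": float(orr),
                     "p": float(p)})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1] if n_sig else 1.0
    table["prioritized"] = (table["q"] < alpha) & (table["odds_ratio"] > 1)
    return PrioritizationResult(table=table, n_significant_subsets=n_sig,
                                n_subsets=n_subsets)


def fisher_enrichment(query, target, reference):
    """Two-sided Fisher exact enrichment of a gene list in a gene set.

    The 2x2 table crosses query and target membership over the reference
    universe.  Returns (odds ratio, p); when a cell is zero the sample OR
    uses the Haldane 0.5 correction and the result is flagged via the third
    return value.
    """
    query, target, reference = set(query), set(target), set(reference)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= reference or not target <= reference:
        raise ValueError("query and target must be subsets of the reference universe")
    a = len(query & target)
    b = len(query - target)
    c = len(target - query)
    d = len(reference - query - target)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), float(p), corrected


def de_novo_enrichment(de_novo_calls: pd.DataFrame, all_calls: pd.DataFrame,
                       gene_sets: dict, design: str = "vs_all_genes",
                       expressed_genes=None, case_status: pd.Series | None = None
                       ) -> pd.DataFrame:
    """Fisher enrichment of de novo vs inherited variants per gene set.

    ``design="vs_all_genes"``: per set, the 2x2 crosses (de novo, inherited)
    x (in set, rest of the expressed genes).  ``design="case_vs_sibling"``:
    per set, (de novo, inherited) within the set x (case, unaffected
    sibling); requires ``case_status`` over offspring and errors if either
    group is absent.  BH FDR across sets.
    """
    if de_novo_calls.empty:
        raise ValueError("no de novo variants")
    dn_ids = set(de_novo_calls["variant_id"])
    calls = all_calls.copy()
    calls["is_dn"] = calls["variant_id"].isin(dn_ids)
    if expressed_genes is not None:
        calls = calls[calls["gene"].isin(set(expressed_genes))]
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes)
        in_set = calls["gene"].isin(genes)
        if design == "vs_all_genes":
            a = int((calls["is_dn"] & in_set).sum())
            b = int((~calls["is_dn"] & in_set).sum())
            c = int((calls["is_dn"] & ~in_set).sum())
            d = int((~calls["is_dn"] & ~in_set).sum())
        elif design == "case_vs_sibling":
            if case_status is None:
                raise ValueError("case_vs_sibling design requires case_status")
            status = calls["individual_id"].map(case_status)
            known = status.notna()
            if not ((status == 1) & known).any() or not ((status == 0) & known).any():
                raise ValueError("both cases and unaffected siblings are required")
            sub = calls[in_set & known]
            st = status[sub.index]
            a = int((sub["is_dn"] & (st == 1)).sum())
            b = int((~sub["is_dn"] & (st == 1)).sum())
            c = int((sub["is_dn"] & (st == 0)).sum())
            d = int((~sub["is_dn"] & (st == 0)).sum())
        else:
            raise ValueError(f"unknown design {design!r}")
        orr, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if 0 in (a, b, c, d):
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append({"set_id": name, "dn_in": a, "inh_in": b, "dn_out": c,
                     "inh_out": d, "odds_ratio": float(orr), "p": float(p)})
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class NullEffectDistribution:
    """Mean/SD of burden estimates from random gene sets, on a size grid."""

    table: pd.DataFrame                # index size: mean, sd, n_ok
    vclass: str
    skipped_sizes: list = field(default_factory=list)

    def closest(self, size):
        """Grid row closest to ``size`` (ties to the smaller size)."""
        sizes = self.table.index.to_numpy()
        d = np.abs(sizes - size)
        return self.table.loc[sizes[np.lexsort((sizes, d))[0]]]


def build_null_effect_distribution(universe, collapsed, covariates, vclass,
                                   sizes=None, reps_per_size: int = 30, seed: int = 0,
                                   **fit_kw) -> NullEffectDistribution:
    """Burden-estimate null from random gene sets across a size grid.

    Sizes default to 50..950 by 50; sets are drawn without replacement from
    the universe, sizes exceeding the universe are skipped and flagged.
    """
    universe = list(universe)
    sizes = list(sizes) if sizes is not None else list(range(50, 1000, 50))
    rng = np.random.default_rng(seed)
    rows, skipped = [], []
    for size in sizes:
        if size > len(universe):
            skipped.append(size)
            continue
        betas = []
        for _ in range(reps_per_size):
            genes = rng.choice(universe, size=size, replace=False)
            beta, _ = _fit_beta_p(collapsed, genes, vclass, covariates, **fit_kw)
            if np.isfinite(beta):
                betas.append(beta)
        rows.append({"size": size, "mean": float(np.mean(betas)) if betas else np.nan,
                     "sd": float(np.std(betas, ddof=1)) if len(betas) > 1 else np.nan,
                     "n_ok": len(betas)})
    return NullEffectDistribution(
        table=pd.DataFrame(rows).set_index("size"), vclass=vclass, skipped_sizes=skipped
    )


def normalize_effect_size(beta: float, set_size: int,
                          null: NullEffectDistribution) -> float:
    """z-normalize an estimate by the null mean/SD at the closest set size."""
    row = null.closest(set_size)
    if not np.isfinite(row["sd"]) or row["sd"] == 0:
        return np.nan
    return float((beta - row["mean"]) / row["sd"])


@dataclass
class SubgroupBiasResult:
    table: pd.DataFrame                # per (set, class): observed diff, percentile, p, q, significant
    n_perm: int


def subgroup_permutation_test(collapsed, gene_sets: dict, covariates, classes,
                              case_groups: pd.Series, n_perm: int = 5000,
                              seed: int = 0, alpha: float = 0.05,
                              band=(5.0, 95.0), **fit_kw) -> SubgroupBiasResult:
    """Permutation test for liability differences between two case subgroups.

    ``case_groups`` labels every case with one of exactly two group values
    (e.g. sex, early/late diagnosis).  For each (gene set, class) the
    observed statistic is ``beta(group A cases) - beta(group B cases)``,
    where each estimate drops the other subgroup's cases while sharing all
    controls.  The null redraws case group labels ``n_perm`` times at the
    observed proportion; a difference outside the [5th, 95th] percentile band
    is significant, and a two-tailed empirical p (BH-corrected across cells)
    is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    groups = case_groups.dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("case_groups must have exactly two levels")
    cases = covariates.index[covariates["affected"] == 1]
    groups = groups[groups.index.isin(cases)]
    a_ids = set(groups.index[groups == levels[0]])
    b_ids = set(groups.index[groups == levels[1]])
    if not a_ids or not b_ids:
        raise ValueError("both subgroups need at least one case")
    labeled = np.array(sorted(a_ids | b_ids))
    n_a = len(a_ids)
    rng = np.random.default_rng(seed)

    def diff(a_set):
        out = {}
        for name, genes in gene_sets.items():
            for vclass in classes:
                drop_b = covariates.index.isin(labeled) & ~covariates.index.isin(a_set) \
                    & (covariates["affected"] == 1).to_numpy()
                drop_a = covariates.index.isin(a_set) \
                    & (covariates["affected"] == 1).to_numpy()
                beta_a, _ = _fit_beta_p(collapsed, genes, vclass,
                                        covariates[~drop_b], **fit_kw)
                beta_b, _ = _fit_beta_p(collapsed, genes, vclass,
                                        covariates[~drop_a], **fit_kw)
                out[(name, vclass)] = beta_a - beta_b
        return out

    observed = diff(a_ids)
    null = {k: np.empty(n_perm) for k in observed}
    for it in range(n_perm):
        perm_a = set(rng.choice(labeled, size=n_a, replace=False))
        d = diff(perm_a)
        for k, v in d.items():
            null[k][it] = v

    rows = []
    for (name, vclass), obs in observed.items():
        dist = null[(name, vclass)]
        ok = np.isfinite(dist)
        dist = dist[ok]
        if not np.isfinite(obs) or len(dist) == 0:
            rows.append({"set_id": name, "vclass": vclass, "observed_diff": obs,
                         "percentile": np.nan, "p": np.nan, "significant": False})
            continue
        pct = 100.0 * (dist < obs).mean()
        lo = np.percentile(dist, band[0])
        hi = np.percentile(dist, band[1])
        n_lo = int((dist <= obs).sum())
        n_hi = int((dist >= obs).sum())
        p = min(1.0, 2.0 * min(n_lo + 1, n_hi + 1) / (len(dist) + 1))
        rows.append({"set_id": name, "vclass": vclass, "observed_diff": float(obs),
                     "percentile": float(pct), "p": float(p),
                     "significant": bool(obs < lo or obs > hi)})
    table = pd.DataFrame(rows).set_index(["set_id", "vclass"])
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return SubgroupBiasResult(table=table, n_perm=n_perm)
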