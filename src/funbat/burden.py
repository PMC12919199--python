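"""Functional burden association tests (FunBAT) with family strata.

An individual's burden for a gene set and variant class is the number of
distinct set genes carrying at least one QC-passing variant of that class.
The association with case status is estimated by conditional logistic
regression with the family as stratum,

    logit P(case) = beta1 * burden + sex + PC1..PC10 + n_rare_synonymous,

so shared family effects and relatedness cancel.  The exposure log-odds ratio
per burden unit is ``beta1``.  For multigenic CNV classes (deletion,
duplication) two genome-background burdens are added — one over constrained
genes (LOEUF < 1) and one over unconstrained genes outside the studied set —
to absorb the cumulative effect of the other genes a CNV spans.

Families of a single individual or without both outcomes carry no information
for the conditional likelihood and are dropped before fitting.

The module exposes a statsmodels-style pair: :class:`BurdenAssociationModel`
(one gene set x class) whose ``fit`` returns a
:class:`BurdenAssociationResult`, and :func:`run_funbat`, which scans a
collection and returns a :class:`FunbatResults` table with BH FDR applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .clogit import ConditionalLogit
from .simulate import CNV_CLASSES
from .variants import CollapsedGenotypes

__all__ = [
    "build_covariates",
    "compute_burden",
    "filter_strata",
    "BurdenAssociationModel",
    "BurdenAssociationResult",
    "run_funbat",
    "FunbatResults",
    "cohort_downsampling_stability",
]

DEFAULT_COVARIATE_COLS = ["sex_male"] + [f"PC{i}" for i in range(1, 11)] + ["n_rare_synonymous"]


def build_covariates(pedigree: pd.DataFrame, qc_passed_variants: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Assemble the per-individual covariate table from pedigree + variants.

    ``sex_male`` is 1 for PED sex code 1; ``n_rare_synonymous`` counts the
    individual's QC-passing synonymous variant calls (0 when no variant table
    is given).
    """
    cov = pedigree.set_index("individual_id").copy()
    cov["sex_male"] = (cov["sex"].astype(int) == 1).astype(float)
    if qc_passed_variants is not None and len(qc_passed_variants):
        syn = (
            qc_passed_variants[qc_passed_variants["consequence"] == "synonymous"]
            .groupby("individual_id").size()
        )
        cov["n_rare_synonymous"] = cov.index.map(syn).fillna(0).astype(float)
    else:
        cov["n_rare_synonymous"] = 0.0
    keep = ["family_id", "affected", "sex_male", "n_rare_synonymous"] + [
        c for c in cov.columns if c.startswith("PC")
    ]
    return cov[keep]


def compute_burden(collapsed: CollapsedGenotypes, gene_set, vclass,
                   individuals=None) -> pd.Series:
    """Per-individual count of distinct set genes disrupted by ``vclass``.

    Set genes absent from the collapsed universe simply contribute 0.
    """
    gene_set = list(gene_set)
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    if individuals is None:
        individuals = collapsed.individuals
    t = collapsed.triples
    sub = t[(t["vclass"] == vclass) & t["gene"].isin(set(gene_set))]
    counts = sub.groupby("individual_id")["gene"].nunique()
    out = pd.Series(0, index=pd.Index(individuals, name="individual_id"), dtype=float)
    common = counts.index.intersection(out.index)
    out.loc[common] = counts.loc[common].astype(float)
    return out


def filter_strata(covariates: pd.DataFrame):
    """Informative family ids: >= 2 members with both outcome values present."""
    g = covariates.groupby("family_id")["affected"]
    ok = (g.size() >= 2) & (g.nunique() == 2)
    return list(ok.index[ok]), int((~ok).sum())


@dataclass
class BurdenAssociationResult:
    """Estimate and inference for one (gene set, variant class) burden test."""

    set_id: str
    vclass: str
    beta: float
    se: float
    p: float
    n_informative_strata: int
    n_dropped_strata: int
    converged: bool
    diverged: bool
    flag: str = ""
    q: float = np.nan
    details: object = None             # full ConditionalLogitResults, when fitted

    @property
    def odds_ratio(self):
        return float(np.exp(self.beta))

    def to_dict(self):
        return {
            "set_id": self.set_id, "vclass": self.vclass, "beta": self.beta,
            "or": self.odds_ratio if np.isfinite(self.beta) else np.nan,
            "se": self.se, "p": self.p, "q": self.q,
            "n_informative_strata": self.n_informative_strata,
            "n_dropped_strata": self.n_dropped_strata,
            "converged": self.converged, "diverged": self.diverged, "flag": self.flag,
        }

    def summary(self):
        return (
            f"FunBAT {self.set_id} x {self.vclass}: beta1={self.beta:.4f} "
            f"(OR={self.odds_ratio:.3f}), se={self.se:.4f}, p={self.p:.3g}; "
            f"{self.n_informative_strata} informative strata "
            f"({self.n_dropped_strata} dropped)"
            + (f" [{self.flag}]" if self.flag else "")
        )


class BurdenAssociationModel:
    """Family-stratified conditional logistic model for one burden vector.

    Parameters
    ----------
    burden : Series
        Per-individual burden, indexed by individual id.
    covariates : DataFrame
        Must carry ``family_id``, ``affected`` and the adjustment columns
        (``sex_male``, ``PC1``..``PC10``, ``n_rare_synonymous`` by default).
    background : DataFrame, optional
        Extra burden columns entering the linear predictor (the two
        genome-background burdens of the CNV model).
    """

    def __init__(self, burden: pd.Series, covariates: pd.DataFrame,
                 background: pd.DataFrame | None = None,
                 covariate_cols=None, set_id="set", vclass="class"):
        self.set_id, self.vclass = set_id, vclass
        cols = [c for c in (covariate_cols or DEFAULT_COVARIATE_COLS)
                if c in covariates.columns]
        ids = covariates.index
        design = pd.DataFrame({"burden": burden.reindex(ids).fillna(0.0)})
        if background is not None:
            for c in background.columns:
                design[c] = background[c].reindex(ids).fillna(0.0)
        for c in cols:
            design[c] = covariates[c].astype(float)
        self.design = design
        self.endog = covariates["affected"].astype(int).to_numpy()
        self.groups = covariates["family_id"].to_numpy()
        informative, self._n_dropped = filter_strata(covariates)
        self._n_informative = len(informative)

    @classmethod
    def from_cohort(cls, collapsed: CollapsedGenotypes, gene_set, vclass,
                    covariates: pd.DataFrame, gene_annotation: pd.DataFrame | None = None,
                    cnv_background: bool | None = None,
                    background_loeuf_cutoff: float = 1.0, set_id="set", **kw):
        """Build the model from collapsed genotypes and a gene set.

        CNV classes (``deletion``/``duplication``) automatically get the
        two-background-burden design when ``gene_annotation`` (with ``gene``
        and ``loeuf`` columns) is available; ``cnv_background`` overrides the
        class-based default.
        """
        ids = covariates.index
        burden = compute_burden(collapsed, gene_set, vclass, individuals=ids)
        use_bg = vclass in CNV_CLASSES if cnv_background is None else cnv_background
        background = None
        if use_bg:
            if gene_annotation is None:
                raise ValueError("background burdens require a gene annotation with LOEUF")
            loeuf = gene_annotation.set_index("gene")["loeuf"]
            outside = loeuf.index.difference(pd.Index(gene_set))
            constrained = outside[loeuf.loc[outside] < background_loeuf_cutoff]
            unconstrained = outside[loeuf.loc[outside] >= background_loeuf_cutoff]
            background = pd.DataFrame({
                "bg_constrained": compute_burden(collapsed, constrained, vclass, ids)
                if len(constrained) else pd.Series(0.0, index=ids),
                "bg_unconstrained": compute_burden(collapsed, unconstrained, vclass, ids)
                if len(unconstrained) else pd.Series(0.0, index=ids),
            })
        return cls(burden, covariates, background=background,
                   set_id=set_id, vclass=vclass, **kw)

    def fit(self, **fit_kw) -> BurdenAssociationResult:
        base = dict(
            set_id=self.set_id, vclass=self.vclass,
            n_informative_strata=self._n_informative,
            n_dropped_strata=self._n_dropped,
        )
        if self._n_informative == 0:
            return BurdenAssociationResult(
                beta=np.nan, se=np.nan, p=np.nan, converged=False, diverged=False,
                flag="no_informative_strata", **base)
        try:
            model = ConditionalLogit(self.endog, self.design, self.groups)
        except ValueError as exc:
            return BurdenAssociationResult(
                beta=np.nan, se=np.nan, p=np.nan, converged=False, diverged=False,
                flag=str(exc), **base)
        if "burden" in model.dropped_columns:
            return BurdenAssociationResult(
                beta=np.nan, se=np.nan, p=np.nan, converged=False, diverged=False,
                flag="burden_constant_within_strata", **base)
        res = model.fit(**fit_kw)
        j = model.exog_names.index("burden")
        flag = "diverged" if res.diverged else ("" if res.converged else "not_converged")
        return BurdenAssociationResult(
            beta=float(res.params[j]), se=float(res.bse[j]), p=float(res.pvalues[j]),
            converged=res.converged, diverged=res.diverged, flag=flag,
            details=res, **base)


@dataclass
class FunbatResults:
    """Result table of a FunBAT scan over gene sets x variant classes."""

    results: list = field(default_factory=list)
    fdr_family: str = "all"

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def apply_fdr(self):
        df = self.frame
        if self.fdr_family == "per_class":
            families = [df.index[df["vclass"] == c] for c in df["vclass"].unique()]
        else:
            families = [df.index]
        q = pd.Series(np.nan, index=df.index)
        for fam in families:
            ok = fam[df.loc[fam, "p"].notna()]
            if len(ok):
                q.loc[ok] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
        for r, qv in zip(self.results, q):
            r.q = float(qv) if np.isfinite(qv) else np.nan
        return self

    def estimates(self) -> pd.Series:
        df = self.frame
        return df.set_index(["set_id", "vclass"])["beta"]

    def summary(self, alpha=0.05):
        df = self.frame
        n_sig = int((df["q"] < alpha).sum())
        head = (
            f"FunBAT scan: {len(df)} tests ({df['set_id'].nunique()} gene sets x "
            f"{df['vclass'].nunique()} classes), BH family: {self.fdr_family}\n"
            f"{n_sig} associations at FDR < {alpha}\n"
        )
        cols = ["set_id", "vclass", "beta", "or", "se", "p", "q",
                "n_informative_strata", "flag"]
        return head + df[cols].to_string(index=False, float_format=lambda v: f"{v:9.4f}")

    def plot_heatmap(self, value="beta", ax=None):
        """Gene set x class heatmap of estimates (matplotlib)."""
        import matplotlib.pyplot as plt

        wide = self.frame.pivot(index="set_id", columns="vclass", values=value)
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + wide.shape[1], 1 + 0.3 * wide.shape[0]))
        im = ax.imshow(wide.to_numpy(), aspect="auto", cmap="coolwarm")
        ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
        ax.set_yticks(range(wide.shape[0]), wide.index)
        ax.figure.colorbar(im, ax=ax, label=value)
        return ax


def run_funbat(collapsed: CollapsedGenotypes, collection, covariates: pd.DataFrame,
               classes=None, gene_annotation=None, fdr_family="all",
               covariate_cols=None) -> FunbatResults:
    """Fit one burden model per (gene set, variant class) and apply BH FDR.

    ``collection`` is a GeneSetCollection or plain dict of set id -> genes.
    Classes default to every class present in the collapsed triples.  Cells
    that cannot be fitted (no carriers among informative strata, burden
    constant within every family) are kept as NA rows for bookkeeping.
    """
    sets = collection.sets if hasattr(collection, "sets") else dict(collection)
    classes = list(classes) if classes is not None else collapsed.classes()
    out = FunbatResults(fdr_family=fdr_family)
    for set_id, genes in sets.items():
        for vclass in classes:
            model = BurdenAssociationModel.from_cohort(
                collapsed, genes, vclass, covariates,
                gene_annotation=gene_annotation,
                set_id=set_id, covariate_cols=covariate_cols,
            )
            out.results.append(model.fit())
    return out.apply_fdr()


def cohort_downsampling_stability(collapsed, collection, covariates,
                                  fractions=None, reps: int = 20, seed: int = 0,
                                  classes=None, gene_annotation=None,
                                  full_results: FunbatResults | None = None,
                                  covariate_cols=None) -> pd.DataFrame:
    """Spearman correlation of downsampled liability estimates vs the full cohort.

    Families (strata) are sampled without replacement at each fraction
    (default 10%..90% by 10%), estimates are recomputed, and each replicate's
    estimate vector is correlated with the full-cohort vector.  Replicates
    with fewer than 2 informative strata or fewer than 3 comparable estimates
    are skipped and flagged.
    """
    fractions = list(fractions) if fractions is not None else [f / 10 for f in range(1, 10)]
    if full_results is None:
        full_results = run_funbat(collapsed, collection, covariates, classes=classes,
                                  gene_annotation=gene_annotation,
                                  covariate_cols=covariate_cols)
    full = full_results.estimates()
    families = covariates["family_id"].unique()
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n_take = int(round(frac * len(families)))
        for rep in range(reps):
            take = rng.choice(families, size=n_take, replace=False)
            cov_sub = covariates[covariates["family_id"].isin(take)]
            informative, _ = filter_strata(cov_sub)
            if len(informative) < 2:
                rows.append({"fraction": frac, "rep": rep, "spearman_r": np.nan,
                             "n_families": n_take, "skipped": True})
                continue
            res = run_funbat(collapsed, collection, cov_sub, classes=classes,
                             gene_annotation=gene_annotation,
                             covariate_cols=covariate_cols)
            est = res.estimates()
            both = full.notna() & est.notna()
            if both.sum() < 3:
                rows.append({"fraction": frac, "rep": rep, "spearman_r": np.nan,
                             "n_families": n_take, "skipped": True})
                continue
            r = spearmanr(full[both], est[both]).statistic
            rows.append({"fraction": frac, "rep": rep, "spearman_r": float(r),
                         "n_families": n_take, "skipped": False})
    return pd.DataFrame(rows)
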