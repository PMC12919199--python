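"""Synthetic single-cell expression matrices and family-structured variant cohorts.

Every downstream stage of the package (specificity profiles, gene-set
construction, variant QC, burden association) is exercised on data from this
module, with the planted structure returned as an explicit ground truth:

* :func:`simulate_expression` draws negative-binomial counts for clusters
  defined as cell type x developmental epoch, with marker genes whose mean is
  fold-elevated in their home cluster.
* :func:`simulate_cohort` builds trio/quad/singleton families, gives founders
  rare variants per consequence class at a per-gene rate, transmits each
  parental variant to offspring with probability 1/2, injects de novo
  variants into offspring only, attaches QC fields with controlled failure
  fractions, draws multigenic CNVs, and assigns affection status from a
  logistic liability on the true post-QC burden of the planted gene sets.

Affection status is drawn from the same logistic model for parents and
offspring, making family members exchangeable; the conditional-logistic
burden test is then correctly specified and planted log-odds ratios are
recoverable.  The intercept is calibrated by bisection so the expected case
fraction among offspring hits the configured target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ExpressionSimConfig",
    "CohortSimConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_expression",
    "simulate_cohort",
    "SHORT_VARIANT_CLASSES",
    "CNV_CLASSES",
]

SHORT_VARIANT_CLASSES = ("stop_gained", "frameshift", "splice", "missense", "synonymous")
CNV_CLASSES = ("deletion", "duplication")


# --------------------------------------------------------------------------- #
# configs and ground truth
# --------------------------------------------------------------------------- #
@dataclass
class ExpressionSimConfig:
    n_celltypes: int = 3
    n_epochs: int = 2
    cells_per_cluster: int = 200
    n_genes: int = 1000
    markers_per_cluster: int = 20
    marker_fold: float = 8.0
    baseline_mean: float = 0.5
    dispersion: float = 0.5
    dropout: float = 0.3
    n_donors: int = 4
    seed: int = 0

    def validate(self):
        if self.markers_per_cluster * self.n_celltypes * self.n_epochs > self.n_genes:
            raise ValueError(
                "infeasible config: markers_per_cluster x n_celltypes x n_epochs "
                f"({self.markers_per_cluster * self.n_celltypes * self.n_epochs}) "
                f"exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        for name in ("marker_fold", "baseline_mean", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_rates():
    # expected rare-variant count per gene per founder, by consequence class
    return {
        "stop_gained": 1e-3,
        "frameshift": 1e-3,
        "splice": 5e-4,
        "missense": 5e-3,
        "synonymous": 1e-2,
        "deletion": 2e-4,
        "duplication": 2e-4,
    }


def _default_qc_fail():
    return {"dp": 0.05, "gq": 0.05, "allele_ratio": 0.05, "maf": 0.05,
            "class_score": 0.10, "cnv_score": 0.05, "cnv_size": 0.05}


@dataclass
class CohortSimConfig:
    n_families: int = 500
    # proportions of (trio, quad, singleton, all-affected quad)
    family_structure_mix: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    case_fraction_offspring: float = 0.5
    n_genes: int = 1000
    per_gene_rate: dict = field(default_factory=_default_rates)
    de_novo_fraction: float = 0.1
    gene_sets: dict = field(default_factory=dict)            # set id -> list of gene names
    planted_effects: list = field(default_factory=list)      # (set id, class, theta)
    cnv_multigene_rate: float = 0.3
    qc_fail_fractions: dict = field(default_factory=_default_qc_fail)
    n_batches: int = 2
    seed: int = 0

    def validate(self):
        mix = np.asarray(self.family_structure_mix, dtype=float)
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("family_structure_mix must be non-negative and sum to 1")
        if any(r < 0 for r in self.per_gene_rate.values()):
            raise ValueError("per-gene rates must be >= 0")
        for set_id, vclass, theta in self.planted_effects:
            if set_id not in self.gene_sets:
                raise ValueError(f"planted effect references unknown gene set {set_id!r}")
            if len(self.gene_sets[set_id]) == 0:
                raise ValueError(f"planted gene set {set_id!r} is empty")
            if not np.isfinite(theta):
                raise ValueError("planted theta must be finite")
            if vclass not in SHORT_VARIANT_CLASSES + CNV_CLASSES:
                raise ValueError(f"unknown variant class {vclass!r}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset.

    ``marker_assignment`` maps marker genes to their home cluster (expression
    simulations); ``de_novo_variant_ids`` lists the variant-call ids injected
    de novo (cohort simulations); ``true_burden`` holds each individual's
    post-QC burden for every planted (gene set, class) pair.
    """

    marker_assignment: dict = field(default_factory=dict)
    planted_effects: list = field(default_factory=list)
    de_novo_variant_ids: set = field(default_factory=set)
    intercept: float | None = None
    true_burden: pd.DataFrame | None = None
    gene_sets: dict = field(default_factory=dict)

    def to_json(self, path):
        payload = {
            "marker_assignment": self.marker_assignment,
            "planted_effects": [list(e) for e in self.planted_effects],
            "de_novo_variant_ids": sorted(self.de_novo_variant_ids),
            "intercept": self.intercept,
            "gene_sets": {k: list(v) for k, v in self.gene_sets.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedCohort:
    pedigree: pd.DataFrame
    variants: pd.DataFrame
    cnvs: pd.DataFrame
    gene_annotation: pd.DataFrame
    truth: GroundTruth


# --------------------------------------------------------------------------- #
# expression
# --------------------------------------------------------------------------- #
def simulate_expression(config: ExpressionSimConfig):
    """Draw a cell x gene negative-binomial count matrix with planted markers.

    Returns an :class:`anndata.AnnData` (sparse counts in ``X``; ``obs`` has
    ``cell_type``, ``epoch``, ``donor``) and a :class:`GroundTruth` whose
    ``marker_assignment`` maps each marker gene to its home cluster id
    ``"<cell_type>|<epoch>"``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    celltypes = [f"CT{i + 1}" for i in range(config.n_celltypes)]
    epochs = [f"E{j + 1}" for j in range(config.n_epochs)]
    clusters = [(ct, ep) for ct in celltypes for ep in epochs]
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])

    marker_assignment = {}
    mpc = config.markers_per_cluster
    for c, (ct, ep) in enumerate(clusters):
        for g in genes[c * mpc:(c + 1) * mpc]:
            marker_assignment[g] = f"{ct}|{ep}"

    n_clusters = len(clusters)
    n_cells = n_clusters * config.cells_per_cluster
    shape = 1.0 / config.dispersion
    blocks = []
    for c in range(n_clusters):
        mu = np.full(config.n_genes, config.baseline_mean)
        mu[c * mpc:(c + 1) * mpc] *= config.marker_fold
        lam = rng.gamma(shape, mu / shape, size=(config.cells_per_cluster, config.n_genes))
        counts = rng.poisson(lam)
        if config.dropout > 0:
            counts = np.where(rng.random(counts.shape) < config.dropout, 0, counts)
        blocks.append(counts)
    X = np.vstack(blocks)

    obs = pd.DataFrame(
        {
            "cell_type": np.repeat([ct for ct, _ in clusters], config.cells_per_cluster),
            "epoch": np.repeat([ep for _, ep in clusters], config.cells_per_cluster),
            "donor": [f"D{i % config.n_donors + 1}" for i in range(n_cells)],
        },
        index=[f"cell{i:06d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(X), obs=obs, var=pd.DataFrame(index=genes)
    )
    truth = GroundTruth(marker_assignment=marker_assignment)
    return adata, truth


# --------------------------------------------------------------------------- #
# cohort
# --------------------------------------------------------------------------- #
def _gene_annotation(n_genes, rng):
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n_genes)])
    lengths = rng.integers(20_000, 200_000, size=n_genes)
    starts = np.zeros(n_genes, dtype=int)
    pos = {}
    for i in range(n_genes):
        c = chroms[i]
        starts[i] = pos.get(c, 10_000)
        pos[c] = starts[i] + lengths[i] + rng.integers(5_000, 50_000)
    loeuf = np.clip(rng.normal(0.9, 0.45, size=n_genes), 0.01, 2.0)
    return pd.DataFrame(
        {"gene": genes, "chrom": chroms, "start": starts,
         "end": starts + lengths, "loeuf": np.round(loeuf, 4)}
    )


def _build_pedigree(config, rng):
    kinds = rng.choice(4, size=config.n_families, p=np.asarray(config.family_structure_mix))
    rows = []
    for f, kind in enumerate(kinds):
        fam = f"F{f + 1:05d}"
        if kind == 2:  # singleton
            rows.append((fam, f"{fam}_s1", "", "", int(rng.integers(1, 3)), "singleton"))
            continue
        n_children = 1 if kind == 0 else 2
        rows.append((fam, f"{fam}_fa", "", "", 1, "parent"))
        rows.append((fam, f"{fam}_mo", "", "", 2, "parent"))
        for c in range(n_children):
            rows.append(
                (fam, f"{fam}_c{c + 1}", f"{fam}_fa", f"{fam}_mo",
                 int(rng.integers(1, 3)), "offspring")
            )
    ped = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "role"]
    )
    ped["forced_affected"] = ped["family_id"].isin(
        [f"F{f + 1:05d}" for f, k in enumerate(kinds) if k == 3]
    )
    return ped


def _draw_call_qc(n, fail, rng):
    """Per-call QC fields (DP, GQ, allele ratio) with controlled failure rates."""
    dp_fail = rng.random(n) < fail["dp"]
    dp = np.where(dp_fail, rng.integers(5, 20, n), 20 + rng.poisson(20, n))
    gq_fail = rng.random(n) < fail["gq"]
    gq = np.where(gq_fail, rng.integers(0, 30, n), rng.integers(30, 100, n))
    ar_fail = rng.random(n) < fail["allele_ratio"]
    low = rng.random(n) < 0.5
    ar_bad = np.where(low, rng.uniform(0.0, 0.19, n), rng.uniform(0.81, 1.0, n))
    ar = np.where(ar_fail, ar_bad, rng.uniform(0.2, 0.8, n))
    return dp, gq, np.round(ar, 4)


def _site_annotations(classes, fail, rng):
    """Site-level annotations shared by every carrier of a site."""
    n = len(classes)
    maf_fail = rng.random(n) < fail["maf"]
    maf_cohort = np.where(maf_fail, rng.uniform(2e-3, 5e-2, n), rng.uniform(0, 1e-3, n))
    maf_ref = np.where(rng.random(n) < fail["maf"], rng.uniform(2e-3, 5e-2, n),
                       rng.uniform(0, 1e-3, n))
    score_fail = rng.random(n) < fail["class_score"]
    loftee = np.where(np.isin(classes, ("stop_gained", "frameshift")),
                      ~score_fail, False)
    am = np.where(classes == "missense",
                  np.where(score_fail, rng.uniform(0, 0.9, n), rng.uniform(0.9, 1.0, n)),
                  np.nan)
    spl = np.where(classes == "splice",
                   np.where(score_fail, rng.uniform(0, 0.8, n), rng.uniform(0.8, 1.0, n)),
                   np.nan)
    return (np.round(maf_cohort, 6), np.round(maf_ref, 6), loftee,
            np.round(am, 4), np.round(spl, 4))


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Simulate pedigree, short-variant, and CNV tables with known ground truth.

    Short variants are generated at the *site* level in founders (Poisson per
    gene per class), transmitted to each offspring independently with
    probability 1/2, and complemented by de novo sites injected into offspring
    only; a variant call's parental-carrier flags are computed from the actual
    parental site sets, so de novo truth is exactly "absent from both
    parents".  QC annotations fail at the configured fractions; the liability
    model uses only calls whose every QC field passes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_ped, rng_var, rng_cnv, rng_pheno = (np.random.default_rng(s) for s in ss)

    genes_df = _gene_annotation(config.n_genes, rng_ped)
    gene_names = genes_df["gene"].to_numpy()
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for set_id, members in config.gene_sets.items():
        missing = [g for g in members if g not in gene_index]
        if missing:
            raise ValueError(f"gene set {set_id!r} references unknown genes: {missing[:3]}")

    ped = _build_pedigree(config, rng_ped)
    founders = ped.loc[ped["father_id"] == "", "individual_id"].to_numpy()
    offspring = ped.loc[ped["father_id"] != ""]

    # ---- founder short-variant sites ----
    fail = config.qc_fail_fractions
    rec_ind, rec_gene, rec_class, rec_site = [], [], [], []
    site_counter = 0
    for vclass in SHORT_VARIANT_CLASSES:
        rate = config.per_gene_rate.get(vclass, 0.0)
        if rate <= 0:
            continue
        counts = rng_var.poisson(rate * config.n_genes, size=len(founders))
        total = int(counts.sum())
        if total == 0:
            continue
        rec_ind.append(np.repeat(founders, counts))
        rec_gene.append(rng_var.integers(0, config.n_genes, total))
        rec_class.append(np.full(total, vclass))
        rec_site.append(np.arange(site_counter, site_counter + total))
        site_counter += total

    def _concat(parts, dtype=None):
        if not parts:
            return np.array([], dtype=dtype if dtype else object)
        return np.concatenate(parts)

    f_ind = _concat(rec_ind)
    f_gene = _concat(rec_gene, int).astype(int)
    f_class = _concat(rec_class)
    f_site = _concat(rec_site, int).astype(int)

    # ---- transmission to offspring ----
    order = np.argsort(f_ind, kind="stable")
    f_ind, f_gene, f_class, f_site = f_ind[order], f_gene[order], f_class[order], f_site[order]
    bounds = {}
    if len(f_ind):
        starts = np.flatnonzero(np.r_[True, f_ind[1:] != f_ind[:-1]])
        stops = np.r_[starts[1:], len(f_ind)]
        bounds = {f_ind[a]: (a, b) for a, b in zip(starts, stops)}

    o_ind, o_gene, o_class, o_site, o_fc, o_mc = [], [], [], [], [], []
    for _, row in offspring.iterrows():
        for parent in (row.father_id, row.mother_id):
            a, b = bounds.get(parent, (0, 0))
            if b <= a:
                continue
            keep = rng_var.random(b - a) < 0.5
            if not keep.any():
                continue
            sl = slice(a, b)
            o_ind.append(np.full(keep.sum(), row.individual_id))
            o_gene.append(f_gene[sl][keep])
            o_class.append(f_class[sl][keep])
            o_site.append(f_site[sl][keep])

    # de novo sites
    dn_sites = []
    for vclass in SHORT_VARIANT_CLASSES:
        rate = config.de_novo_fraction * config.per_gene_rate.get(vclass, 0.0)
        if rate <= 0:
            continue
        counts = rng_var.poisson(rate * config.n_genes, size=len(offspring))
        total = int(counts.sum())
        if total == 0:
            continue
        o_ind.append(np.repeat(offspring["individual_id"].to_numpy(), counts))
        o_gene.append(rng_var.integers(0, config.n_genes, total))
        o_class.append(np.full(total, vclass))
        new_sites = np.arange(site_counter, site_counter + total)
        o_site.append(new_sites)
        dn_sites.append(new_sites)
        site_counter += total

    all_ind = np.concatenate([f_ind, _concat(o_ind)]) if o_ind else f_ind
    all_gene = np.concatenate([f_gene, _concat(o_gene, int).astype(int)]) if o_ind else f_gene
    all_class = np.concatenate([f_class, _concat(o_class)]) if o_ind else f_class
    all_site = np.concatenate([f_site, _concat(o_site, int).astype(int)]) if o_ind else f_site
    dn_site_set = set(_concat(dn_sites, int).astype(int).tolist()) if dn_sites else set()

    # parental carrier flags, from actual parental site sets
    carrier = {}
    for ind, site in zip(f_ind, f_site):
        carrier.setdefault(ind, set()).add(int(site))
    fa_of = dict(zip(ped["individual_id"], ped["father_id"]))
    mo_of = dict(zip(ped["individual_id"], ped["mother_id"]))
    father_c = np.full(len(all_ind), np.nan, dtype=object)
    mother_c = np.full(len(all_ind), np.nan, dtype=object)
    for i, (ind, site) in enumerate(zip(all_ind, all_site)):
        fa, mo = fa_of[ind], mo_of[ind]
        if fa:
            father_c[i] = int(site) in carrier.get(fa, ())
            mother_c[i] = int(site) in carrier.get(mo, ())

    # site-level annotations (shared across carriers of a site)
    uniq_sites, first_idx = np.unique(all_site, return_index=True)
    site_class = all_class[first_idx]
    maf_c, maf_r, loftee, am, spl = _site_annotations(site_class, fail, rng_var)
    pos = {s: i for i, s in enumerate(uniq_sites)}
    site_row = np.array([pos[s] for s in all_site])
    dp, gq, ar = _draw_call_qc(len(all_ind), fail, rng_var)

    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:07d}" for i in range(len(all_ind))],
            "individual_id": all_ind,
            "gene": gene_names[all_gene],
            "consequence": all_class,
            "site_id": all_site,
            "DP": dp,
            "GQ": gq,
            "allele_ratio": ar,
            "maf_cohort": maf_c[site_row],
            "maf_reference": maf_r[site_row],
            "loftee_hc": loftee[site_row],
            "alphamissense": am[site_row],
            "spliceai_delta": spl[site_row],
            "father_carrier": father_c,
            "mother_carrier": mother_c,
        }
    )

    # ---- CNVs ----
    cnv_rows = []
    individuals = ped["individual_id"].to_numpy()
    fam_of = dict(zip(ped["individual_id"], ped["family_id"]))
    fam_ids = ped["family_id"].unique()
    batch_of_family = {f: f"batch{(i % config.n_batches) + 1}" for i, f in enumerate(fam_ids)}
    cnv_id = 0
    for vclass, cn_choices in (("deletion", (1, 0)), ("duplication", (3, 4))):
        rate = config.per_gene_rate.get(vclass, 0.0)
        if rate <= 0:
            continue
        counts = rng_cnv.poisson(rate * config.n_genes, size=len(individuals))
        for ind, k in zip(individuals, counts):
            for _ in range(k):
                anchor = int(rng_cnv.integers(0, config.n_genes))
                span = 1
                if rng_cnv.random() < config.cnv_multigene_rate:
                    span = int(rng_cnv.integers(2, 5))
                last = min(anchor + span - 1, config.n_genes - 1)
                while genes_df.loc[last, "chrom"] != genes_df.loc[anchor, "chrom"]:
                    last -= 1
                size_fail = rng_cnv.random() < fail["cnv_size"]
                if size_fail:
                    start = int(genes_df.loc[anchor, "start"])
                    end = start + int(rng_cnv.integers(5_000, 50_000))
                else:
                    pad = int(rng_cnv.integers(10_000, 50_000))
                    start = max(0, int(genes_df.loc[anchor, "start"]) - pad)
                    end = int(genes_df.loc[last, "end"]) + pad
                    if end - start < 50_000:
                        end = start + 50_000 + pad
                score_fail = rng_cnv.random() < fail["cnv_score"]
                score = rng_cnv.uniform(5, 30) if score_fail else rng_cnv.uniform(30, 200)
                cnv_rows.append(
                    (f"cnv{cnv_id:06d}", ind, genes_df.loc[anchor, "chrom"], start, end,
                     int(rng_cnv.choice(cn_choices, p=[0.9, 0.1])), round(score, 2),
                     batch_of_family[fam_of[ind]])
                )
                cnv_id += 1
    cnvs = pd.DataFrame(
        cnv_rows, columns=["cnv_id", "individual_id", "chrom", "start", "end",
                           "copy_number", "likelihood_score", "batch"],
    )

    # ---- phenotype from true post-QC burden ----
    qc_pass = _true_qc_pass(variants)
    truth_burden = _true_burdens(config, ped, variants[qc_pass], cnvs, genes_df, gene_index)
    eta = np.zeros(len(ped))
    for set_id, vclass, theta in config.planted_effects:
        eta += theta * truth_burden[f"{set_id}|{vclass}"].to_numpy()
    is_off = (ped["role"] == "offspring").to_numpy() | (ped["role"] == "singleton").to_numpy()
    intercept = _calibrate_intercept(eta[is_off], config.case_fraction_offspring)
    p_aff = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    affected = (rng_pheno.random(len(ped)) < p_aff).astype(int)
    affected[ped["forced_affected"].to_numpy()] = 1
    ped = ped.copy()
    ped["affected"] = affected
    pcs = rng_pheno.standard_normal((len(ped), 10))
    for j in range(10):
        ped[f"PC{j + 1}"] = np.round(pcs[:, j], 4)
    ped = ped.drop(columns=["forced_affected"])

    truth = GroundTruth(
        planted_effects=list(config.planted_effects),
        de_novo_variant_ids=set(
            variants.loc[variants["site_id"].isin(dn_site_set), "variant_id"]
        ),
        intercept=intercept,
        true_burden=truth_burden,
        gene_sets={k: list(v) for k, v in config.gene_sets.items()},
    )
    return SimulatedCohort(ped, variants.drop(columns=["site_id"]), cnvs, genes_df, truth)


def _true_qc_pass(variants):
    v = variants
    base = (
        (v["DP"] >= 20) & (v["GQ"] >= 30)
        & (v["allele_ratio"] >= 0.2) & (v["allele_ratio"] <= 0.8)
        & (v["maf_cohort"] <= 1e-3) & (v["maf_reference"] <= 1e-3)
    )
    cls = v["consequence"].to_numpy()
    rule = np.select(
        [
            np.isin(cls, ("stop_gained", "frameshift")),
            cls == "missense",
            cls == "splice",
        ],
        [
            v["loftee_hc"].astype("boolean").fillna(False).to_numpy(dtype=bool),
            (v["alphamissense"] >= 0.9).to_numpy(),
            (v["spliceai_delta"] >= 0.8).to_numpy(),
        ],
        default=True,
    )
    return (base.to_numpy() & rule)


def _true_burdens(config, ped, passing, cnvs, genes_df, gene_index):
    """Post-QC burden per individual for every planted (set, class)."""
    out = pd.DataFrame(index=ped["individual_id"])
    pass_cnv = cnvs[
        (cnvs["likelihood_score"] >= 30) & ((cnvs["end"] - cnvs["start"]) >= 50_000)
    ] if len(cnvs) else cnvs
    for set_id, vclass, _ in config.planted_effects:
        col = f"{set_id}|{vclass}"
        if col in out.columns:
            continue
        members = set(config.gene_sets[set_id])
        if vclass in SHORT_VARIANT_CLASSES:
            sub = passing[(passing["consequence"] == vclass) & passing["gene"].isin(members)]
            b = sub.groupby("individual_id")["gene"].nunique()
        else:
            want_del = vclass == "deletion"
            rows = []
            for r in pass_cnv.itertuples():
                if (r.copy_number < 2) != want_del:
                    continue
                hits = genes_df[
                    (genes_df["chrom"] == r.chrom)
                    & (genes_df["start"] < r.end) & (genes_df["end"] > r.start)
                ]
                for g in hits["gene"]:
                    if g in members:
                        rows.append((r.individual_id, g))
            b = (
                pd.DataFrame(rows, columns=["individual_id", "gene"])
                .groupby("individual_id")["gene"].nunique()
                if rows else pd.Series(dtype=int)
            )
        out[col] = out.index.map(b).fillna(0).astype(int)
    if not config.planted_effects:
        pass
    return out


def _calibrate_intercept(eta_offspring, target):
    """Bisect the intercept so mean sigmoid(a + eta) over offspring hits target."""
    lo, hi = -25.0, 25.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta_offspring)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
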