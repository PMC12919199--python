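import numpy as np
import pandas as pd
import pytest

from funbat import (
    CohortSimConfig,
    ExpressionSimConfig,
    build_covariates,
    collapse_by_gene,
    label_clusters,
    normalize_cpm_log,
    qc_filter_short_variants,
    simulate_cohort,
    simulate_expression,
)
from funbat.burden import BurdenAssociationModel

GENES = [f"g{i:05d}" for i in range(300)]
TARGET_SET = GENES[:100]


def small_cohort_config(seed, n_families=500, theta=0.0, case_fraction=0.5):
    """Short-variant-only replicate cohort: 300-gene universe, 100-gene target set."""
    rates = {"stop_gained": 1e-3, "frameshift": 1e-3, "splice": 5e-4,
             "missense": 5e-3, "synonymous": 1e-2}
    return CohortSimConfig(
        n_families=n_families,
        n_genes=300,
        per_gene_rate=rates,
        gene_sets={"target": TARGET_SET},
        planted_effects=[("target", "missense", theta)] if theta else [],
        case_fraction_offspring=case_fraction,
        seed=seed,
    )


def fit_cohort(cohort, vclass, gene_set=TARGET_SET):
    """QC -> collapse -> covariates -> one conditional-logistic burden fit."""
    passing, _ = qc_filter_short_variants(cohort.variants)
    collapsed = collapse_by_gene(passing, individuals=cohort.pedigree["individual_id"])
    cov = build_covariates(cohort.pedigree, passing)
    model = BurdenAssociationModel.from_cohort(collapsed, gene_set, vclass, cov)
    return model.fit()


@pytest.fixture(scope="session")
def expr_data():
    """Default synthetic expression matrix (6 clusters, 20 markers each, fold 8)."""
    adata, truth = simulate_expression(ExpressionSimConfig(seed=11))
    adata = normalize_cpm_log(adata)
    labeling = label_clusters(adata.obs, min_cells=50)
    return adata, labeling, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a planted missense effect (theta = 0.5) on the target set."""
    return simulate_cohort(small_cohort_config(seed=71, n_families=800, theta=0.5))


@pytest.fixture(scope="session")
def null_replicates():
    """Null-cohort replicates: per-replicate Wald p for missense and synonymous.

    Shared by the type-I calibration and the p-value uniformity checks so the
    simulations are run once.
    """
    rows = []
    for rep in range(1000):
        cohort = simulate_cohort(small_cohort_config(seed=100_000 + rep, theta=0.0))
        passing, _ = qc_filter_short_variants(cohort.variants)
        collapsed = collapse_by_gene(passing, individuals=cohort.pedigree["individual_id"])
        cov = build_covariates(cohort.pedigree, passing)
        res = {}
        for vclass in ("missense", "synonymous"):
            fit = BurdenAssociationModel.from_cohort(collapsed, TARGET_SET, vclass, cov).fit()
            res[vclass] = fit.p
        rows.append(res)
    return pd.DataFrame(rows)


def toy_qc_table():
    """Six records: five each failing exactly one QC predicate, one clean."""
    base = dict(DP=30, GQ=45, allele_ratio=0.5, maf_cohort=1e-4, maf_reference=1e-4,
                consequence="missense", alphamissense=0.95, spliceai_delta=np.nan,
                loftee_hc=np.nan, gene="gA", individual_id="I1")
    rows = []
    for i, override in enumerate([
        {},                            # survivor
        {"DP": 10},                    # fails depth
        {"GQ": 20},                    # fails genotype quality
        {"allele_ratio": 0.1},         # fails allelic balance
        {"maf_cohort": 5e-3},          # fails cohort frequency
        {"alphamissense": 0.5},        # fails the missense score rule
    ]):
        rows.append({**base, "variant_id": f"v{i}", **override})
    return pd.DataFrame(rows)
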