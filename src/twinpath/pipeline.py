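"""End-to-end orchestration of the pathway-factor analysis.

Stages: fit global confounder factors with technical covariates, regress
them out, filter pathways to those with more than ``min_genes`` genes
present, fit K factors per pathway, test every pathway phenotype for an
age effect with the twin LRT (Bonferroni-controlled), decompose phenotype
variance, and optionally run the single-gene / Fisher-enrichment
comparison and structure-preserving permutations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .association import (
    bonferroni_threshold,
    compare_methods,
    fisher_enrichment,
    pathway_gene_followup,
    pathway_level_p,
    permutation_null_run,
    qq_data,
    single_gene_tests,
    test_all_phenotypes,
)
from .containers import ExpressionMatrix, GeneSetCollection, TwinCohort
from .factor import FactorFit, fit_factor_model, residualize
from .pathways import PathwayPhenotypes, build_pathway_phenotypes, filter_pathways

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    global_fit: FactorFit
    residuals: ExpressionMatrix
    retained_sets: GeneSetCollection
    phenotypes: PathwayPhenotypes
    association: pd.DataFrame
    bonferroni: float
    gene_table: pd.DataFrame | None = None
    gene_followup: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    method_comparison: tuple[float, float] | None = None
    permutation_p: list[np.ndarray] | None = None

    @property
    def n_phenotypes(self) -> int:
        return self.phenotypes.n_phenotypes

    def qq(self) -> pd.DataFrame:
        return qq_data(self.association["p_value"].to_numpy())


def run_pipeline(
    expression: ExpressionMatrix,
    cohort: TwinCohort,
    gene_sets: GeneSetCollection,
    k_global: int = 5,
    k_pathway: int = 5,
    min_genes: int = 10,
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int = 0,
    single_gene: bool = False,
) -> PipelineResult:
    """Run the full analysis on an aligned expression matrix and cohort."""
    cohort = cohort.reindex(expression.sample_ids)
    covariates, _ = cohort.covariate_design()
    logger.info(
        "global stage: %d samples x %d genes, k=%d", expression.n_samples,
        expression.n_genes, k_global,
    )
    global_fit = fit_factor_model(expression, covariates=covariates, k=k_global)
    residuals = residualize(expression, global_fit)

    retained = filter_pathways(gene_sets, residuals, min_genes=min_genes)
    phenotypes = build_pathway_phenotypes(residuals, retained, k=k_pathway)
    association = test_all_phenotypes(phenotypes, cohort, alpha=alpha, decompose=True)
    threshold = bonferroni_threshold(alpha, phenotypes.n_phenotypes)

    result = PipelineResult(
        global_fit=global_fit,
        residuals=residuals,
        retained_sets=retained,
        phenotypes=phenotypes,
        association=association,
        bonferroni=threshold,
    )

    if single_gene:
        gene_table = single_gene_tests(residuals, cohort, alpha=alpha)
        sig = set(gene_table.loc[gene_table["significant_bonferroni"], "gene_id"])
        universe = set(residuals.gene_ids)
        enrichment = fisher_enrichment(sig, retained, universe)
        factor_p = pathway_level_p(association)
        enrich_p = enrichment.set_index("pathway_id")["fisher_p"]
        result.gene_table = gene_table
        result.gene_followup = pathway_gene_followup(gene_table, retained, alpha=alpha)
        result.enrichment = enrichment
        if len(retained) >= 3:
            result.method_comparison = compare_methods(factor_p, enrich_p)

    if n_perm > 0:
        result.permutation_p = permutation_null_run(
            phenotypes, cohort, n_perm=n_perm, seed=seed, alpha=alpha
        )
    return result
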