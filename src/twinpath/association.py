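"""Genome-wide association runs and method comparison.

Phenotype-versus-age tests with Bonferroni control, twin-structure-
preserving permutations, single-gene tests with Bonferroni / BH-FDR,
one-sided Fisher enrichment per pathway, Spearman comparison of the two
discovery routes, and Q-Q coordinates for diagnostic plots.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection, TwinCohort, ValidationError
from .pathways import PathwayPhenotypes
from .streams import stream
from .twin import CohortBlocks, decompose_variance, lrt_age

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def test_all_phenotypes(
    phenotypes: PathwayPhenotypes,
    cohort: TwinCohort,
    alpha: float = DEFAULT_ALPHA,
    decompose: bool = False,
) -> pd.DataFrame:
    """Age LRT for every pathway phenotype, Bonferroni-flagged.

    Rows are ordered by (pathway_id, factor_index). With
    ``decompose=True`` the variance decomposition of the full model is
    appended per phenotype.
    """
    if list(phenotypes.scores.index) != cohort.sample_ids:
        raise ValidationError("phenotype and cohort sample rosters differ")
    blocks = CohortBlocks(cohort)
    n_tests = phenotypes.n_phenotypes
    threshold = bonferroni_threshold(alpha, n_tests)
    rows = []
    for pid, fidx in sorted(phenotypes.phenotype_ids()):
        y = phenotypes.scores[(pid, fidx)].to_numpy()
        if y.var() < 1e-30:
            # fully shrunk factor: constant phenotype carries no age signal
            logger.warning("phenotype (%s, %d) is constant; reported as null", pid, fidx)
            rows.append(
                {
                    "pathway_id": pid,
                    "factor_index": fidx,
                    "beta_age": 0.0,
                    "lrt_stat": 0.0,
                    "p_value": 1.0,
                    "significant_bonferroni": False,
                    "converged": False,
                }
            )
            continue
        res = lrt_age(y, cohort, blocks=blocks)
        row = {
            "pathway_id": pid,
            "factor_index": fidx,
            "beta_age": res.fit_full.beta_age,
            "lrt_stat": res.statistic,
            "p_value": res.p_value,
            "significant_bonferroni": res.p_value < threshold,
            "converged": res.converged,
        }
        if decompose:
            dec = decompose_variance(res.fit_full, cohort)
            row.update(
                h2=dec.h2,
                c2=dec.c2,
                e2=dec.e2,
                age_share_total=dec.age_share_total,
                age_share_env=dec.age_share_env,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info(
        "tested %d phenotypes; %d significant at Bonferroni %.3g",
        n_tests,
        int(table["significant_bonferroni"].sum()),
        threshold,
    )
    return table


def permute_cohort(cohort: TwinCohort, seed: int) -> TwinCohort:
    """Structure-preserving permutation of the cohort.

    (age, family identity) assignments are shuffled among family units
    within each stratum — MZ pairs with MZ pairs, DZ pairs with DZ pairs,
    singletons with singletons — so twin pairs stay together, zygosity
    labels and the multiset of ages are unchanged, and only the
    phenotype-to-age pairing is broken.
    """
    rng = stream(seed, "permutation")
    df = cohort.samples.copy()
    units = cohort.family_units()
    for zyg in ("MZ", "DZ", "singleton"):
        stratum = units[zyg]
        if len(stratum) < 2:
            continue
        perm = rng.permutation(len(stratum))
        fam_age = [
            (
                df.loc[stratum[j][0], "family_id"],
                df.loc[stratum[j][0], "age"],
            )
            for j in perm
        ]
        for unit, (fam, age) in zip(stratum, fam_age):
            for sid in unit:
                df.loc[sid, "family_id"] = fam
                df.loc[sid, "age"] = age
    return TwinCohort(df)


def permutation_null_run(
    phenotypes: PathwayPhenotypes,
    cohort: TwinCohort,
    n_perm: int = 10,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> list[np.ndarray]:
    """Re-run the phenotype-age tests on ``n_perm`` permuted cohorts.

    Returns one p-value array per permutation; pooled, they form the
    empirical null for Q-Q display.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    out = []
    for i in range(n_perm):
        permuted = permute_cohort(cohort, seed=int(stream(seed, "perm", i).integers(2**31)))
        table = test_all_phenotypes(phenotypes, permuted, alpha=alpha)
        out.append(table["p_value"].to_numpy())
    return out


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def single_gene_tests(
    residuals: ExpressionMatrix,
    cohort: TwinCohort,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene age LRT with Bonferroni flags and BH-FDR q-values."""
    if residuals.sample_ids != cohort.sample_ids:
        raise ValidationError("expression and cohort sample rosters differ")
    blocks = CohortBlocks(cohort)
    n_genes = residuals.n_genes
    threshold = bonferroni_threshold(alpha, n_genes)
    values = residuals.values
    rows = []
    for j, gene in enumerate(residuals.gene_ids):
        res = lrt_age(values[:, j], cohort, blocks=blocks)
        rows.append(
            {
                "gene_id": gene,
                "beta_age": res.fit_full.beta_age,
                "lrt_stat": res.statistic,
                "p_value": res.p_value,
                "significant_bonferroni": res.p_value < threshold,
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_qvalues(table["p_value"].to_numpy())
    return table


def pathway_gene_followup(
    gene_table: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Count age-associated genes per pathway at a within-pathway
    Bonferroni threshold (alpha / number of genes in the pathway)."""
    pvals = gene_table.set_index("gene_id")["p_value"]
    rows = []
    for s in sets:
        member_p = pvals.reindex([g for g in s.genes if g in pvals.index]).dropna()
        cut = bonferroni_threshold(alpha, len(s.genes))
        rows.append(
            {
                "pathway_id": s.set_id,
                "n_genes": len(s.genes),
                "n_age_associated": int((member_p < cut).sum()),
            }
        )
    return pd.DataFrame(rows)


def fisher_enrichment(
    sig_genes: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment per pathway.

    Tests whether the proportion of significant genes within the pathway
    exceeds what chance would produce, against the given gene universe.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    if not sig_genes <= universe:
        raise ValidationError("significant genes must be a subset of the universe")
    rows = []
    n_universe = len(universe)
    n_sig = len(sig_genes)
    for s in sets:
        members = set(s.genes) & universe
        in_sig = len(members & sig_genes)
        in_non = len(members) - in_sig
        out_sig = n_sig - in_sig
        out_non = (n_universe - len(members)) - out_sig
        _, p = fisher_exact(
            [[in_sig, in_non], [out_sig, out_non]], alternative="greater"
        )
        rows.append(
            {
                "pathway_id": s.set_id,
                "n_genes": len(members),
                "n_significant_genes": in_sig,
                "universe_size": n_universe,
                "universe_significant": n_sig,
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def pathway_level_p(
    table: pd.DataFrame, method: str = "min"
) -> pd.Series:
    """Reduce a phenotype association table to one p-value per pathway.

    ``min`` takes the smallest of the pathway's factor p-values; ``sidak``
    additionally corrects it for the number of factors.
    """
    grouped = table.groupby("pathway_id")["p_value"]
    if method == "min":
        return grouped.min()
    if method == "sidak":
        return grouped.agg(lambda p: 1.0 - (1.0 - p.min()) ** len(p))
    raise ValidationError(f"unknown reduction {method!r}")


def compare_methods(
    pathway_factor_p: pd.Series, enrichment_p: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) between per-pathway
    p-values from the factor and enrichment routes."""
    shared = sorted(set(pathway_factor_p.index) & set(enrichment_p.index))
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared pathways to compare")
    rho, p = spearmanr(
        pathway_factor_p.loc[shared].to_numpy(), enrichment_p.loc[shared].to_numpy()
    )
    return float(rho), float(p)


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot.

    Observed p-values sorted ascending are paired with i/(n+1) uniform
    quantiles.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    observed = np.sort(p, kind="stable")
    expected = np.arange(1, p.size + 1) / (p.size + 1.0)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(observed),
        }
    )
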