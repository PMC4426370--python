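"""Self-contained validation experiments.

Each function builds its own synthetic inputs from a seed, runs one part
of the pipeline, and returns summary metrics. They back the package's
validation suite and the reproduction script: likelihood and enrichment
oracles, estimator calibration and recovery, the end-to-end pipeline
shape, and the variance-source comparison between pathway phenotypes and
single genes.

Problem sizes are chosen to finish in minutes on one core while keeping
Monte-Carlo error well inside the tolerances they are checked against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles
from scipy.stats import fisher_exact, hypergeom, multivariate_normal

from .association import (
    bonferroni_threshold,
    compare_methods,
    fisher_enrichment,
    pathway_level_p,
    permute_cohort,
)
from .containers import ExpressionMatrix, TwinCohort
from .factor import fit_factor_model
from .pathways import build_pathway_phenotypes, filter_pathways
from .pipeline import run_pipeline
from .simulate import (
    CohortSpec,
    generate_cohort,
    generate_expression,
    make_truth,
    simulate_ace_phenotype,
    simulate_twin_model_phenotype,
)
from .streams import stream
from .twin import CohortBlocks, decompose_variance, fit_twin_model, lrt_age, twin_loglik


# ---------------------------------------------------------------------------
# end-to-end pipeline shape
# ---------------------------------------------------------------------------

def pipeline_shape(seed: int) -> dict[str, float]:
    """Full-size pipeline run: 200 gene sets of which 186 pass the
    more-than-10-genes filter, five factors each, every phenotype tested.

    Cohort: 100 MZ + 100 DZ pairs; ~5,600 genes in 186 pathways of 20-40
    genes plus 14 undersized sets; three pathways age-responsive.
    """
    cohort = generate_cohort(CohortSpec(n_mz_pairs=100, n_dz_pairs=100, seed=seed))
    truth = make_truth(
        cohort,
        n_genes=3000,
        n_pathways=186,
        pathway_size_range=(20, 40),
        n_small_pathways=14,
        seed=seed,
    )
    matrix = generate_expression(cohort, truth)
    result = run_pipeline(matrix, cohort, truth.gene_sets(), single_gene=False)
    sig = result.association[result.association["significant_bonferroni"]]
    found = set(sig["pathway_id"]) & set(truth.age_pathways)
    return {
        "n_gene_sets_input": float(len(truth.pathway_members)),
        "n_pathways_retained": float(len(result.retained_sets)),
        "n_phenotypes_tested": float(result.n_phenotypes),
        "bonferroni_threshold": result.bonferroni,
        "global_variance_explained_pct": 100.0 * result.global_fit.variance_explained_total,
        "mean_pathway_variance_explained_pct": float(
            100.0 * result.phenotypes.summary["variance_explained"].mean()
        ),
        "n_significant_phenotypes": float(len(sig)),
        "n_planted_pathways_recovered": float(len(found)),
    }


# ---------------------------------------------------------------------------
# twin likelihood oracle
# ---------------------------------------------------------------------------

def _random_small_cohort(rng: np.random.Generator) -> TwinCohort:
    rows = []
    n = 0
    fam = 0
    while n < 12:
        zyg = rng.choice(["MZ", "DZ", "singleton"])
        members = 1 if zyg == "singleton" else 2
        if n + members > 12:
            break
        fam += 1
        age = float(rng.uniform(39, 85))
        for _ in range(members):
            n += 1
            rows.append((f"s{n}", f"i{n}", f"fam{fam}", zyg, age))
        if fam >= 3 and rng.random() < 0.3:
            break
    df = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "family_id", "zygosity", "age"]
    ).set_index("sample_id")
    df["batch"] = "B1"
    df["rna_quality"] = 8.0
    df["rna_concentration"] = 100.0
    return TwinCohort(df)


def _dense_cov(cohort: TwinCohort, sp: float, sm: float, se: float) -> np.ndarray:
    n = cohort.n_individuals
    V = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    for zyg, units in cohort.family_units().items():
        for unit in units:
            idx = [pos[s] for s in unit]
            extra = sm if zyg == "MZ" else 0.0
            for i in idx:
                V[i, i] = sp + se + extra
            if len(idx) == 2:
                V[idx[0], idx[1]] = V[idx[1], idx[0]] = sp + extra
    return V


def twin_loglik_oracle(seed: int, n_draws: int = 1000) -> dict[str, float]:
    """Block likelihood vs a dense multivariate-normal density on random
    cohorts of at most 12 individuals; returns the worst absolute error."""
    rng = stream(seed, "loglik-oracle")
    max_err = 0.0
    for _ in range(n_draws):
        cohort = _random_small_cohort(rng)
        y = rng.normal(size=cohort.n_individuals)
        b0, ba = rng.normal(size=2)
        sp, sm = rng.uniform(0, 2, size=2)
        se = rng.uniform(0.1, 2)
        ll = twin_loglik(y, cohort, b0, ba, sp, sm, se)
        oracle = multivariate_normal.logpdf(
            y, mean=b0 + ba * cohort.ages, cov=_dense_cov(cohort, sp, sm, se)
        )
        max_err = max(max_err, abs(ll - oracle))
    return {"max_abs_loglik_error": float(max_err), "n_draws": float(n_draws)}


# ---------------------------------------------------------------------------
# heritability recovery and LRT calibration
# ---------------------------------------------------------------------------

#: generating parameters (sigma2_pair, sigma2_mz_extra, sigma2_resid) of the
#: nested twin model, total variance 1, for each target heritability
H2_RECOVERY_CONFIGS: dict[float, tuple[float, float, float]] = {
    0.0: (0.0, 0.0, 1.0),
    0.3: (0.45, 0.15, 0.40),
    0.6: (0.50, 0.30, 0.20),
}


def heritability_recovery(seed: int, n_reps: int = 200) -> dict[float, float]:
    """Mean estimated h2 over replicate phenotypes drawn from the nested
    twin model at true h2 in {0, 0.3, 0.6}; 250 MZ + 250 DZ pairs."""
    cohort = generate_cohort(CohortSpec(n_mz_pairs=250, n_dz_pairs=250, seed=seed))
    blocks = CohortBlocks(cohort)
    out: dict[float, float] = {}
    for h2_true, (sp, sm, se) in H2_RECOVERY_CONFIGS.items():
        rng = stream(seed, "h2-recovery", h2_true)
        estimates = []
        for _ in range(n_reps):
            y = simulate_twin_model_phenotype(cohort, sp, sm, se, rng=rng)
            fit = fit_twin_model(y, cohort, blocks=blocks)
            estimates.append(decompose_variance(fit, cohort).h2)
        out[h2_true] = float(np.mean(estimates))
    return out


def lrt_calibration(
    seed: int, n_reps: int = 2000, alpha: float = 0.05
) -> dict[str, float]:
    """Type-I error of the age LRT on null twin phenotypes (ACE structure
    a=0.3, c=0.2, e=0.5, no age effect); 250 MZ + 250 DZ pairs."""
    cohort = generate_cohort(CohortSpec(n_mz_pairs=250, n_dz_pairs=250, seed=seed))
    blocks = CohortBlocks(cohort)
    rng = stream(seed, "lrt-calibration")
    rejections = 0
    for _ in range(n_reps):
        y = simulate_ace_phenotype(cohort, 0.3, 0.2, 0.5, rng=rng)
        rejections += lrt_age(y, cohort, blocks=blocks).p_value < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": float(n_reps)}


# ---------------------------------------------------------------------------
# variance-source comparison: pathway phenotypes vs genes
# ---------------------------------------------------------------------------

def variance_source_ordering(seed: int, n_reps: int = 50) -> dict[str, float]:
    """Replicated comparison of variance sources between pathway factor
    phenotypes and their constituent genes on modular twin data.

    Each replicate: 350 MZ + 350 DZ pairs, 16 pathways of 20-30 genes with
    a heritable co-expression module on 30% of members; five factors per
    pathway; h2 and unique-environment share estimated for every phenotype
    and every member gene. Reports how often phenotypes show higher mean
    h2 and lower mean unique-environment share than genes. The cohort and
    pathway counts keep the Monte-Carlo error of the within-replicate
    means (and the boundary-truncation bias of near-zero heritability
    estimates) small against the expected ordering margins.
    """
    both_ordered = 0
    h2_p, h2_g, e2_p, e2_g = [], [], [], []
    for rep in range(n_reps):
        rep_seed = int(stream(seed, "ordering", rep).integers(2**31))
        cohort = generate_cohort(
            CohortSpec(n_mz_pairs=350, n_dz_pairs=350, seed=rep_seed)
        )
        truth = make_truth(
            cohort,
            n_genes=500,
            n_pathways=16,
            pathway_size_range=(20, 30),
            k_global=0,
            global_share=0.0,
            n_age_pathways=0,
            seed=rep_seed,
        )
        matrix = generate_expression(cohort, truth)
        sets = filter_pathways(truth.gene_sets(), matrix, min_genes=10)
        phen = build_pathway_phenotypes(matrix, sets, k=5)
        blocks = CohortBlocks(cohort)

        def _decomp(values: np.ndarray) -> tuple[float, float]:
            fit = fit_twin_model(values, cohort, blocks=blocks)
            dec = decompose_variance(fit, cohort)
            return dec.h2, dec.e2

        ph = [_decomp(phen.scores[col].to_numpy()) for col in phen.scores.columns]
        member_genes = sorted({g for s in sets for g in s.genes})
        sub = matrix.subset_genes(member_genes).values
        ge = [_decomp(sub[:, j]) for j in range(sub.shape[1])]

        h2_phen, e2_phen = (float(np.mean(x)) for x in zip(*ph))
        h2_gene, e2_gene = (float(np.mean(x)) for x in zip(*ge))
        h2_p.append(h2_phen)
        h2_g.append(h2_gene)
        e2_p.append(e2_phen)
        e2_g.append(e2_gene)
        both_ordered += (h2_phen > h2_gene) and (e2_phen < e2_gene)
    return {
        "fraction_replicates_ordered": both_ordered / n_reps,
        "mean_h2_pathway_phenotypes": float(np.mean(h2_p)),
        "mean_h2_genes": float(np.mean(h2_g)),
        "mean_e2_pathway_phenotypes": float(np.mean(e2_p)),
        "mean_e2_genes": float(np.mean(e2_g)),
        "n_reps": float(n_reps),
    }


# ---------------------------------------------------------------------------
# factor-model oracles
# ---------------------------------------------------------------------------

def factor_model_oracles(seed: int) -> dict[str, float]:
    """Flat-prior fit vs truncated SVD, and planted rank-1 recovery."""
    rng = stream(seed, "factor-oracle")
    Y = ExpressionMatrix.from_arrays(
        rng.standard_normal((50, 80)),
        [f"s{i}" for i in range(50)],
        [f"g{j}" for j in range(80)],
    )
    fit = fit_factor_model(Y, k=3, ard=False, shared_noise=True, tol=1e-10)
    Yc = Y.values - Y.values.mean(axis=0)
    U = np.linalg.svd(Yc, full_matrices=False)[0]
    max_angle = float(subspace_angles(fit.scores, U[:, :3]).max())

    x = rng.standard_normal(120)
    w = rng.standard_normal(40)
    Y1 = ExpressionMatrix.from_arrays(
        np.outer(x, w), [f"s{i}" for i in range(120)], [f"g{j}" for j in range(40)]
    )
    fit1 = fit_factor_model(Y1, k=1, ard=False)
    r = float(abs(np.corrcoef(fit1.scores[:, 0], x)[0, 1]))
    return {"ppca_svd_max_principal_angle_rad": max_angle, "rank1_recovery_abs_corr": r}


# ---------------------------------------------------------------------------
# permutation invariants
# ---------------------------------------------------------------------------

def permutation_invariants(seed: int) -> dict[str, float]:
    """Exact invariants of the structure-preserving permutation plus the
    enumeration of the permutation group on a 2-MZ + 2-DZ cohort."""
    cohort = generate_cohort(
        CohortSpec(n_mz_pairs=30, n_dz_pairs=30, n_singletons=10, seed=seed)
    )
    ok = 1.0
    for perm_seed in range(20):
        permuted = permute_cohort(cohort, seed=perm_seed)
        permuted.validate()  # pairs intact, co-twin ages equal
        if sorted(permuted.ages) != sorted(cohort.ages):
            ok = 0.0
        if permuted.zygosity_counts() != cohort.zygosity_counts():
            ok = 0.0
        if (permuted.samples["zygosity"] != cohort.samples["zygosity"]).any():
            ok = 0.0

    tiny = generate_cohort(CohortSpec(n_mz_pairs=2, n_dz_pairs=2, seed=seed))
    df = tiny.samples.copy()
    df["age"] = [40.0, 40.0, 50.0, 50.0, 60.0, 60.0, 70.0, 70.0]
    tiny = TwinCohort(df)
    seen = {tuple(permute_cohort(tiny, seed=s).ages) for s in range(200)}
    within_strata = all(
        sorted(ages[:4]) == [40.0, 40.0, 50.0, 50.0]
        and sorted(ages[4:]) == [60.0, 60.0, 70.0, 70.0]
        for ages in seen
    )
    return {
        "invariants_hold": ok,
        "n_distinct_assignments_2mz_2dz": float(len(seen)),
        "assignments_within_strata": 1.0 if within_strata else 0.0,
    }


# ---------------------------------------------------------------------------
# Fisher enrichment oracle
# ---------------------------------------------------------------------------

def fisher_oracle(seed: int, n_tables: int = 100) -> dict[str, float]:
    """One-sided Fisher exact p vs direct hypergeometric upper-tail sums
    on random 2x2 tables."""
    rng = stream(seed, "fisher-oracle")
    max_err = 0.0
    for _ in range(n_tables):
        N = int(rng.integers(50, 2000))
        K = int(rng.integers(1, N // 2))
        n = int(rng.integers(1, N // 2))
        k = int(rng.integers(0, min(K, n) + 1))
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = fisher_exact(table, alternative="greater")
        oracle = float(hypergeom.sf(k - 1, N, K, n))
        max_err = max(max_err, abs(p - oracle))
    return {"max_abs_p_error": float(max_err), "n_tables": float(n_tables)}


# ---------------------------------------------------------------------------
# method comparison on planted data
# ---------------------------------------------------------------------------

def method_comparison(seed: int) -> dict[str, float]:
    """Factor route vs single-gene Fisher enrichment on planted data:
    Spearman concordance of per-pathway p-values and the containment of
    enrichment hits in factor hits."""
    cohort = generate_cohort(CohortSpec(n_mz_pairs=120, n_dz_pairs=120, seed=seed))
    truth = make_truth(
        cohort,
        n_genes=300,
        n_pathways=10,
        pathway_size_range=(14, 22),
        n_age_pathways=3,
        seed=seed,
    )
    matrix = generate_expression(cohort, truth)
    result = run_pipeline(matrix, cohort, truth.gene_sets(), single_gene=True)
    factor_p = pathway_level_p(result.association)
    enrich_p = result.enrichment.set_index("pathway_id")["fisher_p"]
    rho, p = compare_methods(factor_p, enrich_p)
    n_pathways = len(result.retained_sets)
    factor_sig = set(
        result.association.loc[
            result.association["significant_bonferroni"], "pathway_id"
        ]
    )
    enrich_sig = set(
        result.enrichment.loc[
            result.enrichment["fisher_p"] < 0.05 / n_pathways, "pathway_id"
        ]
    )
    return {
        "spearman_rho": rho,
        "spearman_p": p,
        "enrichment_hits_contained_in_factor_hits": 1.0
        if enrich_sig <= factor_sig
        else 0.0,
        "n_factor_significant_pathways": float(len(factor_sig)),
        "n_enrichment_significant_pathways": float(len(enrich_sig)),
    }


def bonferroni_headline() -> dict[str, float]:
    """The family-wise threshold for the pipeline's 930 phenotype tests."""
    return {
        "threshold_930_tests": bonferroni_threshold(0.05, 930),
        "threshold_9300_tests": bonferroni_threshold(0.05, 9300),
    }
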