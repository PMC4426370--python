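import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from twinpath import (
    build_pathway_phenotypes,
    filter_pathways,
    generate_expression,
    make_truth,
    run_pipeline,
)
from twinpath.association import (
    bh_qvalues,
    bonferroni_threshold,
    compare_methods,
    fisher_enrichment,
    pathway_gene_followup,
    permutation_null_run,
    permute_cohort,
    qq_data,
    single_gene_tests,
)
from twinpath.association import test_all_phenotypes as run_age_tests
from twinpath.containers import GeneSet, GeneSetCollection, TwinCohort, ValidationError
from twinpath.simulate import CohortSpec, generate_cohort


class TestBonferroniThreshold:
    def test_headline_phenotype_count(self):
        t = bonferroni_threshold(0.05, 930)
        assert t == pytest.approx(5.376e-5, rel=1e-3)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_ten_permutation_pool(self):
        assert bonferroni_threshold(0.05, 9300) == pytest.approx(5.376e-6, rel=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_threshold(1.5, 10)


@pytest.fixture(scope="module")
def planted_run():
    """Shared pipeline run on planted data: 10 pathways, 3 age-responsive."""
    cohort = generate_cohort(CohortSpec(n_mz_pairs=120, n_dz_pairs=120, seed=50))
    truth = make_truth(
        cohort, n_genes=300, n_pathways=10, pathway_size_range=(14, 22),
        n_age_pathways=3, seed=50,
    )
    matrix = generate_expression(cohort, truth)
    result = run_pipeline(matrix, cohort, truth.gene_sets(), single_gene=True)
    return cohort, truth, result


class TestTestAllPhenotypes:
    def test_row_count_and_order(self, planted_run):
        cohort, truth, result = planted_run
        table = result.association
        assert len(table) == 50
        expected_order = sorted(
            zip(table["pathway_id"], table["factor_index"])
        )
        assert list(zip(table["pathway_id"], table["factor_index"])) == expected_order

    def test_planted_pathways_flagged(self, planted_run):
        cohort, truth, result = planted_run
        sig = result.association[result.association["significant_bonferroni"]]
        for pid in truth.age_pathways:
            assert pid in set(sig["pathway_id"])
        false_flags = set(sig["pathway_id"]) - set(truth.age_pathways)
        assert len(false_flags) == 0

    def test_deterministic_rerun(self, planted_run):
        cohort, truth, result = planted_run
        rerun = run_age_tests(result.phenotypes, cohort, decompose=True)
        pd.testing.assert_frame_equal(rerun, result.association)

    def test_misaligned_samples_rejected(self, planted_run):
        cohort, truth, result = planted_run
        renamed = cohort.samples.copy()
        renamed.index = [f"x_{s}" for s in renamed.index]
        with pytest.raises(ValidationError):
            run_age_tests(result.phenotypes, TwinCohort(renamed))


class TestPermuteCohort:
    def test_single_singleton_identity(self):
        cohort = generate_cohort(
            CohortSpec(n_mz_pairs=0, n_dz_pairs=0, n_singletons=1, seed=0)
        )
        permuted = permute_cohort(cohort, seed=3)
        pd.testing.assert_frame_equal(permuted.samples, cohort.samples)

    def test_structure_invariants(self, small_cohort):
        permuted = permute_cohort(small_cohort, seed=9)
        assert sorted(permuted.ages) == pytest.approx(sorted(small_cohort.ages))
        assert permuted.zygosity_counts() == small_cohort.zygosity_counts()
        # co-twins still share one age and pairs are intact
        permuted.validate()
        assert list(permuted.samples.index) == list(small_cohort.samples.index)
        # zygosity labels never move between samples
        assert (
            permuted.samples["zygosity"] == small_cohort.samples["zygosity"]
        ).all()

    def test_tiny_cohort_enumerates_within_stratum_group(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=2, n_dz_pairs=2, seed=1))
        # make unit ages distinct so assignments are distinguishable
        df = cohort.samples.copy()
        df["age"] = [40.0, 40.0, 50.0, 50.0, 60.0, 60.0, 70.0, 70.0]
        cohort = TwinCohort(df)
        seen = set()
        for seed in range(200):
            permuted = permute_cohort(cohort, seed=seed)
            seen.add(tuple(permuted.ages))
        # 2 MZ orders x 2 DZ orders; MZ ages never swap with DZ ages
        assert len(seen) == 4
        for ages in seen:
            assert sorted(ages[:4]) == [40.0, 40.0, 50.0, 50.0]
            assert sorted(ages[4:]) == [60.0, 60.0, 70.0, 70.0]

    def test_deterministic_given_seed(self, small_cohort):
        a = permute_cohort(small_cohort, seed=17)
        b = permute_cohort(small_cohort, seed=17)
        pd.testing.assert_frame_equal(a.samples, b.samples)


class TestPermutationNullRun:
    def test_signal_destroyed_by_permutation(self, planted_run):
        cohort, truth, result = planted_run
        threshold = result.bonferroni
        p_sets = permutation_null_run(
            result.phenotypes, cohort, n_perm=10, seed=99
        )
        lost = sum(min(p) > threshold for p in p_sets)
        assert lost >= 9

    def test_pooled_null_p_values_uniform(self):
        # null data: no age effect anywhere, 20 disjoint pathways -> 1000
        # pooled p-values (disjoint sets keep the pool nearly independent)
        cohort = generate_cohort(CohortSpec(n_mz_pairs=120, n_dz_pairs=120, seed=60))
        truth = make_truth(
            cohort, n_genes=300, n_pathways=20, pathway_size_range=(12, 15),
            loader_fraction=1.0, k_global=0, global_share=0.0,
            n_age_pathways=0, seed=60,
        )
        matrix = generate_expression(cohort, truth)
        sets = filter_pathways(truth.gene_sets(), matrix, min_genes=10)
        phen = build_pathway_phenotypes(matrix, sets, k=5)
        p_sets = permutation_null_run(phen, cohort, n_perm=10, seed=7)
        pooled = np.concatenate(p_sets)
        assert len(pooled) == 1000
        assert kstest(pooled, "uniform").statistic < 0.05

    def test_reproducible(self, planted_run):
        cohort, truth, result = planted_run
        a = permutation_null_run(result.phenotypes, cohort, n_perm=1, seed=5)
        b = permutation_null_run(result.phenotypes, cohort, n_perm=1, seed=5)
        np.testing.assert_array_equal(a[0], b[0])


class TestSingleGeneTests:
    def test_bh_stepup_hand_example(self):
        np.testing.assert_allclose(
            bh_qvalues(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04]
        )

    def test_duplicated_gene_gives_identical_p(self, planted_run):
        cohort, truth, result = planted_run
        sub = result.residuals.data.iloc[:, :3].copy()
        sub["dup"] = sub.iloc[:, 0]
        from twinpath import ExpressionMatrix

        matrix = ExpressionMatrix(sub)
        table = single_gene_tests(matrix, cohort).set_index("gene_id")
        assert (
            table.loc[sub.columns[0], "p_value"] == table.loc["dup", "p_value"]
        )

    def test_planted_genes_enrich_their_pathways(self, planted_run):
        cohort, truth, result = planted_run
        table = result.gene_table.set_index("gene_id")
        age_genes = [g for g, b in truth.age_effect_sizes.items() if b != 0]
        null_genes = [g for g, b in truth.age_effect_sizes.items() if b == 0]
        assert table.loc[age_genes, "p_value"].median() < table.loc[
            null_genes, "p_value"
        ].median()

    def test_followup_uses_within_pathway_bonferroni(self, planted_run):
        cohort, truth, result = planted_run
        followup = pathway_gene_followup(
            result.gene_table, result.retained_sets
        ).set_index("pathway_id")
        pvals = result.gene_table.set_index("gene_id")["p_value"]
        pid = truth.age_pathways[0]
        members = result.retained_sets[pid].genes
        expected = int(
            (pvals.loc[list(members)] < 0.05 / len(members)).sum()
        )
        assert followup.loc[pid, "n_age_associated"] == expected


class TestFisherEnrichment:
    def _universe(self, n):
        return {f"g{j}" for j in range(n)}

    def test_no_significant_genes_gives_p_one(self):
        universe = self._universe(100)
        sets = GeneSetCollection([GeneSet("p0", "", tuple(sorted(universe)[:20]))])
        table = fisher_enrichment(set(), sets, universe)
        assert table["fisher_p"].iloc[0] == 1.0

    def test_matches_hypergeometric_tail_sum(self):
        # 2x2 table: in-set sig 5 / 15, out-set sig 95 / 885
        universe = self._universe(1000)
        members = sorted(universe)[:20]
        sig = set(members[:5]) | set(sorted(universe)[500:595])
        sets = GeneSetCollection([GeneSet("p0", "", tuple(members))])
        table = fisher_enrichment(sig, sets, universe)
        # hypergeometric upper tail: P(X >= 5) drawing 20 from 1000 with 100 sig
        oracle = hypergeom.sf(4, 1000, 100, 20)
        assert table["fisher_p"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_pathway_equal_to_universe_gives_p_one(self):
        universe = self._universe(50)
        sets = GeneSetCollection([GeneSet("all", "", tuple(sorted(universe)))])
        table = fisher_enrichment(set(list(universe)[:10]), sets, universe)
        assert table["fisher_p"].iloc[0] == 1.0

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection([GeneSet("p0", "", ("g1",))])
        with pytest.raises(ValidationError):
            fisher_enrichment(set(), sets, set())


class TestCompareMethods:
    def test_identical_rankings(self):
        p = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        rho, _ = compare_methods(p, p)
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        p = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        rho, _ = compare_methods(p, p.iloc[::-1].set_axis(list("abcd")))
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        a = pd.Series([1, 2, 3, 4, 5], index=list("abcde"), dtype=float)
        b = pd.Series([2, 1, 4, 3, 5], index=list("abcde"), dtype=float)
        rho, _ = compare_methods(a, b)
        assert rho == pytest.approx(0.8)

    def test_too_few_pathways_rejected(self):
        p = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValidationError):
            compare_methods(p, p)

    def test_enrichment_contained_in_factor_hits(self, planted_run):
        cohort, truth, result = planted_run
        factor_sig = set(
            result.association.loc[
                result.association["significant_bonferroni"], "pathway_id"
            ]
        )
        n_pathways = len(result.retained_sets)
        enrich_sig = set(
            result.enrichment.loc[
                result.enrichment["fisher_p"] < 0.05 / n_pathways, "pathway_id"
            ]
        )
        assert enrich_sig <= factor_sig


class TestQqData:
    def test_single_median_point(self):
        out = qq_data(np.array([0.5]))
        assert out["expected_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))
        assert out["observed_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            qq_data(np.array([0.5, 0.0]))
        with pytest.raises(ValidationError):
            qq_data(np.array([1.5]))

    def test_duplicated_input_stable(self):
        p = np.array([0.2, 0.2, 0.8])
        a = qq_data(p)
        b = qq_data(np.array([0.8, 0.2, 0.2]))
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_sample_tracks_diagonal(self):
        rng = np.random.default_rng(0)
        out = qq_data(rng.uniform(size=1000))
        gap = np.abs(
            10 ** -out["observed_neglog10"] - 10 ** -out["expected_neglog10"]
        )
        assert gap.max() < 0.052  # 99% KS band at n=1000
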