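import numpy as np
import pandas as pd
import pytest

from twinpath import CohortSpec, generate_cohort, generate_expression, make_truth
from twinpath.containers import ValidationError
from twinpath.simulate import (
    module_scores,
    permute_genes,
    simulate_ace_phenotype,
    simulate_twin_model_phenotype,
)
from twinpath.streams import stream


def _pair_corr(matrix, cohort, zygosity):
    """Empirical co-twin correlation pooled over gene-centered values."""
    units = cohort.family_units()[zygosity]
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    i1 = [pos[a] for a, b in units]
    i2 = [pos[b] for a, b in units]
    centered = matrix.values - matrix.values.mean(axis=0)
    x = centered[i1].ravel()
    y = centered[i2].ravel()
    return np.corrcoef(x, y)[0, 1]


class TestGenerateCohort:
    def test_full_scale_roster_counts(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=168, n_dz_pairs=260, seed=0))
        assert cohort.n_individuals == 856
        counts = cohort.zygosity_counts()
        assert counts == {"MZ": 336, "DZ": 520, "singleton": 0}

    def test_single_singleton(self):
        cohort = generate_cohort(
            CohortSpec(n_mz_pairs=0, n_dz_pairs=0, n_singletons=1, seed=0)
        )
        assert cohort.n_individuals == 1
        assert cohort.samples["zygosity"].iloc[0] == "singleton"
        assert cohort.n_families == 1

    def test_determinism(self):
        spec = CohortSpec(n_mz_pairs=20, n_dz_pairs=30, n_singletons=5, seed=7)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_cotwins_share_age_and_family(self, small_cohort):
        for zyg in ("MZ", "DZ"):
            for unit in small_cohort.family_units()[zyg]:
                ages = small_cohort.samples.loc[list(unit), "age"]
                fams = small_cohort.samples.loc[list(unit), "family_id"]
                assert ages.nunique() == 1
                assert fams.nunique() == 1

    def test_age_distribution_steered_to_target(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=300, n_dz_pairs=300, seed=1))
        ages = cohort.ages
        assert abs(ages.mean() - 59.0) < 1.0
        assert ages.min() >= 39.0 and ages.max() <= 85.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mz_pairs": -1},
            {"n_mz_pairs": 0, "n_dz_pairs": 0, "n_singletons": 0},
            {"age_mean_target": 20.0},
            {"age_sd": 0.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            generate_cohort(CohortSpec(seed=0, **kwargs))


class TestGenerateExpression:
    def test_pure_noise_has_no_twin_covariance(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=200, n_dz_pairs=200, seed=3))
        truth = make_truth(
            cohort,
            n_genes=40,
            n_pathways=0,
            k_global=0,
            global_share=0.0,
            specific_ace=(0.0, 0.0, 1.0),
            n_age_pathways=0,
            seed=3,
        )
        m = generate_expression(cohort, truth)
        assert abs(_pair_corr(m, cohort, "MZ")) < 0.1
        assert abs(_pair_corr(m, cohort, "DZ")) < 0.1

    def test_ace_twin_correlations_match_closed_form(self):
        # rMZ = vA + vC, rDZ = vA/2 + vC for unit-variance genes
        cohort = generate_cohort(CohortSpec(n_mz_pairs=500, n_dz_pairs=500, seed=4))
        truth = make_truth(
            cohort,
            n_genes=60,
            n_pathways=0,
            k_global=0,
            global_share=0.0,
            specific_ace=(0.6, 0.2, 0.2),
            n_age_pathways=0,
            seed=4,
        )
        m = generate_expression(cohort, truth)
        assert _pair_corr(m, cohort, "MZ") == pytest.approx(0.8, abs=0.05)
        assert _pair_corr(m, cohort, "DZ") == pytest.approx(0.5, abs=0.05)

    def test_mz_covariance_at_least_dz_when_genetic(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=400, n_dz_pairs=400, seed=5))
        truth = make_truth(
            cohort,
            n_genes=50,
            n_pathways=0,
            k_global=0,
            global_share=0.0,
            specific_ace=(0.5, 0.1, 0.4),
            n_age_pathways=0,
            seed=5,
        )
        m = generate_expression(cohort, truth)
        # pooled over genes with 3-MC-SE slack
        r_mz = _pair_corr(m, cohort, "MZ")
        r_dz = _pair_corr(m, cohort, "DZ")
        mc_se = 1.0 / np.sqrt(400 * 50)
        assert r_mz >= r_dz - 3 * mc_se

    def test_planted_age_slope_recovered_by_ols(self):
        cohort = generate_cohort(CohortSpec(n_mz_pairs=250, n_dz_pairs=250, seed=6))
        truth = make_truth(
            cohort,
            n_genes=5,
            n_pathways=0,
            k_global=0,
            global_share=0.0,
            specific_ace=(0.0, 0.0, 1.0),
            n_age_pathways=0,
            seed=6,
        )
        truth.age_effect_sizes["G0001"] = 0.02
        truth.variance_fractions["G0001"] = (0.0, 0.0, 0.01)
        m = generate_expression(cohort, truth)
        ages = cohort.ages
        slope, _ = np.polyfit(ages, m.data["G0001"].to_numpy(), 1)
        resid = m.data["G0001"] - np.poly1d(np.polyfit(ages, m.data["G0001"], 1))(ages)
        # ages are shared within pairs, so the effective n is the family count
        se = resid.std() / (ages.std() * np.sqrt(cohort.n_families))
        assert slope == pytest.approx(0.02, abs=3 * se)

    def test_gene_order_permutation_permutes_columns(self, small_cohort):
        truth = make_truth(small_cohort, n_genes=30, n_pathways=3, pathway_size_range=(5, 8), seed=8)
        m = generate_expression(small_cohort, truth)
        rng = np.random.default_rng(0)
        order = list(rng.permutation(truth.gene_ids))
        permuted = permute_genes(truth, order)
        m2 = generate_expression(small_cohort, permuted)
        pd.testing.assert_frame_equal(m2.data, m.data[order])

    def test_determinism(self, small_cohort):
        truth = make_truth(small_cohort, n_genes=25, n_pathways=2, pathway_size_range=(5, 8), seed=9)
        a = generate_expression(small_cohort, truth)
        b = generate_expression(small_cohort, truth)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_cohort_mismatch_rejected(self, small_cohort, tiny_cohort):
        truth = make_truth(small_cohort, n_genes=10, n_pathways=0, seed=10)
        with pytest.raises(ValidationError, match="different cohort"):
            generate_expression(tiny_cohort, truth)


class TestTruthStructure:
    def test_variance_fractions_valid(self, small_cohort):
        truth = make_truth(small_cohort, seed=11)
        for va, vc, ve in truth.variance_fractions.values():
            assert min(va, vc, ve) >= 0
            assert va + vc + ve <= 1 + 1e-9

    def test_pathway_members_in_universe(self, small_cohort):
        truth = make_truth(small_cohort, seed=12)
        universe = set(truth.gene_ids)
        for members in truth.pathway_members.values():
            assert set(members) <= universe

    def test_small_pathways_below_filter_size(self, small_cohort):
        truth = make_truth(small_cohort, n_small_pathways=5, seed=13)
        small = [p for p in truth.pathway_members if p.startswith("SM")]
        assert len(small) == 5
        assert all(len(truth.pathway_members[p]) <= 10 for p in small)

    def test_module_scores_reproduce_generator_latents(self, small_cohort):
        truth = make_truth(
            small_cohort,
            n_genes=30,
            n_pathways=1,
            loader_fraction=1.0,
            module_share=0.9,
            specific_ace=(0.0, 0.0, 1.0),
            n_age_pathways=0,
            k_global=0,
            global_share=0.0,
            loading_range=(1.0, 1.0),
            neg_loading_prob=0.0,
            seed=14,
        )
        m = generate_expression(small_cohort, truth)
        u = module_scores(small_cohort, truth)["PW001"].to_numpy()
        # with near-pure module signal, each loader tracks the latent
        g = truth.pathway_module_assignments["PW001"][0]
        r = np.corrcoef(m.data[g].to_numpy(), u)[0, 1]
        assert abs(r) > 0.9

    def test_truth_json_round_trip(self, small_cohort, tmp_path):
        from twinpath.simulate import read_truth, write_truth

        truth = make_truth(small_cohort, n_genes=20, n_pathways=2, pathway_size_range=(5, 8), seed=15)
        path = tmp_path / "truth.json"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.gene_ids == truth.gene_ids
        np.testing.assert_allclose(back.global_weights, truth.global_weights)
        assert back.age_effect_sizes == truth.age_effect_sizes


class TestPhenotypeSimulators:
    def test_ace_phenotype_twin_correlations(self, medium_cohort):
        rng = stream(16, "test")
        reps = np.array(
            [
                simulate_ace_phenotype(medium_cohort, 0.6, 0.2, 0.2, rng=rng)
                for _ in range(50)
            ]
        )
        units = medium_cohort.family_units()
        pos = {s: i for i, s in enumerate(medium_cohort.sample_ids)}
        mz = np.array([[pos[a], pos[b]] for a, b in units["MZ"]])
        r = np.corrcoef(reps[:, mz[:, 0]].ravel(), reps[:, mz[:, 1]].ravel())[0, 1]
        assert r == pytest.approx(0.8, abs=0.03)

    def test_nested_model_phenotype_variances(self, medium_cohort):
        rng = stream(17, "test")
        reps = np.array(
            [
                simulate_twin_model_phenotype(medium_cohort, 0.5, 0.25, 0.25, rng=rng)
                for _ in range(200)
            ]
        )
        zyg = medium_cohort.samples["zygosity"].to_numpy()
        var_mz = reps[:, zyg == "MZ"].var()
        var_dz = reps[:, zyg == "DZ"].var()
        assert var_mz == pytest.approx(1.0, abs=0.05)
        assert var_dz == pytest.approx(0.75, abs=0.05)
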