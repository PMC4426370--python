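"""Synthetic twin cohorts and expression matrices with known ground truth.

The generator emulates a female twin cohort (MZ and DZ pairs plus optional
singletons) and a post-QC log2 expression matrix containing, per gene:

* a baseline level,
* low-rank global confounders (shared latent factors across all genes),
* a pathway co-expression module — one latent score per pathway, itself
  built from additive-genetic (A), shared-environment (C) and unique-
  environment (E) components, loading on a fraction of the pathway's
  member genes,
* an age effect (expression units per year) on the module genes of
  age-responsive pathways,
* gene-specific A / C / E components. The additive-genetic component is
  shared exactly between MZ co-twins and correlated 0.5 between DZ
  co-twins; the shared-environment component is shared exactly within any
  twin pair.

Every random draw is keyed by (seed, kind, id) via :mod:`twinpath.streams`
so that permuting gene order permutes matrix columns identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .containers import (
    DZ,
    MZ,
    SINGLETON,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    TwinCohort,
    ValidationError,
)
from .streams import stream

# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Size and age structure of a synthetic twin cohort.

    Defaults give the scaled-down cohort used throughout the test suite;
    ``n_mz_pairs=168, n_dz_pairs=260`` reproduces the 336 MZ + 520 DZ
    individual roster of the motivating skin-expression cohort, with ages
    in 39-85 years averaging 59.
    """

    n_mz_pairs: int = 100
    n_dz_pairs: int = 100
    n_singletons: int = 0
    age_min: float = 39.0
    age_max: float = 85.0
    age_mean_target: float = 59.0
    age_sd: float = 10.0
    n_batches: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ValidationError("cohort counts must be >= 0")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_singletons == 0:
            raise ValidationError("cohort must contain at least one individual")
        if not (self.age_min <= self.age_mean_target <= self.age_max):
            raise ValidationError("need age_min <= age_mean_target <= age_max")
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be positive")


def _truncnorm_loc(a: float, b: float, target: float, sd: float) -> float:
    """Location of a truncated normal on [a, b] whose mean equals target."""
    if b - a < 1e-12:
        return a

    def mean_minus_target(mu: float) -> float:
        alpha, beta = (a - mu) / sd, (b - mu) / sd
        return truncnorm.mean(alpha, beta, loc=mu, scale=sd) - target

    margin = 1e-6 * (b - a)
    target = min(max(target, a + margin), b - margin)
    lo, hi = a - 60 * sd, b + 60 * sd
    return brentq(lambda mu: mean_minus_target(mu), lo, hi, xtol=1e-10)


def generate_cohort(spec: CohortSpec) -> TwinCohort:
    """Generate a twin cohort roster; deterministic given ``spec.seed``.

    Co-twins share one family id and one age; family ages are drawn from a
    truncated normal on [age_min, age_max] whose location is tuned so the
    truncated mean equals ``age_mean_target``.
    """
    spec.validate()
    rng = stream(spec.seed, "cohort")
    n_fam = spec.n_mz_pairs + spec.n_dz_pairs + spec.n_singletons

    loc = _truncnorm_loc(spec.age_min, spec.age_max, spec.age_mean_target, spec.age_sd)
    if spec.age_max - spec.age_min < 1e-12:
        fam_ages = np.full(n_fam, spec.age_min)
    else:
        alpha = (spec.age_min - loc) / spec.age_sd
        beta = (spec.age_max - loc) / spec.age_sd
        fam_ages = truncnorm.rvs(
            alpha, beta, loc=loc, scale=spec.age_sd, size=n_fam, random_state=rng
        )

    zygosities = (
        [MZ] * spec.n_mz_pairs + [DZ] * spec.n_dz_pairs + [SINGLETON] * spec.n_singletons
    )
    rows = []
    sample_counter = 0
    for fam_i, zyg in enumerate(zygosities):
        family_id = f"F{fam_i + 1:05d}"
        n_members = 2 if zyg in (MZ, DZ) else 1
        for _ in range(n_members):
            sample_counter += 1
            rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "individual_id": f"I{sample_counter:05d}",
                    "family_id": family_id,
                    "zygosity": zyg,
                    "age": float(fam_ages[fam_i]),
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    n = len(df)
    df["batch"] = [f"B{b + 1}" for b in rng.integers(0, spec.n_batches, size=n)]
    df["rna_quality"] = rng.normal(8.0, 0.5, size=n)
    df["rna_concentration"] = np.clip(rng.normal(100.0, 20.0, size=n), 10.0, None)
    return TwinCohort(df)


# ---------------------------------------------------------------------------
# ACE building blocks
# ---------------------------------------------------------------------------


def _family_arrays(cohort: TwinCohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample family index (0..n_fam-1, in roster order) and zygosity."""
    fam_codes, _ = pd.factorize(cohort.samples["family_id"], sort=False)
    zyg = cohort.samples["zygosity"].to_numpy()
    return fam_codes, zyg


def _ace_components(
    rng: np.random.Generator, fam_codes: np.ndarray, zyg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-variance A, C, E components with twin covariance structure.

    A is shared exactly by MZ co-twins and correlated 0.5 between DZ
    co-twins; C is shared exactly within any twin pair; E is iid.
    """
    n = len(fam_codes)
    n_fam = int(fam_codes.max()) + 1 if n else 0
    z_fam = rng.standard_normal(n_fam)
    z_own = rng.standard_normal(n)
    c_fam = rng.standard_normal(n_fam)
    e = rng.standard_normal(n)

    a = np.empty(n)
    is_mz = zyg == MZ
    is_dz = zyg == DZ
    a[is_mz] = z_fam[fam_codes[is_mz]]
    a[is_dz] = np.sqrt(0.5) * z_fam[fam_codes[is_dz]] + np.sqrt(0.5) * z_own[is_dz]
    rest = ~(is_mz | is_dz)
    a[rest] = z_own[rest]
    c = c_fam[fam_codes]
    return a, c, e


def simulate_ace_phenotype(
    cohort: TwinCohort,
    v_a: float,
    v_c: float,
    v_e: float,
    beta_age: float = 0.0,
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phenotype from the biometric ACE model plus an optional age slope."""
    if rng is None:
        rng = np.random.default_rng(0)
    fam_codes, zyg = _family_arrays(cohort)
    a, c, e = _ace_components(rng, fam_codes, zyg)
    ages = cohort.ages
    return (
        mean
        + beta_age * (ages - ages.mean())
        + np.sqrt(v_a) * a
        + np.sqrt(v_c) * c
        + np.sqrt(v_e) * e
    )


def simulate_twin_model_phenotype(
    cohort: TwinCohort,
    sigma2_pair: float,
    sigma2_mz_extra: float,
    sigma2_resid: float,
    beta_0: float = 0.0,
    beta_age: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phenotype drawn from the nested twin mixed model itself
    (pair-shared effect + MZ-only extra effect + iid residual)."""
    if rng is None:
        rng = np.random.default_rng(0)
    fam_codes, zyg = _family_arrays(cohort)
    n_fam = int(fam_codes.max()) + 1
    f = rng.standard_normal(n_fam)
    m = rng.standard_normal(n_fam)
    e = rng.standard_normal(len(fam_codes))
    y = beta_0 + beta_age * cohort.ages + np.sqrt(sigma2_pair) * f[fam_codes]
    is_mz = zyg == MZ
    y[is_mz] += np.sqrt(sigma2_mz_extra) * m[fam_codes[is_mz]]
    return y + np.sqrt(sigma2_resid) * e


# ---------------------------------------------------------------------------
# simulation truth
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth for one synthetic expression matrix.

    ``variance_fractions`` hold the gene-specific (v_A, v_C, v_E)
    variances; the remainder of each gene's unit variance budget is
    carried by the global-factor, pathway-module and age terms.
    ``age_effect_sizes`` are slopes in expression units per year (0 for
    non-responsive genes). ``module_loadings[p][g]`` is the coefficient of
    pathway p's latent module score on gene g (already including the
    module-share scale).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    baseline: dict[str, float]
    global_factor_scores: np.ndarray
    global_weights: np.ndarray
    pathway_members: dict[str, list[str]]
    pathway_module_assignments: dict[str, list[str]]
    module_loadings: dict[str, dict[str, float]]
    module_ace: tuple[float, float, float]
    age_pathways: list[str]
    age_module_share: float
    age_effect_sizes: dict[str, float]
    variance_fractions: dict[str, tuple[float, float, float]]
    age_mean: float
    age_sd: float
    seed: int

    def validate(self) -> None:
        universe = set(self.gene_ids)
        for pid, members in self.pathway_members.items():
            missing = set(members) - universe
            if missing:
                raise ValidationError(
                    f"pathway {pid!r} members outside gene universe: {sorted(missing)[:5]}"
                )
        for pid, loaders in self.pathway_module_assignments.items():
            if not set(loaders) <= set(self.pathway_members[pid]):
                raise ValidationError(f"pathway {pid!r}: loaders not in member list")
        for g, (va, vc, ve) in self.variance_fractions.items():
            if min(va, vc, ve) < 0 or va + vc + ve > 1 + 1e-9:
                raise ValidationError(f"gene {g!r}: bad variance fractions {(va, vc, ve)}")

    def gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection(
            GeneSet(pid, f"synthetic pathway {pid}", tuple(members))
            for pid, members in self.pathway_members.items()
        )


def make_truth(
    cohort: TwinCohort,
    n_genes: int = 200,
    n_pathways: int = 20,
    pathway_size_range: tuple[int, int] = (12, 25),
    n_small_pathways: int = 0,
    small_size_range: tuple[int, int] = (3, 10),
    k_global: int = 5,
    global_share: float = 0.30,
    loader_fraction: float = 0.30,
    module_share: float = 0.30,
    module_ace: tuple[float, float, float] = (0.70, 0.10, 0.20),
    specific_ace: tuple[float, float, float] = (0.12, 0.08, 0.80),
    n_age_pathways: int = 3,
    age_module_share: float = 0.15,
    loading_range: tuple[float, float] = (0.8, 1.2),
    neg_loading_prob: float = 0.3,
    baseline_range: tuple[float, float] = (6.0, 12.0),
    seed: int = 0,
) -> SimulationTruth:
    """Construct the ground-truth object for :func:`generate_expression`.

    Each regular pathway receives a disjoint block of "core" (module-
    loading) genes plus additional members sampled from a shared pool, so
    pathways overlap in their non-module genes as curated gene sets do.
    ``n_small_pathways`` adds sets drawn only from the pool, below the
    usual membership filter, to exercise pathway filtering.
    """
    rng = stream(seed, "truth")
    n = cohort.n_individuals
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    # pathway construction: disjoint cores + shared pool
    sizes = rng.integers(pathway_size_range[0], pathway_size_range[1] + 1, n_pathways)
    n_loaders = np.maximum(2, np.round(loader_fraction * sizes).astype(int))
    total_core = int(n_loaders.sum())
    if total_core > n_genes:
        raise ValidationError(
            f"n_genes={n_genes} too small for {n_pathways} pathways "
            f"({total_core} core genes needed)"
        )
    pool = list(gene_ids[total_core:])
    if sizes.size and len(pool) < int((sizes - n_loaders).max(initial=0)):
        raise ValidationError("shared gene pool too small for pathway sizes")

    pathway_members: dict[str, list[str]] = {}
    module_assignments: dict[str, list[str]] = {}
    module_loadings: dict[str, dict[str, float]] = {}
    cursor = 0
    for p in range(n_pathways):
        pid = f"PW{p + 1:03d}"
        loaders = gene_ids[cursor : cursor + n_loaders[p]]
        cursor += n_loaders[p]
        extra = list(rng.choice(pool, size=sizes[p] - n_loaders[p], replace=False))
        pathway_members[pid] = loaders + extra
        module_assignments[pid] = list(loaders)
        signs = np.where(rng.random(len(loaders)) < neg_loading_prob, -1.0, 1.0)
        mags = rng.uniform(*loading_range, size=len(loaders))
        module_loadings[pid] = {
            g: float(np.sqrt(module_share) * s * m)
            for g, s, m in zip(loaders, signs, mags)
        }
    for p in range(n_small_pathways):
        pid = f"SM{p + 1:03d}"
        size = int(rng.integers(small_size_range[0], small_size_range[1] + 1))
        pathway_members[pid] = list(rng.choice(pool, size=size, replace=False))
        module_assignments[pid] = []
        module_loadings[pid] = {}

    regular = [f"PW{p + 1:03d}" for p in range(n_pathways)]
    n_age = min(n_age_pathways, n_pathways)
    if n_age > 0:
        age_pathways = sorted(rng.choice(regular, size=n_age, replace=False).tolist())
    else:
        age_pathways = []

    # global confounders
    global_scores = rng.standard_normal((n, k_global))
    if k_global > 0 and global_share > 0:
        w = rng.standard_normal((n_genes, k_global))
        w *= np.sqrt(global_share) / np.linalg.norm(w, axis=1, keepdims=True)
    else:
        w = np.zeros((n_genes, k_global))

    ages = cohort.ages
    age_mean = float(ages.mean())
    age_sd = float(ages.std()) if ages.std() > 0 else 1.0

    # per-gene variance budget
    ratios = np.asarray(specific_ace, dtype=float)
    ratios = ratios / ratios.sum() if ratios.sum() > 0 else ratios
    loader_coeff = {
        g: c for pid in module_loadings for g, c in module_loadings[pid].items()
    }
    variance_fractions: dict[str, tuple[float, float, float]] = {}
    age_effects: dict[str, float] = {}
    age_loaders = {
        g for pid in age_pathways for g in module_assignments[pid]
    }
    for j, g in enumerate(gene_ids):
        v_mod = loader_coeff.get(g, 0.0) ** 2
        v_glob = float(np.sum(w[j] ** 2)) if k_global else 0.0
        leftover = max(1.0 - v_glob - v_mod, 0.0)
        va, vc, ve = (leftover * ratios).tolist()
        variance_fractions[g] = (float(va), float(vc), float(ve))
        if g in age_loaders:
            # age acts through the module score: slope per year
            age_effects[g] = float(
                loader_coeff[g] * np.sqrt(age_module_share) / age_sd
            )
        else:
            age_effects[g] = 0.0

    baseline = dict(zip(gene_ids, rng.uniform(*baseline_range, size=n_genes)))
    truth = SimulationTruth(
        gene_ids=gene_ids,
        sample_ids=cohort.sample_ids,
        baseline=baseline,
        global_factor_scores=global_scores,
        global_weights=w,
        pathway_members=pathway_members,
        pathway_module_assignments=module_assignments,
        module_loadings=module_loadings,
        module_ace=tuple(float(x) for x in module_ace),
        age_pathways=age_pathways,
        age_module_share=float(age_module_share),
        age_effect_sizes=age_effects,
        variance_fractions=variance_fractions,
        age_mean=age_mean,
        age_sd=age_sd,
        seed=seed,
    )
    truth.validate()
    return truth


def generate_expression(cohort: TwinCohort, truth: SimulationTruth) -> ExpressionMatrix:
    """Simulate the log2 expression matrix implied by ``truth``.

    Y[i, g] = baseline_g + global term + module term + age_effect_g *
    (age_i - mean age) + A + C + E, with the twin covariance structure
    described in the module docstring. Deterministic given ``truth.seed``;
    each gene's draws are keyed by its id, so reordering genes in the
    truth object permutes columns and nothing else.
    """
    if not truth.gene_ids:
        raise ValidationError("truth gene universe is empty")
    if truth.sample_ids != cohort.sample_ids:
        raise ValidationError("truth was built for a different cohort roster")

    fam_codes, zyg = _family_arrays(cohort)
    n = cohort.n_individuals
    gene_pos = {g: j for j, g in enumerate(truth.gene_ids)}
    n_genes = len(truth.gene_ids)

    baseline = np.array([truth.baseline[g] for g in truth.gene_ids])
    Y = np.tile(baseline, (n, 1))
    if truth.global_weights.size:
        # global_weights rows follow the original truth gene order; map by id
        Y += truth.global_factor_scores @ truth.global_weights.T

    # pathway module latents (pure ACE; age enters via per-gene slopes)
    a_m, c_m, e_m = truth.module_ace
    for pid in truth.pathway_module_assignments:
        loadings = truth.module_loadings.get(pid, {})
        if not loadings:
            continue
        rng_m = stream(truth.seed, "module", pid)
        a, c, e = _ace_components(rng_m, fam_codes, zyg)
        u = np.sqrt(a_m) * a + np.sqrt(c_m) * c + np.sqrt(e_m) * e
        share = truth.age_module_share if pid in truth.age_pathways else 0.0
        u = np.sqrt(1.0 - share) * u
        for g, coeff in loadings.items():
            Y[:, gene_pos[g]] += coeff * u

    ages_centered = cohort.ages - truth.age_mean
    for g in truth.gene_ids:
        j = gene_pos[g]
        beta = truth.age_effect_sizes.get(g, 0.0)
        if beta:
            Y[:, j] += beta * ages_centered
        va, vc, ve = truth.variance_fractions[g]
        rng_g = stream(truth.seed, "gene", g)
        a, c, e = _ace_components(rng_g, fam_codes, zyg)
        Y[:, j] += np.sqrt(va) * a + np.sqrt(vc) * c + np.sqrt(ve) * e

    return ExpressionMatrix.from_arrays(Y, cohort.sample_ids, truth.gene_ids)


def module_scores(cohort: TwinCohort, truth: SimulationTruth) -> pd.DataFrame:
    """Reconstruct the latent module score realized for each pathway.

    Uses the same keyed streams as :func:`generate_expression`, so the
    returned columns are exactly the latents that entered the matrix
    (useful for factor-recovery checks against ground truth).
    """
    fam_codes, zyg = _family_arrays(cohort)
    a_m, c_m, e_m = truth.module_ace
    out: dict[str, np.ndarray] = {}
    for pid, loadings in truth.module_loadings.items():
        if not loadings:
            continue
        rng_m = stream(truth.seed, "module", pid)
        a, c, e = _ace_components(rng_m, fam_codes, zyg)
        u = np.sqrt(a_m) * a + np.sqrt(c_m) * c + np.sqrt(e_m) * e
        share = truth.age_module_share if pid in truth.age_pathways else 0.0
        out[pid] = np.sqrt(1.0 - share) * u
    return pd.DataFrame(out, index=cohort.sample_ids)


def permute_genes(truth: SimulationTruth, order: list[str]) -> SimulationTruth:
    """Reorder the truth's gene universe (same genes, new column order)."""
    if sorted(order) != sorted(truth.gene_ids):
        raise ValidationError("order must be a permutation of the gene universe")
    pos = {g: j for j, g in enumerate(truth.gene_ids)}
    idx = [pos[g] for g in order]
    return dataclasses.replace(
        truth, gene_ids=list(order), global_weights=truth.global_weights[idx]
    )


# ---------------------------------------------------------------------------
# truth JSON sidecar
# ---------------------------------------------------------------------------


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    payload = dataclasses.asdict(truth)
    payload["global_factor_scores"] = truth.global_factor_scores.tolist()
    payload["global_weights"] = truth.global_weights.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        payload = json.load(fh)
    payload["global_factor_scores"] = np.asarray(payload["global_factor_scores"])
    payload["global_weights"] = np.asarray(payload["global_weights"])
    payload["module_ace"] = tuple(payload["module_ace"])
    payload["variance_fractions"] = {
        g: tuple(v) for g, v in payload["variance_fractions"].items()
    }
    truth = SimulationTruth(**payload)
    truth.validate()
    return truth
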