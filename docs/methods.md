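# Methods

`twinpath` analyses gene expression measured on a cohort of monozygotic
(MZ) and dizygotic (DZ) twins. Its goal is to summarize each biological
pathway's expression as a handful of derived phenotypes, test those
phenotypes for association with age, and partition their variance into
genetic, shared-environment, unique-environment and age components. This
note documents the models, the estimators, the synthetic data the tests
run on, and the numerical choices that were genuinely open.

## Two-stage factor analysis

**Model.** For an n x G log2 expression matrix Y, covariate design C
(batch dummies, RNA quality, RNA concentration, intercept) the factor
model is

    Y = C B + X Wᵀ + ε,   x_i ~ N(0, I_K),   ε_ig ~ N(0, ψ_g)

with per-gene noise variances ψ_g and an automatic relevance
determination (ARD) prior on the weight columns, w_gk ~ N(0, 1/α_k),
α_k ~ Gamma(10⁻³, 10⁻³). The ARD precisions shrink factors the data do
not support. Fitting is MAP expectation–maximization: the E-step
integrates over X in closed form; the M-step updates W (a per-gene ridge
solve), ψ, the covariate effects B, and α in turn. The penalized marginal
log-likelihood is recorded every iteration and is non-decreasing by the
EM argument (each coordinate update cannot decrease the bound).

**Initialization and determinism.** Factors start at the top-K singular
vectors of the covariate-adjusted matrix, so a fit is bit-reproducible
without any random seed. Convergence is declared when the relative
objective change drops below `tol` (default 1e-6; `max_iter` 1000, with a
non-convergence flag rather than an exception).

**Identifiability conventions.** After fitting, each factor's score
vector is standardized to unit variance (weights absorb the scale) and
its sign is fixed so the gene with the largest absolute weight loads
positively. Per-factor variance shares use the exact symmetric
attribution ⟨F_k, 2Y_adj − F⟩ / ‖Y_adj‖², which sums to the total
variance explained to machine precision even when score vectors are not
exactly orthogonal.

**Shrunk factors.** The MAP for a truly irrelevant factor is exactly
W_k = 0; uninterrupted EM drives such columns below floating-point range.
Once a factor's weight norm falls under 1e-8 of the data scale its
coordinates are frozen (skipping a coordinate update preserves
monotonicity exactly). The frozen factor keeps a tiny but genuine score
direction — the limiting direction is a leading residual-variation
component — so downstream stages always receive K usable phenotypes per
pathway, with the factor's negligible variance share recorded honestly.

**Flat-prior configuration.** With `ard=False, shared_noise=True` the
model is probabilistic PCA; its fitted score subspace coincides with the
top-K left singular vectors of the adjusted matrix, which is used as an
exact oracle in the tests.

**Residualization.** The fitted global factors are treated as nuisance
covariates: the residual matrix is the least-squares residual of Y on
[C, X]. This makes every residual gene vector numerically orthogonal to
every covariate and factor score (the EM point estimates alone would not
guarantee that).

## Pathway phenotypes

Pathways (any GMT file; KEGG in the motivating application) are filtered
to those with strictly more than `min_genes` (default 10) members present
in the matrix. Each retained pathway's member-gene submatrix of the
global-stage residuals is fitted with the same factor engine, K = 5
factors, intercept only (confounders were removed once, globally —
re-adding technical covariates per pathway would double-adjust). Factors
are ordered within a pathway by variance explained. Genes belonging to
several pathways contribute to each of them; overlapping pathways
therefore yield correlated phenotypes, as overlapping curated gene sets
do in practice.

## Twin mixed model

For a phenotype y on the cohort, the model is

    y_ij = β₀ + β_age·age_ij + f_i + m_i·[MZ] + e_ij

with f ~ N(0, σ²_pair) shared by any twin pair, m ~ N(0, σ²_mz) shared
only by MZ co-twins, and iid residual e ~ N(0, σ²_res). Implied
covariances: cov(DZ) = σ²_pair, cov(MZ) = σ²_pair + σ²_mz — the nested
random-intercept parameterization, under which twice the extra MZ
covariance is the additive-genetic variance of the classical twin design.
The exact equations of the original description are in a figure not
available in text form; this parameterization is the standard one
consistent with every stated property and is used throughout.

**Fitting.** Maximum likelihood (not REML: the age test compares models
differing in a fixed effect). For fixed variance parameters the fixed
effects have a closed-form GLS solution computed block by block, so the
optimizer works on the 3-dimensional profiled likelihood with analytic
gradients (L-BFGS-B, variances bounded below by 0, residual variance by
1e-8 of the phenotype variance). Three deterministic starts — method of
moments from co-twin covariances, an equal split, and residual-only —
guard against local optima; ties keep the moments start.

**Age LRT.** 2·(ℓ_full − ℓ_null) floored at zero, referred to χ²(1).
Multiple testing uses Bonferroni α/n across all phenotypes, a
within-pathway Bonferroni (α / pathway size) for per-gene follow-up, and
Benjamini–Hochberg q-values for the genome-wide single-gene list.

**Variance decomposition.** With V = var(β_age·age) + σ²_pair + σ²_mz +
σ²_res: genetic share h² = 2σ²_mz/V, shared environment c² =
(σ²_pair − σ²_mz)/V, unique environment e² = σ²_res/V, age share =
var(β_age·age)/V. Negative implied shares (possible when σ²_mz > σ²_pair)
are clipped at zero and the four shares renormalized to sum to one, so
every reported proportion is in [0, 1]. The proportion of environmental
variance explained by age is age share / (1 − h²). Because all shares are
ratios, the decomposition is invariant to phenotype scale, so covariance
differences and correlation differences coincide on the standardized
phenotypes the pipeline produces.

**Estimator properties worth knowing.** (i) The non-negativity constraint
makes h² estimates at or near zero biased upward (a truncated-Gaussian
effect of order the sampling SD); the recovery experiment therefore
defines its zero-heritability configuration with no familial variance at
all, where the bias is smallest. (ii) When data come from the classical
biometric ACE model (equal MZ/DZ total variance, DZ genetic correlation
0.5), the nested model — which implies extra MZ variance — attenuates h²
systematically; "true h²" in the recovery experiment is therefore defined
under the nested model family itself, the family the estimator fits and
reports.

## Structure-preserving permutation

The permutation reassigns (age, family identity) among family units
within each stratum — MZ pairs with MZ pairs, DZ pairs with DZ pairs,
singletons with singletons — keeping twin pairs together, zygosity labels
in place, and the age multiset unchanged. Only the phenotype-to-age
pairing is broken, so within-pair phenotype covariance is preserved and
the permuted p-values form an honest empirical null. On a 2-MZ + 2-DZ
cohort exactly four distinct assignments exist (2 MZ orders x 2 DZ
orders), which the tests enumerate.

## Enrichment comparison

Single-gene age tests (same twin LRT) feed a one-sided Fisher exact test
per pathway (significant x in-pathway 2x2 table, alternative "greater";
universe = all genes in the analyzed matrix, configurable). Per-pathway
p-values from the two routes — the minimum of the pathway's K factor
p-values (Šidák-adjusted minimum available as an option) versus the
Fisher p — are compared by Spearman correlation with midrank ties.

## Quantile normalization

Two stages: technical replicates are quantile-normalized within each
individual and collapsed by the mean of the normalized replicates, then
the per-individual profiles are quantile-normalized across individuals.
Ties map to the mean of the reference quantiles they span (midrank
convention); consequently the "all sorted rows identical" property is
exact only for tie-free data, which continuous expression values are
almost surely. The choice of mean (not median) for the replicate collapse
is a convention; stage 1 is the identity when no replicates exist. The
normalization is idempotent and rank-preserving within samples.

## Synthetic data

The generator emulates a female twin cohort and a post-QC expression
matrix. Defaults were chosen once to mirror the motivating study's
conditions and magnitudes:

* **Cohort**: MZ and DZ pairs (full-scale configuration 168 + 260 pairs =
  856 individuals; scaled-down default 100 + 100 pairs) plus optional
  singletons; family ages drawn from a truncated normal on [39, 85] years
  with SD 10 and location tuned so the truncated mean is 59 (the source
  cohort reports only range and mean; the truncated normal is a
  stand-in). Technical covariates: 4 batches, RIN-like quality ~N(8,
  0.5), concentration ~N(100, 20).
* **Per-gene variance budget** (fractions of unit variance): global
  confounders 0.30 spread over 5 latent factors (all genes); for the 30%
  of pathway members that load on their pathway's co-expression module, a
  module share of 0.30 (loadings ±U(0.8, 1.2), 30% negative — antagonistic
  expression); the remainder split among gene-specific A/C/E in ratios
  0.12 / 0.08 / 0.80. Single genes are thus noisy and weakly heritable
  (h² ≈ 0.1–0.3), as bulk expression traits are.
* **Module score**: one latent per pathway with ACE fractions
  (0.70, 0.10, 0.20) — co-expression modules are substantially heritable,
  which is what makes pathway factors more heritable than genes.
* **Age**: in age-responsive pathways (default 3) age replaces 15% of the
  module-score variance; the implied per-gene slopes in expression units
  per year are recorded in the truth object.
* **Twin structure**: additive-genetic components are shared exactly by
  MZ co-twins and correlated 0.5 between DZ co-twins; shared-environment
  components are shared within any pair. Every draw is keyed by
  (seed, kind, id) so regenerating with permuted gene order permutes the
  matrix columns and nothing else.

**What the generator does not emulate**: probe-level bead data and raw
intensities, nonlinear batch artifacts, covariate effects on expression
(the metadata covariates are present but carry no planted effect by
default), count noise or heteroskedastic mean–variance coupling, sex
effects (the emulated cohort is all female), and linkage between genetic
variants and expression. Passing tests therefore demonstrate correctness
of the estimators and pipeline plumbing under an idealized Gaussian
world, not robustness to real microarray artifacts.

## Validation experiment sizes

The self-contained experiments in `twinpath.experiments` (run by
`scripts/acceptance.py` and the acceptance tests) use: a 186-pathway /
930-phenotype pipeline run at 100+100 pairs and ~5,600 genes; 1000
random draws for the likelihood oracle; 200 replicates x {0, 0.3, 0.6}
for heritability recovery at 250+250 pairs; 2000 null phenotypes for LRT
calibration; and 50 replicates of the variance-source comparison at
350+350 pairs with 16 pathways. The latter two sizes keep binomial /
Monte-Carlo error comfortably inside the bands they are checked against;
all finish in minutes on one core.

## Known limitations

* The nested twin model is fitted by unconstrained-in-β, bounded-in-σ²
  ML; standard errors of the variance components are not reported.
* No dominance (ADE) models, no covariate random slopes, no kinship
  structures beyond MZ/DZ/singleton.
* K is fixed (default 5) rather than selected by variance criteria.
* The Fisher universe defaults to all analyzed genes; restricting it to
  pathway-annotated genes changes enrichment p-values and is left to the
  caller.
* The factor engine is this package's own MAP-EM estimator; it satisfies
  the documented recovery and shrinkage properties but is not a
  re-implementation of any specific published software's internals.
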