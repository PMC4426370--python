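# twinpath

Pathway-level factor phenotypes from twin gene-expression data.

Bulk expression of a single gene is a noisy trait: much of its variance
is stochastic, individual-specific "unique environment", which drowns out
systematic signals such as aging. `twinpath` implements a two-stage
factor-analysis pipeline for twin cohorts that addresses this:

1. **Global stage** — fit K latent factors to the whole expression matrix
   (with technical covariates: batch, RNA quality and concentration as
   fixed effects) and regress them out as nuisance variation.
2. **Pathway stage** — for every pathway with more than 10 genes present,
   fit K = 5 factors to the residual expression of its member genes. Each
   factor score vector is a *pathway phenotype*: a weighted sum of member
   gene expression that averages away gene-specific noise.
3. **Twin modelling** — test each phenotype for an age effect with a
   likelihood-ratio test of the twin linear mixed model
   `y = β₀ + β_age·age + f + m·[MZ] + e`, where `f ~ N(0, σ²_pair)` is
   shared by any twin pair and `m ~ N(0, σ²_mz)` only by monozygotic
   co-twins. Decompose each phenotype's variance into heritability
   `h² = 2σ²_mz / V` (twice the extra MZ covariance), shared environment
   `(σ²_pair − σ²_mz)/V`, unique environment `σ²_res/V`, and an age share
   `var(β_age·age)/V`, all constrained to [0, 1].
4. **Comparison** — single-gene age tests with Bonferroni/BH-FDR control,
   one-sided Fisher exact enrichment per pathway, Spearman concordance of
   the two routes, structure-preserving permutations (twin pairs stay
   together) and Q-Q coordinates.

The package is aimed at statistical geneticists and transcriptomics
analysts working with family-structured expression data. It ships a
first-class synthetic-data generator (`twinpath.simulate`) that plants
global confounders, heritable pathway co-expression modules, ACE variance
structure and age effects with a recorded ground truth, so every stage is
testable against known answers.

## Worked example

```python
from twinpath import (
    CohortSpec, generate_cohort, make_truth, generate_expression, run_pipeline,
)

cohort = generate_cohort(CohortSpec(n_mz_pairs=100, n_dz_pairs=100, seed=7))
truth = make_truth(cohort, seed=7)      # 200 genes, 20 pathways, 3 age-responsive
matrix = generate_expression(cohort, truth)
result = run_pipeline(matrix, cohort, truth.gene_sets(), single_gene=True)

print(len(result.retained_sets), result.n_phenotypes)
sig = result.association[result.association.significant_bonferroni]
```

This prints `20 100` (20 pathways survive the >10-gene filter, 5 factors
each → 100 phenotypes) and the significant rows are exactly the three
planted age-responsive pathways, each led by its first factor:

```
PW001  1  beta_age=+0.0257  p=2.69e-05  h2=0.43  e2=0.52
PW012  1  beta_age=+0.0318  p=8.88e-07  h2=0.36  e2=0.42
PW016  1  beta_age=+0.0405  p=9.27e-11  h2=0.35  e2=0.40
```

`beta_age` is the phenotype change per year of age; `p` is the χ²(1) LRT
p-value (the Bonferroni threshold here is 0.05/100 = 5e-4); `h2`/`e2`
are the heritability and unique-environment shares of the phenotype —
note they are substantially more heritable than single genes in the same
matrix (mean gene h² ≈ 0.1). The per-gene follow-up inside the hits
(within-pathway Bonferroni) finds 3–8 age-associated member genes each,
and the factor route's per-pathway p-values agree with single-gene Fisher
enrichment (Spearman ρ = 0.62, p = 3.4e-3 on this run). The global
factors explain 31% of covariate-adjusted variance and the five pathway
factors explain on average 17% of their pathway's residual variance.

A command-line interface mirrors the library:

```bash
twinpath simulate-data --out data/ --seed 7
twinpath run-all --config config.yaml --out results/
```

with subcommands `global-factors`, `pathway-factors`, `associate`,
`genes`, `enrich` for the individual stages.

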