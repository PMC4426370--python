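"""Per-pathway factor phenotypes.

After the global confounder factors have been regressed out, each
pathway's member-gene submatrix is treated as a new expression dataset
and the same factor model is fitted to it (no covariates beyond an
intercept — confounders were removed once, globally). The K factor score
vectors per pathway are the "pathway phenotypes" tested downstream.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection, ValidationError
from .factor import FactorFit, fit_factor_model

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 10


def filter_pathways(
    sets: GeneSetCollection,
    matrix: ExpressionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
) -> GeneSetCollection:
    """Keep sets with strictly more than ``min_genes`` members present in
    the matrix; membership lists are trimmed to present genes."""
    present = set(matrix.gene_ids)
    kept = GeneSetCollection()
    for s in sets:
        members = tuple(g for g in s.genes if g in present)
        if len(members) > min_genes:
            kept.add(GeneSet(s.set_id, s.description, members))
    logger.info(
        "pathway filter: %d of %d sets have > %d genes present",
        len(kept),
        len(sets),
        min_genes,
    )
    if len(kept) == 0:
        logger.warning("no pathways survived the membership filter")
    return kept


@dataclasses.dataclass
class PathwayPhenotypes:
    """K factor phenotypes per retained pathway.

    ``scores`` has samples as rows and a (pathway_id, factor_index)
    MultiIndex on columns; factor indices run 1..K in decreasing order of
    the variance each factor explains within its pathway. ``weights`` maps
    pathway id to its genes x K weight matrix, ``summary`` records
    n_genes_present and variance_explained per pathway.
    """

    scores: pd.DataFrame
    weights: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    k: int

    @property
    def n_phenotypes(self) -> int:
        return self.scores.shape[1]

    def phenotype_ids(self) -> list[tuple[str, int]]:
        return list(self.scores.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.scores.stack([0, 1], future_stack=True).rename("score").reset_index()
        long.columns = ["sample_id", "pathway_id", "factor_index", "score"]
        return long


def fit_pathway(
    residuals: ExpressionMatrix,
    gene_set: GeneSet,
    k: int = 5,
    **fit_kwargs,
) -> FactorFit:
    """Fit the K-factor model to one pathway's member-gene submatrix."""
    if residuals.n_samples < k + 2:
        raise ValidationError(
            f"pathway {gene_set.set_id!r}: {residuals.n_samples} samples "
            f"cannot support k={k}"
        )
    sub = residuals.subset_genes(list(gene_set.genes))
    return fit_factor_model(sub, covariates=None, k=k, **fit_kwargs)


def build_pathway_phenotypes(
    residuals: ExpressionMatrix,
    sets: GeneSetCollection,
    k: int = 5,
    **fit_kwargs,
) -> PathwayPhenotypes:
    """Fit K factors per pathway and collect the phenotype score vectors.

    Pathways are fitted independently (a pathway's phenotypes do not
    depend on which other pathways are in the collection); within each
    pathway, factors are ordered by variance explained, descending, ties
    broken by the fit's own factor order.
    """
    score_blocks: dict[tuple[str, int], np.ndarray] = {}
    weights: dict[str, pd.DataFrame] = {}
    rows = []
    for s in sets:
        fit = fit_pathway(residuals, s, k=k, **fit_kwargs)
        order = np.argsort(-fit.per_factor_variance, kind="stable")
        for rank, j in enumerate(order, start=1):
            score_blocks[(s.set_id, rank)] = fit.scores[:, j]
        weights[s.set_id] = pd.DataFrame(
            fit.weights[:, order],
            index=list(s.genes),
            columns=[f"factor{r}" for r in range(1, k + 1)],
        )
        rows.append(
            {
                "pathway_id": s.set_id,
                "n_genes_present": len(s.genes),
                "variance_explained": fit.variance_explained_total,
                "converged": fit.converged,
            }
        )
    if not rows:
        raise ValidationError("no pathways to fit")
    scores = pd.DataFrame(score_blocks, index=residuals.sample_ids)
    scores.columns = pd.MultiIndex.from_tuples(
        scores.columns, names=["pathway_id", "factor_index"]
    )
    summary = pd.DataFrame(rows).set_index("pathway_id")
    return PathwayPhenotypes(scores=scores, weights=weights, summary=summary, k=k)
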