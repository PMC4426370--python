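"""File formats and normalization.

Expression matrices and sample metadata travel as TSV, gene sets as
standard GMT. Normalization follows the two-stage scheme used for
replicate microarray designs: quantile-normalize technical replicates
within each individual, collapse to one profile per individual, then
quantile-normalize across individuals.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    COHORT_COLUMNS,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    TwinCohort,
    ValidationError,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file violated the expected layout."""


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write samples x genes TSV: header of gene ids, first column sample id."""
    df = matrix.data.copy()
    df.index.name = "sample_id"
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a samples x genes TSV written by :func:`write_expression`.

    Rejects duplicate ids, ragged rows, missing and non-numeric cells,
    naming the offending row or column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    gene_header = header[1:]
    seen: set[str] = set()
    dup_genes = []
    for g in gene_header:
        if g in seen:
            dup_genes.append(g)
        seen.add(g)
    if dup_genes:
        raise ParseError(f"{path}: duplicate gene ids {sorted(set(dup_genes))[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at sample "
            f"{df.index[i]!r}, gene {df.columns[j]!r}"
        )
    try:
        # astype(float) parses exactly (full round-trip precision)
        return ExpressionMatrix(df.astype(float))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Average columns sharing a gene id (probe -> gene collapse utility)."""
    if not df.columns.has_duplicates:
        return df
    n_before = df.shape[1]
    out = df.T.groupby(level=0, sort=False).mean().T
    logger.info(
        "collapsed %d duplicate-named columns to %d genes by mean",
        n_before,
        out.shape[1],
    )
    return out


# ---------------------------------------------------------------------------
# cohort metadata TSV
# ---------------------------------------------------------------------------

def write_cohort(cohort: TwinCohort, path: str | Path) -> None:
    df = cohort.samples.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_cohort(path: str | Path) -> TwinCohort:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    df["batch"] = df["batch"].astype(str)
    try:
        return TwinCohort(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members).

    Duplicate members within a line are stored once, with a warning.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            set_id, description, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicated members, deduplicated",
                    path,
                    lineno,
                    set_id,
                    len(members) - len(deduped),
                )
            collection.add(GeneSet(set_id, description, tuple(deduped)))
    return collection


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _quantile_normalize_rows(values: np.ndarray) -> np.ndarray:
    """Map each row onto the mean quantile profile (midrank ties)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n == 0 or p == 0:
        return values.copy()
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    grid = np.arange(1, p + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(values[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return out


def quantile_normalize(
    matrix: ExpressionMatrix,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
) -> ExpressionMatrix:
    """Two-stage quantile normalization.

    Stage 1: within each individual's replicate group, samples are
    quantile-normalized to the group's mean quantile profile and collapsed
    to one profile per individual (mean of the normalized replicates).
    Stage 2: the per-individual profiles are quantile-normalized across
    individuals. With no replicate groups stage 1 is the identity and the
    output keeps one row per input sample.

    After stage 2 every row shares the same sorted value vector (exactly,
    up to floating error, for tie-free data; tied values receive the mean
    of the reference quantiles they span).
    """
    values = matrix.values
    sample_pos = {s: i for i, s in enumerate(matrix.sample_ids)}

    if replicate_groups is None:
        replicate_groups = {s: [s] for s in matrix.sample_ids}

    assigned: list[str] = []
    for sample_list in replicate_groups.values():
        assigned.extend(sample_list)
    unknown = [s for s in assigned if s not in sample_pos]
    if unknown:
        raise ValidationError(f"replicate group references unknown samples: {unknown[:5]}")
    if sorted(assigned) != sorted(sample_pos):
        raise ValidationError(
            "every sample must be assigned to exactly one replicate group"
        )

    # stage 1: within-individual normalization + collapse
    profiles = []
    individuals = []
    for individual, sample_list in replicate_groups.items():
        rows = values[[sample_pos[s] for s in sample_list]]
        if rows.shape[0] > 1:
            rows = _quantile_normalize_rows(rows)
        profiles.append(rows.mean(axis=0))
        individuals.append(individual)
    stage1 = np.vstack(profiles)

    # stage 2: across-individual normalization
    stage2 = _quantile_normalize_rows(stage1)
    return ExpressionMatrix.from_arrays(stage2, individuals, matrix.gene_ids)


def drop_incomplete_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Pre-filter dropping genes with any missing entry (modelling needs a
    complete matrix)."""
    keep = df.notna().all(axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d genes with missing values", dropped)
    return df.loc[:, keep]
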