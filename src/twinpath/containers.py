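"""In-memory containers shared across the pipeline.

Three objects travel through every stage: the expression matrix
(samples x genes, log2 scale), the twin cohort roster (family structure,
zygosity, age, technical covariates), and the pathway gene-set collection.
All are thin, validated wrappers around pandas objects.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from collections.abc import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MZ = "MZ"
DZ = "DZ"
SINGLETON = "singleton"
ZYGOSITIES = (MZ, DZ, SINGLETON)

#: metadata columns required for every sample
COHORT_COLUMNS = (
    "individual_id",
    "family_id",
    "zygosity",
    "age",
    "batch",
    "rna_quality",
    "rna_concentration",
)


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Samples x genes matrix of log2 expression values.

    ``data`` is indexed by sample id with gene ids as columns. Ids must be
    unique and every value finite: the modelling stages assume a complete,
    post-QC matrix.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        sample_ids: Sequence[str],
        gene_ids: Sequence[str],
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        return cls(
            pd.DataFrame(values, index=list(sample_ids), columns=list(gene_ids))
        )

    # -- accessors --------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(gene_ids)].copy())

    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            bad = np.argwhere(~np.isfinite(vals.astype(float)))[0]
            raise ValidationError(
                "non-finite expression value at sample "
                f"{idx[bad[0]]!r}, gene {cols[bad[1]]!r}"
            )


@dataclasses.dataclass
class TwinCohort:
    """Sample roster for a twin cohort.

    ``samples`` is indexed by sample id and carries, per sample, the
    individual and family identifiers, zygosity (MZ / DZ / singleton), age
    in years, and the technical covariates (categorical batch, RNA quality,
    RNA concentration). Families of size two are twin pairs and must agree
    on zygosity and age; families of size one are singletons.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_families(self) -> int:
        return self.samples["family_id"].nunique()

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy(dtype=float)

    def zygosity_counts(self) -> dict[str, int]:
        return {z: int((self.samples["zygosity"] == z).sum()) for z in ZYGOSITIES}

    def family_units(self) -> dict[str, list[tuple[str, ...]]]:
        """Family units (tuples of row positions) grouped by stratum."""
        units: dict[str, list[tuple[str, ...]]] = {MZ: [], DZ: [], SINGLETON: []}
        fams = self.samples.groupby("family_id", sort=True)
        for _, grp in fams:
            zyg = grp["zygosity"].iloc[0]
            units[zyg].append(tuple(grp.index))
        return units

    def covariate_design(
        self, include_intercept: bool = True
    ) -> tuple[np.ndarray, list[str]]:
        """Technical-covariate design matrix: batch dummies + RNA measures."""
        parts: list[np.ndarray] = []
        names: list[str] = []
        if include_intercept:
            parts.append(np.ones((len(self.samples), 1)))
            names.append("intercept")
        batch = pd.get_dummies(
            self.samples["batch"].astype(str), prefix="batch", drop_first=True
        )
        if batch.shape[1]:
            parts.append(batch.to_numpy(dtype=float))
            names.extend(batch.columns.tolist())
        for col in ("rna_quality", "rna_concentration"):
            v = self.samples[col].to_numpy(dtype=float)
            parts.append((v - v.mean())[:, None])
            names.append(col)
        return np.hstack(parts), names

    def reindex(self, sample_ids: Sequence[str]) -> "TwinCohort":
        missing = [s for s in sample_ids if s not in self.samples.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return TwinCohort(self.samples.loc[list(sample_ids)].copy())

    def validate(self) -> None:
        df = self.samples
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"cohort missing columns: {missing_cols}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in cohort")
        bad_zyg = set(df["zygosity"].unique()) - set(ZYGOSITIES)
        if bad_zyg:
            raise ValidationError(f"unknown zygosity labels: {sorted(bad_zyg)}")
        ages = df["age"].to_numpy(dtype=float)
        if not np.isfinite(ages).all():
            raise ValidationError("non-finite ages")
        for fam, grp in df.groupby("family_id"):
            if len(grp) > 2:
                raise ValidationError(f"family {fam!r} has {len(grp)} members (max 2)")
            if len(grp) == 2:
                if grp["zygosity"].nunique() != 1:
                    raise ValidationError(f"family {fam!r}: zygosity labels disagree")
                if grp["zygosity"].iloc[0] == SINGLETON:
                    raise ValidationError(
                        f"family {fam!r}: two members labelled singleton"
                    )
                if grp["age"].nunique() != 1:
                    raise ValidationError(f"family {fam!r}: co-twin ages differ")
            elif grp["zygosity"].iloc[0] != SINGLETON:
                raise ValidationError(
                    f"family {fam!r}: lone member must be labelled singleton"
                )


@dataclasses.dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Ordered collection of gene sets (e.g. KEGG pathways from a GMT file)."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: "OrderedDict[str, GeneSet]" = OrderedDict()
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self._sets:
            raise ValidationError(f"duplicate set id {gene_set.set_id!r}")
        if not gene_set.genes:
            raise ValidationError(f"set {gene_set.set_id!r} has no members")
        if len(set(gene_set.genes)) != len(gene_set.genes):
            raise ValidationError(f"set {gene_set.set_id!r} has duplicate members")
        self._sets[gene_set.set_id] = gene_set

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, tuple[str, Sequence[str]]]
    ) -> "GeneSetCollection":
        return cls(
            GeneSet(set_id, desc, tuple(genes))
            for set_id, (desc, genes) in mapping.items()
        )

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def set_ids(self) -> list[str]:
        return list(self._sets)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out.update(s.genes)
        return out
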