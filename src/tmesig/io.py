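"""Expression matrices, sample annotations and gene-set collections: read,
validate, align, write.

All tabular formats are TSV (UTF-8, header row). Expression matrices are
stored genes × samples with the first column header ``gene_id`` and values
on the raw (unlogged) abundance scale; transforms are explicit downstream.
Missing values are a hard error — no imputation rule is defined anywhere in
the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_gmt",
    "write_gmt",
    "align_cohort",
]


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense non-negative gene × sample abundance matrix.

    Invariants (enforced at construction): unique gene and sample ids,
    all values finite and >= 0, at least 2 genes and 2 samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __init__(self, gene_ids: Iterable[str], sample_ids: Iterable[str], values: np.ndarray):
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        values = np.array(values, dtype=float)  # copy: frozen below
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"value shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        dup = _find_duplicates(gene_ids)
        if dup:
            raise ValueError(f"duplicate gene identifier(s): {', '.join(dup)}")
        dup = _find_duplicates(sample_ids)
        if dup:
            raise ValueError(f"duplicate sample identifier(s): {', '.join(dup)}")
        if len(gene_ids) < 2 or len(sample_ids) < 2:
            raise ValueError("expression matrix needs at least 2 genes and 2 samples")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        values.flags.writeable = False
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> pd.Series:
        """Expression of one gene as a Series indexed by sample id."""
        return pd.Series(self.values[self.gene_index(gene)], index=list(self.sample_ids), name=gene)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"sample(s) not in matrix: {', '.join(missing[:5])}")
        idx = [pos[s] for s in wanted]
        return ExpressionMatrix(self.gene_ids, wanted, self.values[:, idx].copy())

    def drop_gene(self, gene: str) -> "ExpressionMatrix":
        i = self.gene_index(gene)
        keep = [g for g in self.gene_ids if g != gene]
        return ExpressionMatrix(keep, self.sample_ids, np.delete(self.values, i, axis=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))
        df.index.name = "gene_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class SampleAnnotation:
    """Mapping sample id → cohort entity label."""

    entities: pd.Series = field(repr=False)

    def __init__(self, entities: pd.Series | Mapping[str, str]):
        s = pd.Series(entities, dtype=str)
        s.index = s.index.astype(str)
        s.index.name = "sample_id"
        s.name = "entity"
        dup = _find_duplicates(s.index)
        if dup:
            raise ValueError(f"duplicate sample identifier(s) in annotation: {', '.join(dup)}")
        if len(s) == 0:
            raise ValueError("annotation is empty")
        object.__setattr__(self, "entities", s)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.entities.index)

    @property
    def entity_names(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.entities))

    def entity_of(self, sample_id: str) -> str:
        return str(self.entities.loc[sample_id])

    def entity_sizes(self) -> pd.Series:
        return self.entities.value_counts()

    def samples_of(self, entity: str) -> list[str]:
        return list(self.entities.index[self.entities == entity])

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.entities.loc[list(sample_ids)])


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: set_name → (description, frozenset of member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __init__(self, sets: Mapping[str, tuple[str, Iterable[str]]]):
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, members) in sets.items():
            members = frozenset(str(m) for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = (str(desc), members)
        if not clean:
            raise ValueError("gene-set collection is empty")
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers


def read_expression_tsv(path: str | Path, orientation: str = "genes_rows") -> ExpressionMatrix:
    """Read an expression TSV into a validated :class:`ExpressionMatrix`.

    The first column holds identifiers; all other cells must be numeric and
    non-negative. ``orientation`` says what the rows are; the result is
    always genes × samples.
    """
    if orientation not in ("genes_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ValueError(f"missing value at row {row!r}, column {col!r} in {path}")
    try:
        num = df.astype(float)
    except ValueError:
        for r in df.index:
            for c in df.columns:
                try:
                    float(df.at[r, c])
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {df.at[r, c]!r} at row {r!r}, column {c!r} in {path}"
                    ) from None
        raise
    if orientation == "samples_rows":
        num = num.T
    return ExpressionMatrix.from_frame(num)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV with columns ``sample_id`` and ``entity``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "entity"):
        if col not in df.columns:
            raise ValueError(f"annotation {path} lacks required column {col!r}")
    return SampleAnnotation(pd.Series(df["entity"].values, index=df["sample_id"].values))


def write_annotation_tsv(ann: SampleAnnotation, path: str | Path) -> None:
    ann.entities.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member+, one set per line).

    Duplicate members within a set are de-duplicated; a line with fewer than
    three fields is a hard error naming the line number.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, set(m for m in members if m))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection:
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Cohort alignment


def align_cohort(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    min_entity_size: int = 60,
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Intersect matrix and annotation samples, then drop entities with
    fewer than ``min_entity_size`` samples (inclusive threshold: an entity
    of exactly ``min_entity_size`` is retained).
    """
    if min_entity_size < 1:
        raise ValueError("min_entity_size must be a positive integer")
    ann_set = set(ann.sample_ids)
    shared = [s for s in expr.sample_ids if s in ann_set]
    if not shared:
        raise ValueError("no samples shared between expression matrix and annotation")
    sub_ann = ann.subset(shared)
    sizes = sub_ann.entity_sizes()
    keep_entities = set(sizes.index[sizes >= min_entity_size])
    dropped = sorted(set(sizes.index) - keep_entities)
    if dropped:
        logger.info(
            "align_cohort: dropping %d entit%s below %d samples: %s",
            len(dropped), "y" if len(dropped) == 1 else "ies", min_entity_size,
            ", ".join(f"{e} (n={sizes[e]})" for e in dropped),
        )
    kept = [s for s in shared if sub_ann.entity_of(s) in keep_entities]
    if not kept:
        raise ValueError(f"no entity reaches min_entity_size={min_entity_size}")
    return expr.subset_samples(kept), sub_ann.subset(kept)
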