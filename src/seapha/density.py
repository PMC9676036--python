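"""Gene-density matrices and per-algal-class summaries.

"Density" here is the raw occurrence count of a gene label per entity (a
genome, or a taxonomic family after aggregation) — not a per-Mb rate.
Duplicate (genome_id, gene_id, label) rows count once; a gene carrying two
distinct labels (e.g. two CAZyme modules) counts once per label.

Two class-level views are derived from a density matrix:

* unique class counts — how many *distinct* scheme families of one algal
  class are present in an entity; this drives all enrichment thresholds.
* class gene density — the summed occurrence count over a class's labels.

A label shared between classes (GH3: green and brown) contributes to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import AlgalClassScheme, GeneAnnotation
from .taxonomy import UNKNOWN_FAMILY, TaxonomyDB, family_of

__all__ = [
    "DensityMatrix",
    "ClassDensitySummary",
    "build_density",
    "unique_class_counts",
    "class_gene_density",
    "log2_normalize",
    "summarize_class",
]

#: Row id used for genomes whose taxid resolves to no family rank.
UNKNOWN_ENTITY = "UNKNOWN"


@dataclass
class DensityMatrix:
    """Entity × gene-label occurrence counts.

    ``counts`` is an integer DataFrame with entity ids (genome ids, or family
    taxids as strings) on the index and gene labels on the columns.
    """

    counts: pd.DataFrame
    level: str  # "genome" | "family"

    def __post_init__(self) -> None:
        if self.level not in ("genome", "family"):
            raise ValueError(f"level must be 'genome' or 'family', got {self.level!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("density counts must be non-negative")

    @property
    def entities(self) -> list[str]:
        return list(self.counts.index)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    def drop_unknown(self) -> "DensityMatrix":
        """Family-level matrix without the UNKNOWN row (for reports)."""
        if UNKNOWN_ENTITY in self.counts.index:
            return DensityMatrix(self.counts.drop(index=UNKNOWN_ENTITY), self.level)
        return self

    def to_frame(self) -> pd.DataFrame:
        return self.counts

    def to_long(self) -> pd.DataFrame:
        """Long-format (entity, label, count) table, zero rows omitted."""
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .set_axis(["entity", "label", "count"], axis=1)
        )
        return long[long["count"] > 0].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("entity").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, level: str) -> "DensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(counts=df.astype(int), level=level)


def build_density(
    annotations: Iterable[GeneAnnotation],
    level: str = "genome",
    taxonomy: TaxonomyDB | None = None,
    genome_taxids: dict[str, int] | None = None,
    all_entities: Sequence[str] | None = None,
) -> DensityMatrix:
    """Count label occurrences per genome, optionally aggregated to family.

    ``level="family"`` requires ``taxonomy`` and a ``genome_taxids`` map;
    genomes with no family-rank ancestor are routed to the ``UNKNOWN`` row.
    ``all_entities`` adds all-zero rows for listed entities with no
    annotations (e.g. genomes known only from metadata).
    """
    if level not in ("genome", "family"):
        raise ValueError(f"level must be 'genome' or 'family', got {level!r}")
    if level == "family" and (taxonomy is None or genome_taxids is None):
        raise ValueError("family-level aggregation requires taxonomy and genome_taxids")

    seen: set[tuple[str, str, str]] = set()
    tally: dict[tuple[str, str], int] = {}
    entities: list[str] = []
    labels: list[str] = []
    for a in annotations:
        key = (a.genome_id, a.gene_id, a.label)
        if key in seen:  # duplicate annotation rows count once
            continue
        seen.add(key)
        if level == "family":
            taxid = genome_taxids.get(a.genome_id)
            fam = UNKNOWN_FAMILY if taxid is None else family_of(taxonomy, taxid)
            entity = UNKNOWN_ENTITY if fam == UNKNOWN_FAMILY else str(fam)
        else:
            entity = a.genome_id
        k = (entity, a.label)
        if k not in tally:
            if entity not in entities:
                entities.append(entity)
            if a.label not in labels:
                labels.append(a.label)
        tally[k] = tally.get(k, 0) + 1

    if all_entities is not None:
        for e in all_entities:
            e = str(e)
            if e not in entities:
                entities.append(e)

    counts = pd.DataFrame(0, index=pd.Index(entities, dtype=object), columns=labels, dtype=int)
    for (e, l), c in tally.items():
        counts.loc[e, l] = c
    return DensityMatrix(counts=counts, level=level)


def unique_class_counts(matrix: DensityMatrix, scheme: AlgalClassScheme) -> pd.DataFrame:
    """Per-entity count of distinct in-scheme labels present, per algal class.

    Columns ``u_green, u_brown, u_red``; a label belonging to two classes
    increments both.
    """
    present = matrix.counts > 0
    out = {}
    for c in scheme.CLASSES:
        cols = [l for l in matrix.labels if l in scheme.labels_for(c)]
        out[f"u_{c}"] = present[cols].sum(axis=1) if cols else pd.Series(0, index=present.index)
    return pd.DataFrame(out, index=matrix.counts.index).astype(int)


def class_gene_density(matrix: DensityMatrix, scheme: AlgalClassScheme) -> pd.DataFrame:
    """Per-entity summed occurrence count per class (``d_green, d_brown, d_red``).

    Shared labels are double-counted into every class containing them.
    """
    out = {}
    for c in scheme.CLASSES:
        cols = [l for l in matrix.labels if l in scheme.labels_for(c)]
        out[f"d_{c}"] = (
            matrix.counts[cols].sum(axis=1) if cols else pd.Series(0, index=matrix.counts.index)
        )
    return pd.DataFrame(out, index=matrix.counts.index).astype(int)


def log2_normalize(matrix: DensityMatrix | pd.DataFrame) -> pd.DataFrame:
    """log2(count + 1) transform; 0 -> 0, strictly monotone in count."""
    df = matrix.to_frame() if isinstance(matrix, DensityMatrix) else matrix
    return np.log2(df.astype(float) + 1.0)


@dataclass(frozen=True)
class ClassDensitySummary:
    """Cohort summary of one class's gene density: mean ± dispersion over entities.

    ``sem`` (standard error of the mean) is the primary dispersion; the
    sample standard deviation is also carried since published mean±x
    notation is ambiguous between the two.
    """

    algal_class: str
    mean: float
    sem: float
    sd: float
    n_entities: int


def summarize_class(
    matrix: DensityMatrix, scheme: AlgalClassScheme, algal_class: str
) -> ClassDensitySummary:
    """Mean ± SEM of per-entity class gene density."""
    if matrix.counts.shape[0] == 0:
        raise ValueError("cannot summarize an empty density matrix")
    d = class_gene_density(matrix, scheme)[f"d_{algal_class}"].to_numpy(dtype=float)
    n = d.size
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    return ClassDensitySummary(
        algal_class=algal_class,
        mean=float(np.mean(d)),
        sem=sd / np.sqrt(n) if n > 1 else 0.0,
        sd=sd,
        n_entities=int(n),
    )
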