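"""Strict readers and writers for every external table the pipeline touches.

The canonical table dialect everywhere is TSV (tab-separated, UTF-8, one
header row), matching the output conventions of the annotation/quality tools
whose tables this pipeline consumes.  Readers are dialect-strict: malformed
rows are rejected (collected or raised), never silently coerced, and
``total rows = accepted + rejected`` always holds.

Also houses the two reference mappings the screen is built on:

* :class:`AlgalClassScheme` — CAZy families used as proxies for degrading the
  cell-wall polysaccharides of green (ulvan), brown (alginate/laminarin/
  fucoidan) and red (agar/agarose/carrageenan/porphyran) macroalgae.  Sets may
  overlap: GH2/GH3-type broad-specificity hydrolases act on more than one
  substrate class (GH3 appears under both green and brown).
* :class:`PhaGeneCatalog` — PHA-related genes with their functional role
  (synthase, monomer synthesis, phasin, regulator, depolymerase) and, for
  monomer-synthesis genes, the hydroxyacyl-CoA monomer(s) they supply.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CAZY_LABEL_RE",
    "Category",
    "GeneAnnotation",
    "GenomeMetadata",
    "AlgalClassScheme",
    "PhaRole",
    "Monomer",
    "CatalogEntry",
    "PhaGeneCatalog",
    "SchemaError",
    "RowValidationError",
    "AnnotationTable",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "write_candidates",
    "read_candidates",
    "write_itol_heatmap",
    "write_newick",
]

#: A CAZy family label: GH/PL class, family number, optional _subfamily.
#: A bare "GH16" is a different label from "GH16_3" and never matches a
#: subfamily-specific scheme entry.
CAZY_LABEL_RE = re.compile(r"^(GH|PL)[0-9]+(_[0-9]+)?$")


class Category(str, Enum):
    """Annotation category: CAZyme family label or PHA gene name."""

    CAZYME = "cazyme"
    PHA = "pha"


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed as TSV."""


class RowValidationError(ValueError):
    """One or more rows violate a domain invariant.

    Attributes
    ----------
    rows : list of (row_index, reason)
        0-based data-row indices (header excluded) with the failure reason.
    """

    def __init__(self, message: str, rows: list[tuple[int, str]]):
        super().__init__(message)
        self.rows = rows


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene call in one genome.

    ``position`` is an optional 0-based base offset, used only for
    architecture-style exports.
    """

    genome_id: str
    gene_id: str
    label: str
    category: Category
    position: int | None = None


@dataclass(frozen=True)
class GenomeMetadata:
    """Assembly/taxonomy metadata for one genome.

    ``completeness`` and ``contamination`` are percentages; ``marker_count``
    is the number of universal bacterial marker genes found (0..31).
    """

    genome_id: str
    taxid: int
    isolation_source: str
    n50: int
    completeness: float
    contamination: float
    marker_count: int


def expected_category(label: str) -> Category:
    """Category implied by the label syntax (CAZy-shaped labels are CAZymes)."""
    return Category.CAZYME if CAZY_LABEL_RE.match(label) else Category.PHA


# --------------------------------------------------------------------------
# Algal class scheme
# --------------------------------------------------------------------------

_GREEN = (
    "GH2", "GH3", "GH39", "GH43", "GH78", "GH88", "GH105",
    "PL24", "PL25", "PL28",
)
_BROWN = (
    "GH107", "GH16_3", "GH17", "GH29", "GH3", "GH30", "GH95",
    "PL14", "PL15", "PL17", "PL18", "PL31", "PL39", "PL5", "PL6", "PL7",
)
_RED = (
    "GH117", "GH118", "GH127", "GH129", "GH167",
    "GH16_12", "GH16_13", "GH16_16",
    "GH50", "GH82", "GH86", "GH96",
)


@dataclass(frozen=True)
class AlgalClassScheme:
    """CAZy family labels grouped by the macroalgal class they act on."""

    green: frozenset[str]
    brown: frozenset[str]
    red: frozenset[str]

    CLASSES = ("green", "brown", "red")

    @classmethod
    def default(cls) -> "AlgalClassScheme":
        """The core SPD proxy-enzyme scheme (GH3 is in green and brown)."""
        return cls(green=frozenset(_GREEN), brown=frozenset(_BROWN), red=frozenset(_RED))

    def labels_for(self, algal_class: str) -> frozenset[str]:
        if algal_class not in self.CLASSES:
            raise KeyError(f"unknown algal class: {algal_class!r}")
        return getattr(self, algal_class)

    @property
    def all_labels(self) -> frozenset[str]:
        return self.green | self.brown | self.red

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlgalClassScheme":
        """Read a ``label<TAB>class`` table (one row per label/class pair)."""
        df = _read_tsv(path, required=["label", "class"])
        sets: dict[str, set[str]] = {c: set() for c in cls.CLASSES}
        bad = [
            (int(i), f"unknown class {row['class']!r}")
            for i, row in df.iterrows()
            if row["class"] not in sets
        ]
        if bad:
            raise RowValidationError(f"{path}: invalid scheme rows", bad)
        for _, row in df.iterrows():
            sets[row["class"]].add(str(row["label"]))
        return cls(**{c: frozenset(v) for c, v in sets.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"label": lab, "class": c}
            for c in self.CLASSES
            for lab in sorted(self.labels_for(c))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# PHA gene catalog
# --------------------------------------------------------------------------


class PhaRole(str, Enum):
    SYNTHASE = "synthase"
    MONOMER_SYNTHESIS = "monomer_synthesis"
    PHASIN = "phasin"
    REGULATOR = "regulator"
    DEPOLYMERASE = "depolymerase"


class Monomer(str, Enum):
    """Hydroxyacyl-CoA monomers polymerizable into PHA."""

    HB3 = "3HB-CoA"   # 3-hydroxybutyryl-CoA
    HV3 = "3HV-CoA"   # 3-hydroxyvaleryl-CoA
    R3HA = "R3HA-CoA"  # (R)-3-hydroxyacyl-CoA
    HB4 = "4HB-CoA"   # 4-hydroxybutyryl-CoA
    HP3 = "3HP-CoA"   # 3-hydroxypropionyl-CoA


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    role: PhaRole
    monomers: frozenset[Monomer] = frozenset()


# gene -> (role, monomers).  Monomer-synthesis genes map to the monomer(s)
# whose biosynthesis they catalyse; Pct acts on both 4HB and 3HP substrates.
_DEFAULT_CATALOG: tuple[tuple[str, PhaRole, tuple[Monomer, ...]], ...] = (
    ("PhaC", PhaRole.SYNTHASE, ()),
    ("PhaC2", PhaRole.SYNTHASE, ()),
    ("PhaE", PhaRole.SYNTHASE, ()),
    ("PhaA", PhaRole.MONOMER_SYNTHESIS, (Monomer.HB3,)),
    ("PhaB", PhaRole.MONOMER_SYNTHESIS, (Monomer.HB3, Monomer.HV3)),
    ("FabG", PhaRole.MONOMER_SYNTHESIS, (Monomer.R3HA,)),
    ("PhaG", PhaRole.MONOMER_SYNTHESIS, (Monomer.R3HA,)),
    ("PhaJ", PhaRole.MONOMER_SYNTHESIS, (Monomer.R3HA,)),
    ("maoC", PhaRole.MONOMER_SYNTHESIS, (Monomer.R3HA,)),
    ("Cat2", PhaRole.MONOMER_SYNTHESIS, (Monomer.HB4,)),
    ("HadA", PhaRole.MONOMER_SYNTHESIS, (Monomer.HB4,)),
    ("Pct", PhaRole.MONOMER_SYNTHESIS, (Monomer.HB4, Monomer.HP3)),
    ("Pcs", PhaRole.MONOMER_SYNTHESIS, (Monomer.HP3,)),
    ("PrpE", PhaRole.MONOMER_SYNTHESIS, (Monomer.HP3,)),
    ("PduP", PhaRole.MONOMER_SYNTHESIS, (Monomer.HP3,)),
    ("PhaF", PhaRole.PHASIN, ()),
    ("PhaI", PhaRole.PHASIN, ()),
    ("PhaP", PhaRole.PHASIN, ()),
    ("PhaD", PhaRole.REGULATOR, ()),
    ("PhaQ", PhaRole.REGULATOR, ()),
    ("PhaR", PhaRole.REGULATOR, ()),
    ("PhaZ", PhaRole.DEPOLYMERASE, ()),
)


@dataclass(frozen=True)
class PhaGeneCatalog:
    """PHA gene → role and producible monomer(s)."""

    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        bad = [
            e.gene
            for e in self.entries
            if e.monomers and e.role is not PhaRole.MONOMER_SYNTHESIS
        ]
        if bad:
            raise ValueError(
                f"monomers only allowed on monomer_synthesis entries: {bad}"
            )

    @classmethod
    def default(cls) -> "PhaGeneCatalog":
        return cls(
            entries=tuple(
                CatalogEntry(g, r, frozenset(m)) for g, r, m in _DEFAULT_CATALOG
            )
        )

    def genes_with_role(self, role: PhaRole) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries if e.role is role)

    @property
    def synthases(self) -> frozenset[str]:
        return self.genes_with_role(PhaRole.SYNTHASE)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries)

    def monomers_of(self, gene: str) -> frozenset[Monomer]:
        for e in self.entries:
            if e.gene == gene:
                return e.monomers
        raise KeyError(gene)

    def role_of(self, gene: str) -> PhaRole:
        for e in self.entries:
            if e.gene == gene:
                return e.role
        raise KeyError(gene)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhaGeneCatalog":
        """Read a ``gene<TAB>role<TAB>monomers`` table (monomers comma-separated)."""
        df = _read_tsv(path, required=["gene", "role", "monomers"])
        entries = []
        bad: list[tuple[int, str]] = []
        for i, row in df.iterrows():
            try:
                role = PhaRole(row["role"])
                raw = "" if pd.isna(row["monomers"]) else str(row["monomers"])
                monomers = frozenset(
                    Monomer(m.strip()) for m in raw.split(",") if m.strip()
                )
            except ValueError as exc:
                bad.append((int(i), str(exc)))
                continue
            entries.append(CatalogEntry(str(row["gene"]), role, monomers))
        if bad:
            raise RowValidationError(f"{path}: invalid catalog rows", bad)
        return cls(entries=tuple(entries))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene": e.gene,
                "role": e.role.value,
                "monomers": ",".join(sorted(m.value for m in e.monomers)),
            }
            for e in self.entries
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: cannot read TSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


ANNOTATION_COLUMNS = ("genome_id", "gene_id", "label", "category")


@dataclass
class AnnotationTable:
    """Parsed annotation table with per-row reject accounting."""

    annotations: list[GeneAnnotation]
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.annotations)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_annotations(
    path: str | Path, *, on_error: str = "raise"
) -> AnnotationTable:
    """Read a gene-annotation TSV.

    Columns: ``genome_id  gene_id  label  category  position(optional)``.
    ``category`` must be consistent with the label syntax (a CAZy-shaped
    label is ``cazyme``, anything else ``pha``); (genome_id, gene_id, label)
    triples must be unique.  With ``on_error="raise"`` any invalid row raises
    :class:`RowValidationError`; with ``"collect"`` invalid rows are reported
    in ``rejected`` and valid rows kept in original order.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    df = _read_tsv(path, required=ANNOTATION_COLUMNS)
    has_pos = "position" in df.columns

    annotations: list[GeneAnnotation] = []
    rejected: list[tuple[int, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        genome_id = str(row.genome_id).strip()
        gene_id = str(row.gene_id).strip()
        label = str(row.label).strip()
        cat_raw = str(row.category).strip()
        reason = None
        if not genome_id or not gene_id:
            reason = "empty genome_id or gene_id"
        elif not label:
            reason = "empty label"
        elif cat_raw not in (c.value for c in Category):
            reason = f"unknown category {cat_raw!r}"
        elif Category(cat_raw) is not expected_category(label):
            reason = (
                f"category {cat_raw!r} contradicts label {label!r} "
                f"(expected {expected_category(label).value!r})"
            )
        elif (genome_id, gene_id, label) in seen:
            reason = "duplicate (genome_id, gene_id, label)"
        position: int | None = None
        if reason is None and has_pos:
            raw = str(row.position).strip()
            if raw:
                try:
                    position = int(raw)
                except ValueError:
                    reason = f"non-integer position {raw!r}"
                else:
                    if position < 0:
                        reason = f"negative position {position}"
        if reason is not None:
            rejected.append((i, reason))
            continue
        seen.add((genome_id, gene_id, label))
        annotations.append(
            GeneAnnotation(genome_id, gene_id, label, Category(cat_raw), position)
        )
    if rejected and on_error == "raise":
        raise RowValidationError(
            f"{path}: {len(rejected)} invalid annotation row(s)", rejected
        )
    return AnnotationTable(annotations=annotations, rejected=rejected)


def write_annotations(
    annotations: Iterable[GeneAnnotation], path: str | Path
) -> None:
    rows = []
    any_pos = False
    for a in annotations:
        rows.append(
            {
                "genome_id": a.genome_id,
                "gene_id": a.gene_id,
                "label": a.label,
                "category": a.category.value,
                "position": "" if a.position is None else a.position,
            }
        )
        any_pos = any_pos or a.position is not None
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS) + ["position"])
    if not any_pos:
        df = df.drop(columns=["position"])
    df.to_csv(path, sep="\t", index=False)


METADATA_COLUMNS = (
    "genome_id",
    "taxid",
    "isolation_source",
    "n50",
    "completeness",
    "contamination",
    "marker_count",
)


def read_metadata(
    path: str | Path, *, on_error: str = "raise"
) -> list[GenomeMetadata]:
    """Read a genome-metadata TSV; empty isolation sources are preserved."""
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    df = _read_tsv(path, required=METADATA_COLUMNS)
    records: list[GenomeMetadata] = []
    rejected: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        genome_id = str(row.genome_id).strip()
        reason = None
        taxid = n50 = marker = 0
        completeness = contamination = 0.0
        try:
            taxid = int(str(row.taxid))
            n50 = int(str(row.n50))
            completeness = float(str(row.completeness))
            contamination = float(str(row.contamination))
            marker = int(str(row.marker_count))
        except ValueError as exc:
            reason = f"unparseable numeric field: {exc}"
        if reason is None:
            if not genome_id:
                reason = "empty genome_id"
            elif genome_id in seen_ids:
                reason = f"duplicate genome_id {genome_id!r}"
            elif not 0.0 <= completeness <= 100.0:
                reason = f"completeness {completeness} outside [0, 100]"
            elif contamination < 0.0:
                reason = f"negative contamination {contamination}"
            elif n50 < 0:
                reason = f"negative n50 {n50}"
            elif not 0 <= marker <= 31:
                reason = f"marker_count {marker} outside [0, 31]"
        if reason is not None:
            rejected.append((i, reason))
            continue
        seen_ids.add(genome_id)
        records.append(
            GenomeMetadata(
                genome_id=genome_id,
                taxid=taxid,
                isolation_source=str(row.isolation_source),
                n50=n50,
                completeness=completeness,
                contamination=contamination,
                marker_count=marker,
            )
        )
    if rejected and on_error == "raise":
        raise RowValidationError(
            f"{path}: {len(rejected)} invalid metadata row(s)", rejected
        )
    return records


def write_metadata(records: Iterable[GenomeMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "genome_id": m.genome_id,
                "taxid": m.taxid,
                "isolation_source": m.isolation_source,
                "n50": m.n50,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "marker_count": m.marker_count,
            }
            for m in records
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Candidate-tier, iTOL and Newick exports
# --------------------------------------------------------------------------


def write_candidates(tiers, path: str | Path) -> None:
    """Write per-genome tier membership as a boolean TSV (round-trippable).

    One row per genome that reached at least the polymerase-positive tier;
    columns are the nested genome tiers plus one ``top_<class>`` column per
    algal class.
    """
    classes = sorted(tiers.top_percentile)
    rows = []
    for g in sorted(tiers.polymerase_positive):
        row = {
            "genome_id": g,
            "polymerase_positive": True,
            "spd_positive": g in tiers.spd_positive,
            "enriched": g in tiers.enriched,
            "highly_enriched": g in tiers.highly_enriched,
        }
        for c in classes:
            row[f"top_{c}"] = g in tiers.top_percentile[c]
        rows.append(row)
    cols = [
        "genome_id",
        "polymerase_positive",
        "spd_positive",
        "enriched",
        "highly_enriched",
    ] + [f"top_{c}" for c in classes]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> dict[str, set[str]]:
    """Read a candidate table back into ``tier name -> set of genome ids``."""
    df = _read_tsv(path, required=["genome_id"])
    out: dict[str, set[str]] = {}
    for col in df.columns:
        if col == "genome_id":
            continue
        out[col] = set(df.loc[df[col] == "True", "genome_id"])
    return out


def write_itol_heatmap(matrix, path: str | Path, *, dataset_label: str = "gene density") -> None:
    """Export a density matrix as an iTOL-style plain-text heatmap dataset.

    Header block (SEPARATOR/DATASET_LABEL/FIELD_LABELS) followed by one
    data row per entity: ``entity<TAB>v1<TAB>v2...``.
    """
    df = matrix.to_frame() if hasattr(matrix, "to_frame") else matrix
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("DATASET_HEATMAP\n")
        fh.write("SEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\t{dataset_label}\n")
        fh.write("COLOR\t#1f78b4\n")
        fh.write("FIELD_LABELS\t" + "\t".join(str(c) for c in df.columns) + "\n")
        fh.write("DATA\n")
        for entity, row in df.iterrows():
            fh.write(str(entity) + "\t" + "\t".join(str(v) for v in row) + "\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a taxon tree (or bare ``skbio.TreeNode``) as Newick."""
    node = getattr(tree, "tree", tree)
    node.write(str(path), format="newick")
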