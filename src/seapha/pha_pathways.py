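"""Per-genome PHA monomer-pathway resolution from the gene catalog.

Presence/absence logic only: a genome can produce a monomer iff it carries at
least one monomer-synthesis gene mapped to that monomer.  A genome with a
PHA synthase but no recognizable monomer-supply gene is flagged
``unresolved`` — polymerase present, pathway undiscernible.

The gene→monomer map is the catalog default:
{PhaA, PhaB}→3HB-CoA; PhaB→3HV-CoA; {FabG, PhaG, PhaJ, maoC}→(R)-3HA-CoA;
{Cat2, HadA, Pct}→4HB-CoA; {Pct, Pcs, PrpE, PduP}→3HP-CoA.  FabG-mediated
3HB-CoA supply, discussed in the literature but outside the formal map, is
available behind ``fabg_also_3hb``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .tables_io import Monomer, PhaGeneCatalog, PhaRole
from .taxonomy import UNKNOWN_FAMILY, TaxonomyDB, family_of

__all__ = ["PathwayProfile", "resolve_pathways", "cohort_pathway_summary"]


@dataclass
class PathwayProfile:
    """Resolved PHA biosynthesis capability of one genome."""

    genome_id: str
    synthases_present: frozenset[str]
    monomers: frozenset[Monomer]
    monomer_genes: frozenset[str]
    phasins: frozenset[str]
    regulators: frozenset[str]
    depolymerases: frozenset[str]

    @property
    def unresolved(self) -> bool:
        """Synthase present but no monomer-supply pathway discernible."""
        return bool(self.synthases_present) and not self.monomers

    @property
    def class_iii_possible(self) -> bool:
        """Class III synthases are two-subunit (PhaC + PhaE) enzymes."""
        return {"PhaC", "PhaE"} <= self.synthases_present


def resolve_pathways(
    genome_id: str,
    labels: Iterable[str],
    catalog: PhaGeneCatalog | None = None,
    *,
    fabg_also_3hb: bool = False,
) -> PathwayProfile:
    """Resolve synthases, producible monomers and accessory genes of a genome.

    Labels not in the catalog (CAZy labels, typos) are ignored; an
    unrecognized PHA-shaped label triggers a warning, not an error.
    """
    catalog = catalog or PhaGeneCatalog.default()
    present = set(labels)
    known = present & catalog.genes
    unknown_pha = {
        l for l in present - known
        if not l[:2] in ("GH", "PL") and l[:3].lower() == "pha"
    }
    if unknown_pha:
        warnings.warn(
            f"{genome_id}: unrecognized PHA-like label(s) ignored: {sorted(unknown_pha)}",
            stacklevel=2,
        )

    monomer_genes = known & catalog.genes_with_role(PhaRole.MONOMER_SYNTHESIS)
    monomers: set[Monomer] = set()
    for g in monomer_genes:
        monomers |= catalog.monomers_of(g)
    if fabg_also_3hb and "FabG" in monomer_genes:
        monomers.add(Monomer.HB3)

    return PathwayProfile(
        genome_id=genome_id,
        synthases_present=frozenset(known & catalog.synthases),
        monomers=frozenset(monomers),
        monomer_genes=frozenset(monomer_genes),
        phasins=frozenset(known & catalog.genes_with_role(PhaRole.PHASIN)),
        regulators=frozenset(known & catalog.genes_with_role(PhaRole.REGULATOR)),
        depolymerases=frozenset(known & catalog.genes_with_role(PhaRole.DEPOLYMERASE)),
    )


def cohort_pathway_summary(
    profiles: Iterable[PathwayProfile],
    taxonomy: TaxonomyDB | None = None,
    genome_taxids: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-family prevalence of each PHA gene, each monomer, and unresolved genomes.

    Without a taxonomy all genomes are pooled under family id ``ALL``.
    Genomes with no family rank are pooled under ``UNKNOWN``.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cohort_pathway_summary requires at least one profile")

    def fam(g: str) -> str:
        if taxonomy is None or genome_taxids is None:
            return "ALL"
        taxid = genome_taxids.get(g)
        f = UNKNOWN_FAMILY if taxid is None else family_of(taxonomy, taxid)
        return "UNKNOWN" if f == UNKNOWN_FAMILY else str(f)

    rows: dict[str, dict[str, float]] = {}
    for p in profiles:
        r = rows.setdefault(fam(p.genome_id), {})
        r["n_genomes"] = r.get("n_genomes", 0) + 1
        for g in (
            p.synthases_present | p.monomer_genes | p.phasins | p.regulators | p.depolymerases
        ):
            r[f"gene_{g}"] = r.get(f"gene_{g}", 0) + 1
        for m in p.monomers:
            r[f"monomer_{m.value}"] = r.get(f"monomer_{m.value}", 0) + 1
        if p.unresolved:
            r["n_unresolved"] = r.get("n_unresolved", 0) + 1

    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    if "n_unresolved" not in df.columns:
        df["n_unresolved"] = 0
    df = df.astype(int)
    df["unresolved_fraction"] = df["n_unresolved"] / df["n_genomes"]
    return df.sort_index().rename_axis("family")
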