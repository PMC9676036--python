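"""The multi-tier enrichment filter cascade producing candidate genomes.

Tier definitions (defaults are the published thresholds, all configurable):

1. polymerase-positive — the genome carries at least one terminal PHA
   synthase gene (PhaC, PhaC2 or PhaE).
2. SPD-positive — additionally carries ≥1 unique seaweed-polysaccharide-
   degrading (SPD) enzyme family from the algal class scheme.
3. enriched — ≥3 unique SPD families in total AND ≥2 for at least one of the
   three macroalgal groups.
4. highly enriched — ≥3 unique SPD families for a single macroalgal type.
5. top percentile — within the highly-enriched subset, per algal class,
   genomes whose class gene density is ≥ the 70th percentile (inclusive).

Genome tiers are nested by construction; every comparison made for every
genome is recorded in an audit table.  A separate family-level filter
(≥2 unique red-acting OR ≥4 green OR ≥4 brown families) reproduces the
family-enrichment screen used on the enzyme-database side of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .density import (
    DensityMatrix,
    build_density,
    class_gene_density,
    unique_class_counts,
)
from .tables_io import AlgalClassScheme, GeneAnnotation, PhaGeneCatalog
from .taxonomy import TaxonomyDB

__all__ = [
    "ScreeningConfig",
    "ScreeningTiers",
    "family_enrichment_filter",
    "polymerase_filter",
    "enriched_filter",
    "highly_enriched_filter",
    "percentile_threshold",
    "percentile_filter",
    "run_cascade",
]


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds and percentile semantics of the cascade."""

    spd_min_unique: int = 1
    enriched_total_min: int = 3
    enriched_group_min: int = 2
    highly_enriched_min: int = 3
    family_red_min: int = 2
    family_green_min: int = 4
    family_brown_min: int = 4
    percentile: float = 70.0
    percentile_metric: str = "occurrences"  # or "unique"
    percentile_method: str = "linear"  # or "nearest"
    nested: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if self.percentile_metric not in ("occurrences", "unique"):
            raise ValueError("percentile_metric must be 'occurrences' or 'unique'")
        if self.percentile_method not in ("linear", "nearest"):
            raise ValueError("percentile_method must be 'linear' or 'nearest'")


@dataclass
class ScreeningTiers:
    """Nested candidate sets with full per-genome audit provenance."""

    polymerase_positive: set[str]
    spd_positive: set[str]
    enriched: set[str]
    highly_enriched: set[str]
    top_percentile: dict[str, set[str]]
    family_enriched: set[int]
    audit: pd.DataFrame
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    def counts(self) -> dict[str, int]:
        out = {
            "polymerase_positive": len(self.polymerase_positive),
            "spd_positive": len(self.spd_positive),
            "enriched": len(self.enriched),
            "highly_enriched": len(self.highly_enriched),
            "family_enriched": len(self.family_enriched),
        }
        for c, s in sorted(self.top_percentile.items()):
            out[f"top_{c}"] = len(s)
        return out

    def check_nesting(self) -> None:
        assert self.spd_positive <= self.polymerase_positive
        assert self.enriched <= self.spd_positive
        assert self.highly_enriched <= self.enriched
        for s in self.top_percentile.values():
            assert s <= self.highly_enriched


# --------------------------------------------------------------------------
# Individual filters
# --------------------------------------------------------------------------


def polymerase_filter(labels: Iterable[str], catalog: PhaGeneCatalog) -> bool:
    """True iff the genome carries ≥1 terminal PHA synthase gene."""
    return bool(set(labels) & catalog.synthases)


def enriched_filter(
    u_green: int,
    u_brown: int,
    u_red: int,
    total_unique_spd: int,
    config: ScreeningConfig = ScreeningConfig(),
) -> bool:
    """≥3 unique SPD families overall and ≥2 for at least one algal group."""
    return (
        total_unique_spd >= config.enriched_total_min
        and max(u_green, u_brown, u_red) >= config.enriched_group_min
    )


def highly_enriched_filter(
    u_green: int, u_brown: int, u_red: int, config: ScreeningConfig = ScreeningConfig()
) -> bool:
    """≥3 unique SPD families for a single macroalgal type."""
    return max(u_green, u_brown, u_red) >= config.highly_enriched_min


def family_enrichment_filter(
    family_unique_counts: pd.DataFrame, config: ScreeningConfig = ScreeningConfig()
) -> set:
    """Families with ≥2 unique red-acting OR ≥4 green OR ≥4 brown families.

    ``family_unique_counts`` is the ``unique_class_counts`` frame of a
    family-level density matrix (index = family taxids as strings).
    """
    u = family_unique_counts
    mask = (
        (u["u_red"] >= config.family_red_min)
        | (u["u_green"] >= config.family_green_min)
        | (u["u_brown"] >= config.family_brown_min)
    )
    return set(u.index[mask])


def percentile_threshold(values: np.ndarray, q: float, method: str = "linear") -> float:
    """The q-th percentile by linear interpolation or classic nearest-rank."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    if method == "linear":
        return float(np.percentile(v, q, method="linear"))
    if method == "nearest":
        # classic nearest-rank: ceil(q/100 * n)-th smallest value
        rank = int(np.ceil(q / 100.0 * v.size))
        return float(np.sort(v)[max(rank, 1) - 1])
    raise ValueError(f"unknown percentile method {method!r}")


def percentile_filter(
    class_densities: Mapping[str, float] | pd.Series,
    q: float = 70.0,
    method: str = "linear",
) -> tuple[set[str], float]:
    """Genomes whose density is ≥ the q-th percentile of the input set.

    The comparison is inclusive, so all-tied inputs are all retained.
    Returns (retained genome ids, threshold used).
    """
    s = pd.Series(class_densities, dtype=float)
    if s.empty:
        raise ValueError("percentile_filter requires a non-empty genome set")
    thr = percentile_threshold(s.to_numpy(), q, method)
    return set(s.index[s >= thr]), thr


# --------------------------------------------------------------------------
# Cascade
# --------------------------------------------------------------------------


def run_cascade(
    annotations: Iterable[GeneAnnotation],
    scheme: AlgalClassScheme | None = None,
    catalog: PhaGeneCatalog | None = None,
    taxonomy: TaxonomyDB | None = None,
    genome_taxids: dict[str, int] | None = None,
    all_genomes: Iterable[str] | None = None,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningTiers:
    """Run the full filter cascade and return nested tiers with audit trail.

    ``all_genomes`` (e.g. metadata genome ids) adds annotation-free genomes
    to the audited universe; they fail at the polymerase stage.  Family-level
    enrichment is computed only when ``taxonomy`` and ``genome_taxids`` are
    given.
    """
    scheme = scheme or AlgalClassScheme.default()
    catalog = catalog or PhaGeneCatalog.default()
    annotations = list(annotations)

    universe = list(dict.fromkeys(a.genome_id for a in annotations))
    if all_genomes is not None:
        for g in all_genomes:
            if g not in universe:
                universe.append(g)

    matrix = build_density(annotations, level="genome", all_entities=universe)
    u = unique_class_counts(matrix, scheme)
    d = class_gene_density(matrix, scheme)
    present = matrix.counts > 0
    scheme_cols = [l for l in matrix.labels if l in scheme.all_labels]
    total_unique = (
        present[scheme_cols].sum(axis=1) if scheme_cols else pd.Series(0, index=present.index)
    ).astype(int)
    synth_cols = [l for l in matrix.labels if l in catalog.synthases]
    n_synthases = (
        present[synth_cols].sum(axis=1) if synth_cols else pd.Series(0, index=present.index)
    ).astype(int)

    audit_rows: list[dict] = []

    def record(g: str, rule: str, observed, threshold, passed: bool) -> None:
        audit_rows.append(
            {"genome_id": g, "rule": rule, "observed": observed,
             "threshold": threshold, "passed": bool(passed)}
        )

    polymerase_positive: set[str] = set()
    spd_positive: set[str] = set()
    enriched: set[str] = set()
    highly: set[str] = set()
    for g in universe:
        ok_pol = int(n_synthases.get(g, 0)) >= 1
        record(g, "polymerase_positive", int(n_synthases.get(g, 0)), 1, ok_pol)
        if ok_pol:
            polymerase_positive.add(g)

        tu = int(total_unique.get(g, 0))
        ok_spd = tu >= config.spd_min_unique
        record(g, "spd_positive", tu, config.spd_min_unique, ok_spd)
        if ok_pol and ok_spd:
            spd_positive.add(g)

        ug, ub, ur = int(u.loc[g, "u_green"]), int(u.loc[g, "u_brown"]), int(u.loc[g, "u_red"])
        ok_enr = enriched_filter(ug, ub, ur, tu, config)
        record(
            g, "enriched", f"total={tu},max_group={max(ug, ub, ur)}",
            f"total>={config.enriched_total_min},group>={config.enriched_group_min}", ok_enr,
        )
        ok_high = highly_enriched_filter(ug, ub, ur, config)
        record(g, "highly_enriched", max(ug, ub, ur), config.highly_enriched_min, ok_high)

        if config.nested:
            if g in spd_positive and ok_enr:
                enriched.add(g)
            if g in enriched and ok_high:
                highly.add(g)
        else:
            if ok_enr:
                enriched.add(g)
            if ok_high:
                highly.add(g)

    # per-class 70th-percentile cut within the highly-enriched subset
    metric = d if config.percentile_metric == "occurrences" else u
    prefix = "d_" if config.percentile_metric == "occurrences" else "u_"
    top: dict[str, set[str]] = {}
    for c in scheme.CLASSES:
        if highly:
            col = metric.loc[sorted(highly), f"{prefix}{c}"]
            retained, thr = percentile_filter(col, config.percentile, config.percentile_method)
            for g in sorted(highly):
                record(g, f"top_{c}", float(col[g]), thr, g in retained)
            top[c] = retained
        else:
            top[c] = set()

    family_enriched: set[int] = set()
    if taxonomy is not None and genome_taxids is not None:
        fam_matrix = build_density(
            annotations, level="family", taxonomy=taxonomy, genome_taxids=genome_taxids
        ).drop_unknown()
        if fam_matrix.counts.shape[0]:
            fam_u = unique_class_counts(fam_matrix, scheme)
            family_enriched = {int(f) for f in family_enrichment_filter(fam_u, config)}

    audit = pd.DataFrame(
        audit_rows, columns=["genome_id", "rule", "observed", "threshold", "passed"]
    )
    tiers = ScreeningTiers(
        polymerase_positive=polymerase_positive,
        spd_positive=spd_positive,
        enriched=enriched,
        highly_enriched=highly,
        top_percentile=top,
        family_enriched=family_enriched,
        audit=audit,
        config=config,
    )
    if config.nested:
        tiers.check_nesting()
    return tiers
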