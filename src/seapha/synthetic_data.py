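"""Seeded generator of annotation/metadata/taxonomy tables with planted truth.

The generator emulates the inputs the screen consumes — per-genome gene
annotation tables, assembly metadata, and an NCBI-style taxonomy — with
enough planted structure that every pipeline stage has a known ground truth:

* background gene counts are independent Poisson draws per (genome, label);
* selected label pairs are given a target Pearson correlation via a Gaussian
  copula over Poisson marginals, with the latent correlation calibrated by
  Gauss–Hermite quadrature so the count-scale correlation hits the target;
* planted candidate genomes receive a fixed label multiset guaranteeing the
  screening tier they are planted for (planted "top" candidates share one
  identical high-copy multiset, so the within-tier percentile population is
  all ties and the inclusive cut retains every one of them);
* metadata is split into marine/terrestrial isolation sources and into an
  exact-count quality pass/fail partition where each failing genome violates
  exactly one gate rule by at least one unit.

One ``numpy`` generator seeded once drives all randomness, and all row
orders are deterministic, so identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import (
    AlgalClassScheme,
    Category,
    GeneAnnotation,
    GenomeMetadata,
    PhaGeneCatalog,
    expected_category,
    write_annotations,
    write_metadata,
)
from .quality_gate import QualityThresholds
from .taxonomy import TaxonomyDB

__all__ = [
    "SyntheticConfigError",
    "PlantedSpec",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "generate_quality_cohort",
    "planted_multiset",
]


class SyntheticConfigError(ValueError):
    """Unsatisfiable or out-of-range synthetic configuration."""


@dataclass(frozen=True)
class PlantedSpec:
    """How many genomes to plant for which screening tier.

    ``tier`` ∈ {polymerase, spd, enriched, highly_enriched, top}.  ``copies``
    is the per-label copy number of the guaranteed multiset (only "top"
    benefits from > 1: high copy numbers push planted genomes far above any
    background genome in the percentile population).
    """

    tier: str
    count: int
    copies: int = 1

    def __post_init__(self) -> None:
        if self.tier not in ("polymerase", "spd", "enriched", "highly_enriched", "top"):
            raise SyntheticConfigError(f"unknown planted tier {self.tier!r}")
        if self.count < 0 or self.copies < 1:
            raise SyntheticConfigError("count must be ≥0 and copies ≥1")


def _default_background_rates() -> dict[str, float]:
    """Sparse per-label Poisson means for the stated background world.

    SPD labels are rare per genome (mean ≈1.5 distinct scheme labels per
    genome) while PHA genes are common, so tier attrition is qualitatively
    like the published screen: most polymerase-positive genomes fail the
    enrichment tiers.
    """
    rates = {lab: 0.04 for lab in sorted(AlgalClassScheme.default().all_labels)}
    rates.update(
        {
            "PhaC": 0.5, "PhaC2": 0.08, "PhaE": 0.12,
            "PhaA": 0.3, "PhaB": 0.4, "PhaJ": 0.15, "PhaG": 0.1,
            "FabG": 0.6, "maoC": 0.2, "Pct": 0.05, "Pcs": 0.05,
            "PrpE": 0.15, "PduP": 0.05, "Cat2": 0.05, "HadA": 0.02,
            "PhaF": 0.1, "PhaI": 0.1, "PhaP": 0.2,
            "PhaD": 0.1, "PhaQ": 0.05, "PhaR": 0.2, "PhaZ": 0.3,
        }
    )
    return rates


_MARINE_SOURCES = (
    "coastal seawater",
    "marine sediment",
    "surface of brown seaweed",
    "estuarine water",
    "hydrothermal vent fluid",
    "kelp forest biofilm",
)
_TERRESTRIAL_SOURCES = (
    "rhizosphere soil",
    "forest topsoil",
    "activated sludge",
    "compost heap",
    "freshwater lake",
    "plant root nodule",
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_families: int = 20
    genomes_per_family: int = 10
    background_rates: dict[str, float] = field(default_factory=_default_background_rates)
    planted: tuple[PlantedSpec, ...] = (PlantedSpec("top", 10, copies=8),)
    planted_correlations: tuple[tuple[str, str, float], ...] = (("PhaG", "GH50", 0.54),)
    correlated_pair_mean: float = 3.0
    marine_fraction: float = 0.3
    quality_fail_fraction: float = 0.88
    scheme: AlgalClassScheme = field(default_factory=AlgalClassScheme.default)
    catalog: PhaGeneCatalog = field(default_factory=PhaGeneCatalog.default)

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.genomes_per_family < 1:
            raise SyntheticConfigError("need ≥1 family and ≥1 genome per family")
        if any(r < 0 for r in self.background_rates.values()):
            raise SyntheticConfigError("background rates must be ≥ 0")
        for a, b, rho in self.planted_correlations:
            if not -1.0 < rho < 1.0:
                raise SyntheticConfigError(f"|rho| must be < 1 for pair ({a}, {b})")
        for frac_name in ("marine_fraction", "quality_fail_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{frac_name} must lie in [0, 1]")
        if sum(p.count for p in self.planted) > self.n_genomes:
            raise SyntheticConfigError("more planted candidates than genomes")

    @property
    def n_genomes(self) -> int:
        return self.n_families * self.genomes_per_family


@dataclass
class GroundTruth:
    """Planted facts, consistent with the emitted tables by construction."""

    tiers: dict[str, str]  # genome_id -> planted tier or "background"
    marine: dict[str, bool]
    quality_pass: dict[str, bool]
    correlation_pairs: tuple[tuple[str, str, float], ...]

    def planted_for(self, tier: str) -> set[str]:
        return {g for g, t in self.tiers.items() if t == tier}

    def to_frame(self) -> pd.DataFrame:
        genomes = sorted(self.tiers)
        return pd.DataFrame(
            {
                "genome_id": genomes,
                "planted_tier": [self.tiers[g] for g in genomes],
                "marine": [self.marine[g] for g in genomes],
                "quality_pass": [self.quality_pass[g] for g in genomes],
            }
        )


@dataclass
class SyntheticDataset:
    annotations: list[GeneAnnotation]
    metadata: list[GenomeMetadata]
    taxonomy: TaxonomyDB
    truth: GroundTruth
    genome_taxids: dict[str, int]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write annotations/metadata/taxdump/ground-truth; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": out / "annotations.tsv",
            "metadata": out / "metadata.tsv",
            "nodes": out / "nodes.dmp",
            "names": out / "names.dmp",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_annotations(self.annotations, paths["annotations"])
        write_metadata(self.metadata, paths["metadata"])
        self.taxonomy.to_taxdump(paths["nodes"], paths["names"])
        self.truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


# --------------------------------------------------------------------------
# Planted multisets
# --------------------------------------------------------------------------


def planted_multiset(
    tier: str, scheme: AlgalClassScheme, catalog: PhaGeneCatalog, copies: int = 1
) -> dict[str, int]:
    """A fixed label→count multiset guaranteeing membership of ``tier``.

    Labels are the lexicographically first usable ones from the scheme, so
    the construction is deterministic and fails loudly if the scheme cannot
    supply the required class diversity.
    """
    synthases = sorted(catalog.synthases)
    if not synthases:
        raise SyntheticConfigError("catalog has no synthase genes")
    green = sorted(scheme.green)
    brown = sorted(scheme.brown - scheme.green)  # keep class counts independent
    red = sorted(scheme.red)

    def take(pool: list[str], k: int, cls: str) -> list[str]:
        if len(pool) < k:
            raise SyntheticConfigError(
                f"scheme has only {len(pool)} usable {cls} labels, need {k}"
            )
        return pool[:k]

    base = {synthases[0]: 1}
    if tier == "polymerase":
        labels: list[str] = []
    elif tier == "spd":
        labels = take(green, 1, "green")
    elif tier == "enriched":
        # 3 unique overall, exactly 2 in one class: below the highly bar
        labels = take(green, 2, "green") + take(brown, 1, "brown")
    elif tier == "highly_enriched":
        labels = take(green, 3, "green")
    elif tier == "top":
        # diversity + density in all three classes: clears every tier and
        # dominates any chance background entrant in every class percentile
        labels = take(green, 4, "green") + take(brown, 4, "brown") + take(red, 3, "red")
    else:  # pragma: no cover
        raise SyntheticConfigError(f"unknown tier {tier!r}")
    multiset = dict(base)
    for lab in labels:
        multiset[lab] = copies if tier == "top" else 1
    return multiset


# --------------------------------------------------------------------------
# Copula calibration
# --------------------------------------------------------------------------


def _poisson_ppf_of_normal(z: np.ndarray, mu: float) -> np.ndarray:
    # clip away u == 1.0 at extreme z, where the Poisson quantile is +inf
    u = np.clip(stats.norm.cdf(z), 1e-15, 1.0 - 1e-13)
    return stats.poisson.ppf(u, mu)


def _count_scale_rho(rho_z: float, mu_a: float, mu_b: float, grid: int = 8001) -> float:
    """Pearson correlation of copula-coupled Poisson counts.

    With latent (Z1, Z2) standard bivariate normal at correlation ``rho_z``
    and X = F⁻¹(Φ(Z1)), Y = F⁻¹(Φ(Z2)):  E[XY] = ∫ X(z)·E[Y|Z1=z]·φ(z) dz,
    where E[Y|z] = Σ_l P(Z2 ≥ b_l | z) is smooth (b_l = Φ⁻¹(F(l−1)) are the
    staircase thresholds of Y), so a dense trapezoid over z is accurate even
    though X(z) itself is a staircase.
    """
    z = np.linspace(-8.0, 8.0, grid)
    x = _poisson_ppf_of_normal(z, mu_a)
    top = int(stats.poisson.ppf(1.0 - 1e-12, mu_b)) + 1
    levels = np.arange(1, top + 1)
    b = stats.norm.ppf(
        np.clip(stats.poisson.cdf(levels - 1, mu_b), 1e-15, 1.0 - 1e-15)
    )
    s = np.sqrt(max(1.0 - rho_z**2, 1e-12))
    e_y_given_z = (
        1.0 - stats.norm.cdf((b[None, :] - rho_z * z[:, None]) / s)
    ).sum(axis=1)
    e_xy = float(np.trapezoid(x * e_y_given_z * stats.norm.pdf(z), z))
    return (e_xy - mu_a * mu_b) / np.sqrt(mu_a * mu_b)


@lru_cache(maxsize=None)
def calibrate_copula_rho(target: float, mu_a: float, mu_b: float) -> float:
    """Latent normal correlation whose induced count correlation hits ``target``."""
    if target == 0.0:
        return 0.0
    from scipy.optimize import brentq

    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    f = lambda r: _count_scale_rho(r, mu_a, mu_b) - target
    if f(lo) * f(hi) > 0:
        raise SyntheticConfigError(
            f"target correlation {target} unattainable for means ({mu_a}, {mu_b})"
        )
    return float(brentq(f, lo, hi, xtol=1e-4))


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _make_taxonomy(n_families: int, genomes_per_family: int) -> tuple[TaxonomyDB, dict[str, int], list[str]]:
    """Balanced root/phylum/order/family/species taxonomy.

    Families are grouped 4-per-order and orders 4-per-phylum; every genome
    gets its own species node under its family.  Returns (db, genome→species
    taxid, genome ids in family-major order).
    """
    records: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root")]
    n_orders = -(-n_families // 4)
    n_phyla = -(-n_orders // 4)
    phylum_ids = [10 + i for i in range(n_phyla)]
    for i, pid in enumerate(phylum_ids):
        records.append((pid, 1, "phylum", f"Phylum{i + 1:02d}"))
    order_ids = [100 + i for i in range(n_orders)]
    for i, oid in enumerate(order_ids):
        records.append((oid, phylum_ids[i // 4], "order", f"Order{i + 1:03d}"))
    family_ids = [1000 + i for i in range(n_families)]
    for i, fid in enumerate(family_ids):
        records.append((fid, order_ids[i // 4], "family", f"Family{i + 1:04d}"))

    genome_taxids: dict[str, int] = {}
    genomes: list[str] = []
    next_species = 100_000
    for i, fid in enumerate(family_ids):
        for j in range(genomes_per_family):
            g = f"G{i * genomes_per_family + j + 1:06d}"
            records.append((next_species, fid, "species", f"Species {g}"))
            genome_taxids[g] = next_species
            genomes.append(g)
            next_species += 1
    return TaxonomyDB.from_records(records), genome_taxids, genomes


def generate(config: SyntheticConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset; optionally write it to disk."""
    rng = np.random.default_rng(config.seed)
    taxdb, genome_taxids, genomes = _make_taxonomy(
        config.n_families, config.genomes_per_family
    )
    n = len(genomes)

    # choose planted genomes (scattered, deterministic under the seed)
    n_planted = sum(p.count for p in config.planted)
    planted_order = [g for g in (genomes[i] for i in rng.permutation(n))][:n_planted]
    tier_of: dict[str, str] = {g: "background" for g in genomes}
    planted_sets: dict[str, dict[str, int]] = {}
    idx = 0
    for spec in config.planted:
        multiset = planted_multiset(spec.tier, config.scheme, config.catalog, spec.copies)
        for _ in range(spec.count):
            g = planted_order[idx]
            idx += 1
            tier_of[g] = spec.tier
            planted_sets[g] = multiset

    planted_genomes = set(planted_sets)
    bg_mask = np.array([g not in planted_genomes for g in genomes])

    # per-label counts: background Poisson, then copula pairs overriding
    corr_labels = {lab for a, b, _ in config.planted_correlations for lab in (a, b)}
    counts: dict[str, np.ndarray] = {}
    for lab in sorted(config.background_rates):
        if lab in corr_labels:
            continue
        counts[lab] = rng.poisson(config.background_rates[lab], size=n)
    for a, b, rho in config.planted_correlations:
        mu = config.correlated_pair_mean
        rho_z = calibrate_copula_rho(rho, mu, mu)
        cov = np.array([[1.0, rho_z], [rho_z, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
        counts[a] = _poisson_ppf_of_normal(z[:, 0], mu).astype(int)
        counts[b] = _poisson_ppf_of_normal(z[:, 1], mu).astype(int)

    # planted genomes carry exactly their guaranteed multiset (background and
    # copula counts zeroed) so their tier membership and within-tier ties are
    # exact by construction
    for lab in counts:
        counts[lab] = np.where(bg_mask, counts[lab], 0)

    annotations: list[GeneAnnotation] = []
    gene_counter: dict[str, int] = {}

    def add_rows(genome: str, label: str, k: int) -> None:
        for _ in range(k):
            i = gene_counter.get(genome, 0) + 1
            gene_counter[genome] = i
            annotations.append(
                GeneAnnotation(
                    genome_id=genome,
                    gene_id=f"{genome}_{i:05d}",
                    label=label,
                    category=expected_category(label),
                    position=(i - 1) * 1000,
                )
            )

    labels_sorted = sorted(counts)
    for gi, g in enumerate(genomes):
        if g in planted_sets:
            for lab, k in sorted(planted_sets[g].items()):
                add_rows(g, lab, k)
        else:
            for lab in labels_sorted:
                k = int(counts[lab][gi])
                if k:
                    add_rows(g, lab, k)

    # metadata: marine split and exact-count quality partition
    marine_flags = rng.random(n) < config.marine_fraction
    n_fail = int(round(config.quality_fail_fraction * n))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist())
    thr = QualityThresholds()
    metadata: list[GenomeMetadata] = []
    marine_of: dict[str, bool] = {}
    pass_of: dict[str, bool] = {}
    for gi, g in enumerate(genomes):
        marine_of[g] = bool(marine_flags[gi])
        src_pool = _MARINE_SOURCES if marine_flags[gi] else _TERRESTRIAL_SOURCES
        source = src_pool[int(rng.integers(len(src_pool)))]
        n50 = int(rng.integers(thr.n50_min + 10_000, 500_000))
        completeness = round(float(rng.uniform(96.0, 100.0)), 2)
        contamination = round(float(rng.uniform(0.0, 4.0)), 2)
        markers = thr.marker_count_required
        ok = gi not in fail_idx
        if not ok:  # violate exactly one rule, by ≥1 unit
            rule = int(rng.integers(4))
            if rule == 0:
                n50 = int(rng.integers(5_000, thr.n50_min - 999))
            elif rule == 1:
                completeness = round(float(rng.uniform(80.0, thr.completeness_min - 1.0)), 2)
            elif rule == 2:
                contamination = round(float(rng.uniform(thr.contamination_max + 1.0, 15.0)), 2)
            else:
                markers = int(rng.integers(20, thr.marker_count_required))
        pass_of[g] = ok
        metadata.append(
            GenomeMetadata(
                genome_id=g,
                taxid=genome_taxids[g],
                isolation_source=source,
                n50=n50,
                completeness=completeness,
                contamination=contamination,
                marker_count=markers,
            )
        )

    truth = GroundTruth(
        tiers=tier_of,
        marine=marine_of,
        quality_pass=pass_of,
        correlation_pairs=tuple(config.planted_correlations),
    )
    ds = SyntheticDataset(
        annotations=annotations,
        metadata=metadata,
        taxonomy=taxdb,
        truth=truth,
        genome_taxids=genome_taxids,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def generate_quality_cohort(config: SyntheticConfig) -> tuple[list[GenomeMetadata], GroundTruth]:
    """Metadata-only cohort with a known exact-count quality pass/fail split."""
    ds = generate(config)
    return ds.metadata, ds.truth
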