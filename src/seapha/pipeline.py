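"""End-to-end orchestration: simulate → screen → pathways → correlate →
quality → report, as one reproducible run.

Stages run in a fixed order; a failure in any stage removes that stage's
partial outputs and re-raises as a :class:`StageError` naming the stage.
All thresholds live in :class:`PipelineConfig` with the published screen's
values as defaults, so sensitivity analyses are a config edit away.  The run
ends with a JSON manifest: config echo, seed, input digests, per-stage row
counts, tier counts and output paths.  Outputs carry no timestamps, so two
runs with the same seed and config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cooccurrence import build_network, correlation_matrix
from .density import build_density, log2_normalize
from .pha_pathways import cohort_pathway_summary, resolve_pathways
from .quality_gate import (
    DEFAULT_MARINE_KEYWORDS,
    QualityThresholds,
    marine_filter,
    quality_gate,
)
from .screening import ScreeningConfig, run_cascade
from .synthetic_data import PlantedSpec, SyntheticConfig, generate
from .tables_io import (
    AlgalClassScheme,
    PhaGeneCatalog,
    read_annotations,
    read_metadata,
    write_candidates,
)
from .taxonomy import TaxonomyDB, build_family_tree

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending path."""

    def __init__(self, stage: str, cause: BaseException, path: str | None = None):
        at = f" ({path})" if path else ""
        super().__init__(f"stage {stage!r} failed{at}: {cause}")
        self.stage = stage
        self.path = path
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Single config for the whole run; CLI flags override fields."""

    seed: int = 0
    simulate: bool = True
    annotations: str | None = None
    metadata: str | None = None
    nodes: str | None = None
    names: str | None = None
    synthetic: SyntheticConfig | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    marine_keywords: tuple[str, ...] = DEFAULT_MARINE_KEYWORDS
    correlate_marine_only: bool = True
    correlate_use_log2: bool = False
    min_copresence: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        for key in ("seed", "simulate", "annotations", "metadata", "nodes", "names",
                    "correlate_marine_only", "correlate_use_log2", "min_copresence"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "marine_keywords" in raw:
            cfg.marine_keywords = tuple(raw["marine_keywords"])
        if "screening" in raw:
            cfg.screening = ScreeningConfig(**raw["screening"])
        if "quality" in raw:
            cfg.quality = QualityThresholds(**raw["quality"])
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "planted" in syn:
                syn["planted"] = tuple(PlantedSpec(**p) for p in syn["planted"])
            if "planted_correlations" in syn:
                syn["planted_correlations"] = tuple(
                    tuple(p) for p in syn["planted_correlations"]
                )
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    input_digests: dict[str, str]
    stage_counts: dict[str, dict]
    tier_counts: dict[str, int]
    outputs: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    def clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return sorted(map(clean, obj)) if isinstance(obj, (set, frozenset)) else [
                clean(v) for v in obj
            ]
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if hasattr(obj, "value"):  # enums
            return obj.value
        return obj

    echo = {
        "seed": config.seed,
        "simulate": config.simulate,
        "screening": clean(config.screening),
        "quality": clean(config.quality),
        "marine_keywords": list(config.marine_keywords),
        "correlate_marine_only": config.correlate_marine_only,
        "correlate_use_log2": config.correlate_use_log2,
        "min_copresence": config.min_copresence,
    }
    if config.synthetic is not None:
        syn = clean(config.synthetic)
        syn.pop("scheme", None)
        syn.pop("catalog", None)
        echo["synthetic"] = syn
    for k in ("annotations", "metadata", "nodes", "names"):
        echo[k] = getattr(config, k)
    return echo


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run every stage into ``out_dir`` and return the manifest (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = AlgalClassScheme.default()
    catalog = PhaGeneCatalog.default()
    stage_counts: dict[str, dict] = {}
    outputs: dict[str, str] = {}
    input_digests: dict[str, str] = {}

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def run_stage(name: str, fn, path_hint: str | None = None):
        d = stage_dir(name)
        try:
            return fn(d)
        except Exception as exc:  # partial outputs removed, error stage-named
            shutil.rmtree(d, ignore_errors=True)
            raise StageError(name, exc, path_hint) from exc

    # -- simulate ----------------------------------------------------------
    if config.simulate:
        if config.synthetic is not None:
            from dataclasses import replace

            syn_cfg = replace(config.synthetic, seed=config.seed)
        else:
            syn_cfg = SyntheticConfig(seed=config.seed)

        def do_simulate(d: Path):
            ds = generate(syn_cfg, out_dir=d)
            stage_counts["simulate"] = {
                "genomes": len({m.genome_id for m in ds.metadata}),
                "annotation_rows": len(ds.annotations),
                "planted": sum(1 for t in ds.truth.tiers.values() if t != "background"),
            }
            return ds, d

        ds, sim_dir = run_stage("simulate", do_simulate)
        ann_path = sim_dir / "annotations.tsv"
        meta_path = sim_dir / "metadata.tsv"
        nodes_path, names_path = sim_dir / "nodes.dmp", sim_dir / "names.dmp"
        outputs["simulate"] = "simulate"
    else:
        for key in ("annotations", "metadata", "nodes", "names"):
            p = getattr(config, key)
            if p is None or not Path(p).exists():
                raise StageError("inputs", FileNotFoundError(f"missing {key} file"), p)
        ann_path, meta_path = Path(config.annotations), Path(config.metadata)
        nodes_path, names_path = Path(config.nodes), Path(config.names)

    for p in (ann_path, meta_path, nodes_path, names_path):
        input_digests[p.name] = _digest(p)

    # -- load inputs -------------------------------------------------------
    def do_load(_d: Path):
        table = read_annotations(ann_path)
        meta = read_metadata(meta_path)
        taxdb = TaxonomyDB.from_taxdump(nodes_path, names_path)
        stage_counts["load"] = {
            "annotations_accepted": table.n_accepted,
            "annotations_rejected": table.n_rejected,
            "metadata_rows": len(meta),
            "taxonomy_nodes": len(taxdb),
        }
        return table.annotations, meta, taxdb

    annotations, metadata, taxdb = run_stage("load", do_load, str(ann_path))
    genome_taxids = {m.genome_id: m.taxid for m in metadata}
    all_genomes = [m.genome_id for m in metadata]

    # -- screen ------------------------------------------------------------
    def do_screen(d: Path):
        tiers = run_cascade(
            annotations,
            scheme=scheme,
            catalog=catalog,
            taxonomy=taxdb,
            genome_taxids=genome_taxids,
            all_genomes=all_genomes,
            config=config.screening,
        )
        write_candidates(tiers, d / "candidates.tsv")
        tiers.audit.to_csv(d / "audit.tsv", sep="\t", index=False)
        fams = sorted(tiers.family_enriched)
        pd.DataFrame({"family_taxid": fams,
                      "family_name": [taxdb.name_of(f) for f in fams]}).to_csv(
            d / "family_enriched.tsv", sep="\t", index=False)
        if fams:
            build_family_tree(taxdb, set(fams)).tree.write(
                str(d / "family_enriched.nwk"), format="newick")
        stage_counts["screen"] = tiers.counts()
        return tiers

    tiers = run_stage("screen", do_screen)
    outputs["screen"] = "screen"

    # -- pathways ----------------------------------------------------------
    matrix = build_density(annotations, level="genome", all_entities=all_genomes)

    def do_pathways(d: Path):
        labels_by_genome = {
            g: set(matrix.counts.columns[matrix.counts.loc[g] > 0]) for g in matrix.entities
        }
        profiles = [
            resolve_pathways(g, labels_by_genome[g], catalog)
            for g in sorted(tiers.polymerase_positive)
        ]
        rows = [
            {
                "genome_id": p.genome_id,
                "synthases": ",".join(sorted(p.synthases_present)),
                "monomers": ",".join(sorted(m.value for m in p.monomers)),
                "monomer_genes": ",".join(sorted(p.monomer_genes)),
                "unresolved": p.unresolved,
                "class_iii_possible": p.class_iii_possible,
            }
            for p in profiles
        ]
        pd.DataFrame(rows).to_csv(d / "pathway_profiles.tsv", sep="\t", index=False)
        if profiles:
            cohort_pathway_summary(profiles, taxdb, genome_taxids).to_csv(
                d / "family_pathway_summary.tsv", sep="\t")
        stage_counts["pathways"] = {
            "profiles": len(profiles),
            "unresolved": sum(p.unresolved for p in profiles),
        }
        return profiles

    run_stage("pathways", do_pathways)
    outputs["pathways"] = "pathways"

    # -- correlate ---------------------------------------------------------
    def do_correlate(d: Path):
        genome_set = matrix.entities
        if config.correlate_marine_only:
            marine = [
                m.genome_id
                for m in metadata
                if marine_filter(m.isolation_source, config.marine_keywords)[0]
            ]
            if len(marine) >= 3:
                genome_set = [g for g in matrix.entities if g in set(marine)]
        sub = matrix.counts.loc[genome_set]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        from .density import DensityMatrix

        sub_matrix = DensityMatrix(counts=sub, level="genome")
        corr = correlation_matrix(sub_matrix, use_log2=config.correlate_use_log2)
        corr.to_csv(d / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
        net = build_network(sub_matrix, min_copresence=config.min_copresence)
        net.to_edgelist().to_csv(d / "network_edges.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        net.write_graphml(d / "network.graphml")
        stage_counts["correlate"] = {
            "genomes_used": len(genome_set),
            "labels": sub.shape[1],
            "pairs": len(corr),
            "edges": net.graph.number_of_edges(),
        }
        return corr

    run_stage("correlate", do_correlate)
    outputs["correlate"] = "correlate"

    # -- quality -----------------------------------------------------------
    def do_quality(d: Path):
        verdicts = [
            quality_gate(m, config.quality, config.marine_keywords) for m in metadata
        ]
        rows = [
            {
                "genome_id": v.genome_id,
                "marine": v.marine,
                "matched_keyword": v.matched_keyword or "",
                "pass_n50": v.pass_n50,
                "pass_completeness": v.pass_completeness,
                "pass_contamination": v.pass_contamination,
                "pass_markers": v.pass_markers,
                "overall": v.overall,
            }
            for v in verdicts
        ]
        pd.DataFrame(rows).to_csv(d / "quality_verdicts.tsv", sep="\t", index=False)
        stage_counts["quality"] = {
            "genomes": len(verdicts),
            "marine": sum(v.marine for v in verdicts),
            "high_quality": sum(v.overall for v in verdicts),
            "marine_high_quality": sum(v.overall and v.marine for v in verdicts),
        }
        return verdicts

    run_stage("quality", do_quality)
    outputs["quality"] = "quality"

    # -- report ------------------------------------------------------------
    def do_report(d: Path):
        fam_matrix = build_density(
            annotations, level="family", taxonomy=taxdb, genome_taxids=genome_taxids
        ).drop_unknown()
        fam_matrix.to_tsv(d / "family_density.tsv")
        log2_normalize(fam_matrix).round(6).rename_axis("entity").to_csv(
            d / "family_density_log2.tsv", sep="\t")
        from .tables_io import write_itol_heatmap

        write_itol_heatmap(fam_matrix, d / "family_density_itol.txt")
        stage_counts["report"] = {"families": fam_matrix.counts.shape[0]}

    run_stage("report", do_report)
    outputs["report"] = "report"

    manifest = RunManifest(
        seed=config.seed,
        config=_config_echo(config),
        version=__version__,
        input_digests=input_digests,
        stage_counts=stage_counts,
        tier_counts=tiers.counts(),
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
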