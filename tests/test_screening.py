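"""Filter cascade: individual rules, percentile semantics, nesting, oracles."""

import numpy as np
import pandas as pd
import pytest

from seapha.density import build_density, class_gene_density, unique_class_counts
from seapha.screening import (
    ScreeningConfig,
    enriched_filter,
    family_enrichment_filter,
    highly_enriched_filter,
    percentile_filter,
    polymerase_filter,
    run_cascade,
)
from seapha.tables_io import AlgalClassScheme, PhaGeneCatalog

from conftest import annotate


class TestPolymeraseFilter:
    @pytest.mark.parametrize("labels,expected", [
        ({"PhaE"}, True),
        ({"PhaC"}, True),
        ({"PhaC2", "GH2"}, True),
        ({"PhaZ", "PhaB"}, False),   # accessory genes are not synthases
        (set(), False),
    ])
    def test_synthase_presence(self, labels, expected, catalog):
        assert polymerase_filter(labels, catalog) is expected


class TestEnrichedFilter:
    @pytest.mark.parametrize("u,total,expected", [
        ((2, 1, 0), 3, True),    # 3 unique and one group with >=2
        ((1, 1, 1), 3, False),   # no group reaches 2
        ((5, 0, 0), 5, True),
        ((2, 0, 0), 2, False),   # total below 3
    ])
    def test_rule(self, u, total, expected):
        assert enriched_filter(*u, total) is expected


class TestHighlyEnrichedFilter:
    @pytest.mark.parametrize("u,expected", [
        ((3, 0, 0), True),
        ((0, 0, 3), True),
        ((2, 2, 2), False),   # no single type reaches 3
        ((0, 0, 0), False),
    ])
    def test_rule(self, u, expected):
        assert highly_enriched_filter(*u) is expected


class TestFamilyEnrichmentFilter:
    @pytest.mark.parametrize("u,expected", [
        ((0, 0, 2), True),    # >=2 unique red-acting families
        ((4, 0, 0), True),    # >=4 green
        ((0, 4, 0), True),    # >=4 brown
        ((3, 3, 1), False),   # all below their class thresholds
        ((0, 0, 0), False),
    ])
    def test_rule(self, u, expected):
        df = pd.DataFrame([dict(zip(("u_green", "u_brown", "u_red"), u))], index=["F"])
        assert (("F" in family_enrichment_filter(df)) is expected)


class TestPercentileFilter:
    def test_integer_grid_1_to_100(self):
        # linear-interpolation P70 of 1..100 is 70.3; inclusive cut keeps 71..100
        d = pd.Series({f"g{i}": i for i in range(1, 101)})
        retained, thr = percentile_filter(d, 70)
        assert thr == pytest.approx(70.3)
        assert retained == {f"g{i}" for i in range(71, 101)}
        assert len(retained) == 30

    def test_all_ties_all_retained(self):
        d = pd.Series({f"g{i}": 4.0 for i in range(10)})
        retained, _ = percentile_filter(d, 70)
        assert len(retained) == 10

    def test_single_genome_retained(self):
        retained, thr = percentile_filter(pd.Series({"g1": 5.0}), 70)
        assert retained == {"g1"} and thr == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_filter(pd.Series(dtype=float), 70)

    def test_nearest_rank_method(self):
        # nearest-rank P70 of 1..10 is the ceil(0.7*10)=7th smallest = 7
        d = pd.Series({f"g{i}": i for i in range(1, 11)})
        retained, thr = percentile_filter(d, 70, method="nearest")
        assert thr == 7 and len(retained) == 4

    def test_raising_q_never_grows_retained(self):
        rng = np.random.default_rng(0)
        d = pd.Series(rng.integers(0, 50, size=40).astype(float),
                      index=[f"g{i}" for i in range(40)])
        prev = None
        for q in (10, 30, 50, 70, 90):
            cur, _ = percentile_filter(d, q)
            if prev is not None:
                assert cur <= prev
            prev = cur


def brute_force_tiers(spec, scheme, catalog, config=ScreeningConfig()):
    """Literal set-comprehension reimplementation of the cascade rules.

    ``spec`` is {genome: {label: count}}; independent of run_cascade's code
    path (no density-module reuse beyond building the input).
    """
    genomes = sorted(spec)
    u = {}
    d = {}
    total_unique = {}
    for g in genomes:
        labels = {l for l, c in spec[g].items() if c > 0}
        u[g] = {
            c: len(labels & set(scheme.labels_for(c))) for c in ("green", "brown", "red")
        }
        d[g] = {
            c: sum(cnt for l, cnt in spec[g].items() if l in scheme.labels_for(c))
            for c in ("green", "brown", "red")
        }
        total_unique[g] = len(labels & set(scheme.all_labels))

    polymerase = {g for g in genomes if set(spec[g]) & {"PhaC", "PhaC2", "PhaE"}}
    spd = {g for g in polymerase if total_unique[g] >= config.spd_min_unique}
    enriched = {
        g for g in spd
        if total_unique[g] >= config.enriched_total_min
        and max(u[g].values()) >= config.enriched_group_min
    }
    highly = {g for g in enriched if max(u[g].values()) >= config.highly_enriched_min}
    top = {}
    for c in ("green", "brown", "red"):
        if highly:
            vals = np.array([d[g][c] for g in sorted(highly)], dtype=float)
            thr = np.percentile(vals, config.percentile)
            top[c] = {g for g in highly if d[g][c] >= thr}
        else:
            top[c] = set()
    return polymerase, spd, enriched, highly, top


class TestRunCascade:
    def test_full_candidate(self, scheme, catalog):
        anns = annotate({"g1": {"PhaC": 1, "GH2": 1, "GH43": 1, "PL28": 1}})
        tiers = run_cascade(anns, scheme, catalog)
        assert "g1" in tiers.enriched and "g1" in tiers.highly_enriched

    def test_no_synthase_blocks_everything(self, scheme, catalog):
        anns = annotate({"g1": {"GH2": 1, "GH43": 1, "PL28": 1}})
        tiers = run_cascade(anns, scheme, catalog)
        assert "g1" not in tiers.polymerase_positive
        assert "g1" not in tiers.enriched  # nested: excluded at polymerase stage

    def test_synthase_only_stops_at_spd(self, scheme, catalog):
        tiers = run_cascade(annotate({"g1": {"PhaC": 1}}), scheme, catalog)
        assert "g1" in tiers.polymerase_positive
        assert "g1" not in tiers.spd_positive

    def test_audit_records_every_genome_and_rule(self, scheme, catalog):
        anns = annotate({"g1": {"PhaC": 1, "GH2": 1}, "g2": {"GH117": 1}})
        tiers = run_cascade(anns, scheme, catalog)
        base_rules = {"polymerase_positive", "spd_positive", "enriched", "highly_enriched"}
        for g in ("g1", "g2"):
            assert base_rules <= set(tiers.audit.query("genome_id == @g")["rule"])

    def test_family_tier(self, scheme, catalog, toy_taxonomy):
        # family 1000 accumulates 2 unique red labels across two genomes
        anns = annotate({"g1": {"GH117": 1, "PhaC": 1}, "g2": {"GH118": 1}})
        tiers = run_cascade(
            anns, scheme, catalog, taxonomy=toy_taxonomy,
            genome_taxids={"g1": 10000, "g2": 10001},
        )
        assert tiers.family_enriched == {1000}

    def test_matches_brute_force_on_random_tables(self, scheme, catalog):
        rng = np.random.default_rng(42)
        labels = sorted(scheme.all_labels)[:12] + ["PhaC", "PhaE", "PhaB", "GH1"]
        for _ in range(5):
            spec = {
                f"g{i}": {
                    l: int(rng.poisson(0.5))
                    for l in rng.choice(labels, size=6, replace=False)
                }
                for i in range(40)
            }
            spec = {g: {l: c for l, c in d.items() if c} for g, d in spec.items()}
            anns = annotate(spec)
            tiers = run_cascade(anns, scheme, catalog, all_genomes=sorted(spec))
            pol, spd, enr, high, top = brute_force_tiers(spec, scheme, catalog)
            assert tiers.polymerase_positive == pol
            assert tiers.spd_positive == spd
            assert tiers.enriched == enr
            assert tiers.highly_enriched == high
            assert tiers.top_percentile == top

    def test_adding_spd_labels_never_demotes(self, scheme, catalog):
        base = {"g1": {"PhaC": 1, "GH2": 1, "GH43": 1, "PL28": 1},
                "g2": {"PhaC": 1, "GH117": 1}}
        grown = {g: dict(d) for g, d in base.items()}
        grown["g2"]["GH118"] = 2  # add SPD annotations to g2 only
        t0 = run_cascade(annotate(base), scheme, catalog)
        t1 = run_cascade(annotate(grown), scheme, catalog)
        for tier in ("polymerase_positive", "spd_positive", "enriched", "highly_enriched"):
            assert getattr(t0, tier) - {"g2"} <= getattr(t1, tier)
            assert ("g2" in getattr(t0, tier)) <= ("g2" in getattr(t1, tier))

    def test_nesting_invariant(self, scheme, catalog):
        rng = np.random.default_rng(7)
        labels = sorted(scheme.all_labels)[:10] + ["PhaC"]
        spec = {
            f"g{i}": {l: 1 for l in rng.choice(labels, size=4, replace=False)}
            for i in range(30)
        }
        tiers = run_cascade(annotate(spec), scheme, catalog)
        tiers.check_nesting()

    def test_percentile_metric_unique_configurable(self, scheme, catalog):
        anns = annotate({
            "g1": {"PhaC": 1, "GH2": 10, "GH43": 1, "PL28": 1},
            "g2": {"PhaC": 1, "GH2": 1, "GH43": 1, "PL28": 1, "GH78": 1},
        })
        cfg = ScreeningConfig(percentile_metric="unique")
        tiers = run_cascade(anns, scheme, catalog, config=cfg)
        # by unique green families g2 (4) beats g1 (3)
        assert "g2" in tiers.top_percentile["green"]
        assert "g1" not in tiers.top_percentile["green"]


class TestScreeningConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"percentile": 0.0}, {"percentile": 100.0},
        {"percentile_metric": "bogus"}, {"percentile_method": "bogus"},
    ])
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            ScreeningConfig(**kw)
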