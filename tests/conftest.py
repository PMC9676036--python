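import pytest

from seapha.tables_io import (
    AlgalClassScheme,
    Category,
    GeneAnnotation,
    PhaGeneCatalog,
    expected_category,
)
from seapha.taxonomy import TaxonomyDB


def ann(genome, gene, label, position=None):
    """Shorthand GeneAnnotation with the category implied by the label."""
    return GeneAnnotation(genome, gene, label, expected_category(label), position)


def annotate(spec: dict[str, dict[str, int]]):
    """Build annotations from {genome: {label: count}} with unique gene ids."""
    out = []
    for g, labels in spec.items():
        i = 0
        for label, count in labels.items():
            for _ in range(count):
                i += 1
                out.append(ann(g, f"{g}_g{i}", label))
    return out


@pytest.fixture(scope="session")
def scheme():
    return AlgalClassScheme.default()


@pytest.fixture(scope="session")
def catalog():
    return PhaGeneCatalog.default()


@pytest.fixture(scope="session")
def toy_taxonomy():
    """root(1) > phylum(10, 11) > order(100, 101) > family(1000..1002) > species.

    Species 20000 hangs directly off phylum 11 so its lineage has no family
    rank (UNKNOWN case).
    """
    records = [
        (1, 1, "no rank", "root"),
        (10, 1, "phylum", "PhylumA"),
        (11, 1, "phylum", "PhylumB"),
        (100, 10, "order", "OrderA1"),
        (101, 11, "order", "OrderB1"),
        (1000, 100, "family", "FamA1a"),
        (1001, 100, "family", "FamA1b"),
        (1002, 101, "family", "FamB1a"),
        (10000, 1000, "species", "Sp. one"),
        (10001, 1000, "species", "Sp. two"),
        (10002, 1001, "species", "Sp. three"),
        (10003, 1002, "species", "Sp. four"),
        (20000, 11, "species", "Sp. orphan"),
    ]
    return TaxonomyDB.from_records(records)
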