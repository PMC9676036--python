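"""Lineage tracing and family-rank aggregation over an NCBI-style taxonomy.

The taxonomy is a rooted tree of (taxid, parent, rank, name) nodes read from
taxdump-dialect ``nodes.dmp``/``names.dmp`` files or a flat lineage TSV.
Genomes are aggregated at the literal rank ``family`` (case-insensitive
comparison); nodes whose lineage carries no family rank map to the
:data:`UNKNOWN_FAMILY` sentinel and are retained in genome-level screens but
excluded from family-level reports.

The "phylogenetic tree" exported here is a taxonomy cladogram — topology
comes from the taxonomy, not from sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from skbio.tree import TreeNode

__all__ = [
    "UNKNOWN_FAMILY",
    "TaxonomyError",
    "TaxonomyDB",
    "TaxonTree",
    "trace_lineage",
    "family_of",
    "build_family_tree",
]

#: Sentinel taxid for genomes whose lineage has no node of rank "family".
UNKNOWN_FAMILY = -1


class TaxonomyError(KeyError):
    """Unknown taxid or structurally invalid taxonomy."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyDB:
    """taxid -> (parent, rank, name) with exactly one self-parent root."""

    nodes: dict[int, TaxonNode]
    root: int = field(init=False)

    def __post_init__(self) -> None:
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t, n in self.nodes.items():
            if n.parent not in self.nodes:
                raise TaxonomyError(f"node {t} has missing parent {n.parent}")
        # cycle check by walking every node to root with a step budget
        limit = len(self.nodes) + 1
        for t in self.nodes:
            cur, steps = t, 0
            while cur != self.root:
                cur = self.nodes[cur].parent
                steps += 1
                if steps > limit:
                    raise TaxonomyError(f"cycle detected at taxid {t}")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name_of(self, taxid: int) -> str:
        return self.nodes[taxid].name

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: list[tuple[int, int, str, str]]
    ) -> "TaxonomyDB":
        """Build from (taxid, parent, rank, name) tuples."""
        return cls(nodes={t: TaxonNode(t, p, r, n) for t, p, r, n in records})

    @classmethod
    def from_taxdump(cls, nodes_path: str | Path, names_path: str | Path) -> "TaxonomyDB":
        """Read pipe-delimited ``nodes.dmp`` and ``names.dmp``.

        Only ``scientific name`` rows of names.dmp are used; nodes lacking a
        scientific name get ``taxid:<id>`` as a placeholder.
        """
        names: dict[int, str] = {}
        with open(names_path, encoding="utf-8") as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\n").rstrip("|").split("|")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[int(parts[0])] = parts[1]
        records = []
        with open(nodes_path, encoding="utf-8") as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\n").rstrip("|").split("|")]
                taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
                records.append((taxid, parent, rank, names.get(taxid, f"taxid:{taxid}")))
        return cls.from_records(records)

    @classmethod
    def from_lineage_tsv(cls, path: str | Path) -> "TaxonomyDB":
        """Read a flat ``taxid<TAB>lineage`` table.

        The lineage is root-first, semicolon-separated ``rank:name`` pairs;
        the row's taxid is the last element.  Internal nodes are assigned
        deterministic synthetic taxids (names are the identity key).
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if not {"taxid", "lineage"}.issubset(df.columns):
            raise TaxonomyError(f"{path}: need columns taxid, lineage")
        key_to_id: dict[tuple[str, str], int] = {}
        records: dict[int, tuple[int, str, str]] = {}
        next_internal = -2  # negative ids for unnumbered internal nodes
        for _, row in df.iterrows():
            leaf_taxid = int(row["taxid"])
            pairs = [p for p in str(row["lineage"]).split(";") if p]
            parent = None
            for i, pair in enumerate(pairs):
                rank, _, name = pair.partition(":")
                is_leaf = i == len(pairs) - 1
                key = (rank, name)
                if is_leaf:
                    tid = leaf_taxid
                elif key in key_to_id:
                    tid = key_to_id[key]
                else:
                    tid = next_internal
                    next_internal -= 1
                key_to_id.setdefault(key, tid)
                records[tid] = (tid if parent is None else parent, rank, name)
                parent = tid
        return cls.from_records([(t, p, r, n) for t, (p, r, n) in records.items()])

    def to_taxdump(self, nodes_path: str | Path, names_path: str | Path) -> None:
        with open(nodes_path, "w", encoding="utf-8") as fh:
            for t in sorted(self.nodes):
                n = self.nodes[t]
                fh.write(f"{t}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
        with open(names_path, "w", encoding="utf-8") as fh:
            for t in sorted(self.nodes):
                fh.write(f"{t}\t|\t{self.nodes[t].name}\t|\t\t|\tscientific name\t|\n")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def trace_lineage(db: TaxonomyDB, taxid: int) -> list[tuple[int, str, str]]:
    """Ordered (taxid, rank, name) list from the query node up to the root."""
    if taxid not in db:
        raise TaxonomyError(f"unknown taxid: {taxid}")
    out = []
    cur = taxid
    while True:
        node = db.nodes[cur]
        out.append((cur, node.rank, node.name))
        if cur == db.root:
            return out
        cur = node.parent


def family_of(db: TaxonomyDB, taxid: int) -> int:
    """Taxid of the family-rank ancestor (or self), else UNKNOWN_FAMILY."""
    if taxid not in db:
        raise TaxonomyError(f"unknown taxid: {taxid}")
    cur = taxid
    while True:
        node = db.nodes[cur]
        if node.rank.lower() == "family":
            return cur
        if cur == db.root:
            return UNKNOWN_FAMILY
        cur = node.parent


@dataclass
class TaxonTree:
    """Taxonomy cladogram over a set of family taxids.

    ``tree`` is an ``skbio.TreeNode`` whose leaves are the families (named by
    taxon name); per-node density vectors can be attached via ``attach``.
    """

    tree: TreeNode
    leaf_taxids: dict[str, int]
    densities: dict[int, dict[str, float]] = field(default_factory=dict)

    def attach(self, taxid: int, vector: dict[str, float]) -> None:
        if taxid not in self.leaf_taxids.values():
            raise TaxonomyError(f"taxid {taxid} is not a leaf of this tree")
        self.densities[taxid] = dict(vector)

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()] if self.tree.children else [self.tree.name]


def build_family_tree(db: TaxonomyDB, families: set[int]) -> TaxonTree:
    """Taxonomy restricted to ``families`` and their ancestors, unary nodes collapsed."""
    if not families:
        raise ValueError("family set is empty")
    missing = [f for f in families if f not in db]
    if missing:
        raise TaxonomyError(f"unknown family taxid(s): {missing}")

    children: dict[int, set[int]] = {}
    keep: set[int] = set()
    for fam in families:
        path = [t for t, _, _ in trace_lineage(db, fam)]
        for child, parent in zip(path, path[1:]):
            children.setdefault(parent, set()).add(child)
        keep.update(path)

    def build(taxid: int) -> TreeNode:
        kids = sorted(children.get(taxid, ()))
        node = TreeNode(name=db.name_of(taxid))
        node.children = []
        for k in kids:
            node.append(build(k))
        return node

    root = build(db.root)
    # collapse unary internal chains (a family leaf itself is never collapsed)
    fam_names = {db.name_of(f) for f in families}

    def collapse(node: TreeNode) -> TreeNode:
        while len(node.children) == 1 and node.name not in fam_names:
            node = node.children[0]
        node.children = [collapse(c) for c in list(node.children)]
        for c in node.children:
            c.parent = node
        return node

    root = collapse(root)
    return TaxonTree(tree=root, leaf_taxids={db.name_of(f): f for f in families})
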