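"""Gene–gene co-occurrence statistics, networks and profile clustering.

For each pair of gene labels over a genome cohort we report the sample
Pearson correlation of their per-genome count vectors (two-sided p from the
t distribution with n−2 df), the Jaccard distance between their presence
sets (presence = count > 0), and the co-presence count.  Raw p-values are
kept (the screening criterion in this analysis style is uncorrected
P < 0.05) with Benjamini–Hochberg q-values exported alongside.

The co-occurrence network has one node per label (size log2(total+1)), an
edge wherever co-presence reaches ``min_copresence`` (weight log2(count+1)),
and node cluster assignments from Euclidean agglomerative clustering of the
log2 profiles — a deterministic stand-in for presentation-layer block-model
layouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .density import DensityMatrix, log2_normalize
from .tables_io import AlgalClassScheme, PhaGeneCatalog

__all__ = [
    "CorrelationResult",
    "CooccurrenceNetwork",
    "density_vectors",
    "pearson_with_p",
    "jaccard_distance",
    "correlation_matrix",
    "build_network",
    "cluster_profiles",
]


@dataclass(frozen=True)
class CorrelationResult:
    label_a: str
    label_b: str
    r: float  # NaN when either vector is constant
    p: float  # NaN when r undefined
    jd: float  # NaN when neither label is ever present
    n: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


def density_vectors(matrix: DensityMatrix, labels: Sequence[str]) -> pd.DataFrame:
    """Per-label count vectors over genomes (columns of the density matrix)."""
    missing = [l for l in labels if l not in matrix.counts.columns]
    if missing:
        raise KeyError(f"labels not in matrix: {missing}")
    return matrix.counts[list(labels)]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with two-sided p (t distribution, n−2 df).

    Constant input flags the correlation undefined: returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def jaccard_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 − |A∩B|/|A∪B| over presence sets (count > 0); NaN if both empty."""
    a = np.asarray(x) > 0
    b = np.asarray(y) > 0
    union = int(np.sum(a | b))
    if union == 0:
        return float("nan")
    return 1.0 - int(np.sum(a & b)) / union


def correlation_matrix(
    matrix: DensityMatrix,
    labels: Sequence[str] | None = None,
    *,
    use_log2: bool = False,
) -> pd.DataFrame:
    """All-pairs correlation long table: ``label_a label_b r p q jd n``.

    Pairs are emitted once (a < b in the given label order).  q is the
    Benjamini–Hochberg adjusted p over the defined pairs.
    """
    labels = list(labels) if labels is not None else matrix.labels
    vecs = density_vectors(matrix, labels)
    data = log2_normalize(vecs) if use_log2 else vecs
    n = data.shape[0]
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r, p = pearson_with_p(data[a].to_numpy(), data[b].to_numpy())
            jd = jaccard_distance(vecs[a].to_numpy(), vecs[b].to_numpy())
            rows.append({"label_a": a, "label_b": b, "r": r, "p": p, "jd": jd, "n": n})
    df = pd.DataFrame(rows, columns=["label_a", "label_b", "r", "p", "jd", "n"])
    df["q"] = np.nan
    defined = df["p"].notna()
    if defined.any():
        df.loc[defined, "q"] = multipletests(df.loc[defined, "p"], method="fdr_bh")[1]
    return df[["label_a", "label_b", "r", "p", "q", "jd", "n"]]


@dataclass
class CooccurrenceNetwork:
    """Label co-occurrence graph with log2 node sizes and cluster labels."""

    graph: nx.Graph
    clusters: dict[str, int]
    linkage_matrix: np.ndarray | None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            {"label_a": a, "label_b": b, "copresence": d["copresence"], "weight": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["label_a", "label_b", "copresence", "weight"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(
    matrix: DensityMatrix,
    min_copresence: int = 1,
    *,
    n_clusters: int | None = None,
    linkage_method: str = "average",
) -> CooccurrenceNetwork:
    """Build the label co-occurrence network over genomes.

    Edge iff the pair is co-present in ≥ ``min_copresence`` genomes; edge
    weight and node size are log2(count + 1).  Node clusters come from
    :func:`cluster_profiles` on the log2 label profiles (default
    ``min(8, n_labels)`` flat clusters).
    """
    if min_copresence < 1:
        raise ValueError("min_copresence must be ≥ 1")
    labels = matrix.labels
    present = (matrix.counts > 0).to_numpy()
    totals = matrix.counts.sum(axis=0)

    g = nx.Graph()
    for j, lab in enumerate(labels):
        g.add_node(
            lab,
            presence=int(present[:, j].sum()),
            total=int(totals.iloc[j]),
            size=float(np.log2(totals.iloc[j] + 1)),
        )
    co = present.astype(int).T @ present.astype(int)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            c = int(co[i, j])
            if c >= min_copresence:
                g.add_edge(labels[i], labels[j], copresence=c, weight=float(np.log2(c + 1)))

    clusters: dict[str, int] = {l: 1 for l in labels}
    link: np.ndarray | None = None
    if len(labels) >= 2:
        k = n_clusters if n_clusters is not None else min(8, len(labels))
        link, _, flat = cluster_profiles(
            log2_normalize(matrix), axis="columns", n_clusters=k, linkage_method=linkage_method
        )
        clusters = dict(zip(labels, (int(c) for c in flat)))
    for lab, c in clusters.items():
        g.nodes[lab]["cluster"] = c
    return CooccurrenceNetwork(graph=g, clusters=clusters, linkage_matrix=link)


def cluster_profiles(
    data: pd.DataFrame,
    axis: str = "rows",
    n_clusters: int | None = None,
    height: float | None = None,
    linkage_method: str = "average",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Euclidean agglomerative clustering of profiles along one axis.

    Returns (scipy linkage matrix, leaf order as item names, flat cluster
    labels).  Cut either at ``n_clusters`` or at dissimilarity ``height``;
    with neither, everything is one cluster.  Leaf order is the deterministic
    scipy dendrogram order (tie-break by input position).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    df = data if axis == "rows" else data.T
    items = [str(i) for i in df.index]
    if len(items) < 2:
        raise ValueError("need ≥2 items to cluster")
    if n_clusters is not None and n_clusters > len(items):
        raise ValueError(f"n_clusters={n_clusters} exceeds item count {len(items)}")
    link = linkage(pdist(df.to_numpy(dtype=float), metric="euclidean"), method=linkage_method)
    order = dendrogram(link, no_plot=True)["leaves"]
    leaf_order = [items[i] for i in order]
    if n_clusters is not None:
        flat = fcluster(link, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = fcluster(link, t=height, criterion="distance")
    else:
        flat = np.ones(len(items), dtype=int)
    return link, leaf_order, flat
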