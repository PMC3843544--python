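"""The typed miRNA-TF-gene regulatory network and its summary statistics.

The network is a simple directed graph over three node classes. Edge
direction and relation class are constrained jointly (a ``mir2tf`` edge runs
miRNA -> TF and so on), genes are pure sinks, and duplicate edges collapse.
On top of the container sit the descriptive statistics of the study: per
relation-class summary counts, degree distributions, top-degree hubs with a
tie-expansion rule, miRNA/TF interplay fractions, and two-way hierarchical
clustering of the binary miRNA x TF regulation matrix.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .relations import RELATION_CLASSES, RELATION_ENDPOINTS, RelationTables

logger = logging.getLogger(__name__)

NODE_CLASSES = ("mirna", "tf", "gene")


class NodeClassError(ValueError):
    """An id is used with two incompatible node classes."""


@dataclass
class RegulatoryNetwork:
    """Simple directed heterogeneous graph over {miRNA, TF, gene}."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -----------------------------------------------------

    def add_edge(self, source: str, target: str, relation_class: str) -> None:
        src_kind, tgt_kind = RELATION_ENDPOINTS[relation_class]
        for node, kind in ((source, src_kind), (target, tgt_kind)):
            known = self.graph.nodes.get(node, {}).get("kind")
            if known is not None and known != kind:
                raise NodeClassError(
                    f"id {node!r} used as both {known} and {kind}"
                )
            self.graph.add_node(node, kind=kind)
        self.graph.add_edge(source, target, relation=relation_class)

    def copy_with_edges(
        self, edges: Iterable[tuple[str, str, str]]
    ) -> "RegulatoryNetwork":
        """New network with the same node set/classes but the given edges."""
        other = RegulatoryNetwork()
        for node, data in self.graph.nodes(data=True):
            other.graph.add_node(node, **data)
        for source, target, rel in edges:
            other.add_edge(source, target, rel)
        return other

    # -- inspection -------------------------------------------------------

    def nodes_of(self, kind: str) -> list[str]:
        if kind not in NODE_CLASSES:
            raise ValueError(f"unknown node class: {kind}")
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind
        )

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def iter_edges(self) -> Iterator[tuple[str, str, str]]:
        for u, v, rel in self.graph.edges(data="relation"):
            yield u, v, rel

    def edges_of(self, relation_class: str) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, v, rel in self.iter_edges() if rel == relation_class
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str, direction: str = "total") -> int:
        if direction == "in":
            return self.graph.in_degree(node)
        if direction == "out":
            return self.graph.out_degree(node)
        if direction == "total":
            return self.graph.degree(node)
        raise ValueError(f"unknown direction: {direction}")

    def to_tables(self) -> RelationTables:
        return RelationTables.from_pairs(
            {rel: self.edges_of(rel) for rel in RELATION_CLASSES}
        ).sorted()


def build_network(tables: RelationTables) -> RegulatoryNetwork:
    """Deduplicated typed graph from the four relation tables.

    Node classes are inferred from the relation classes; an id used with two
    incompatible classes raises :class:`NodeClassError` naming the id.
    """
    net = RegulatoryNetwork()
    for _, row in tables.drop_duplicates().edges.iterrows():
        net.add_edge(row["source_id"], row["target_id"], row["relation_class"])
    return net


@dataclass(frozen=True)
class ClassSummary:
    n_pairs: int
    n_sources: int
    n_targets: int


@dataclass(frozen=True)
class NetworkSummary:
    """Per-relation-class pair/source/target counts and node-class counts."""

    relations: dict[str, ClassSummary]
    node_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "relation_class": rel,
                "n_pairs": s.n_pairs,
                "n_sources": s.n_sources,
                "n_targets": s.n_targets,
            }
            for rel, s in self.relations.items()
        ]
        return pd.DataFrame(rows)


def summarize(network: RegulatoryNetwork) -> NetworkSummary:
    relations = {}
    for rel in RELATION_CLASSES:
        pairs = network.edges_of(rel)
        relations[rel] = ClassSummary(
            n_pairs=len(pairs),
            n_sources=len({u for u, _ in pairs}),
            n_targets=len({v for _, v in pairs}),
        )
    node_counts = {kind: len(network.nodes_of(kind)) for kind in NODE_CLASSES}
    return NetworkSummary(relations, node_counts)


def degree_distribution(
    network: RegulatoryNetwork, node_class: str, direction: str = "total"
) -> dict[int, int]:
    """Histogram degree -> number of nodes, over nodes of one class."""
    return dict(
        Counter(network.degree(n, direction) for n in network.nodes_of(node_class))
    )


def hubs(
    network: RegulatoryNetwork,
    node_class: str,
    direction: str = "out",
    fraction: float = 0.05,
) -> list[str]:
    """Top-degree nodes of a class: the ceil(fraction * n) highest degrees.

    Nodes are ordered by degree descending then id ascending; ties straddling
    the cutoff are all included (the expansion is logged).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    nodes = network.nodes_of(node_class)
    if not nodes:
        return []
    ranked = sorted(nodes, key=lambda n: (-network.degree(n, direction), n))
    k = math.ceil(fraction * len(nodes))
    cutoff_degree = network.degree(ranked[k - 1], direction)
    out = [n for n in ranked if network.degree(n, direction) >= cutoff_degree]
    if len(out) > k:
        logger.info(
            "hub cutoff tie at degree %d expanded %s list from %d to %d",
            cutoff_degree, node_class, k, len(out),
        )
    return out


@dataclass(frozen=True)
class InterplayStats:
    """How much the two regulator layers regulate each other."""

    n_mirna: int
    n_mirna_tf_regulated: int
    n_tf: int
    n_tf_mirna_regulated: int
    frac_mirna_tf_regulated: float
    frac_tf_mirna_regulated: float
    frac_regulated_mirna_high_indegree: float  # among TF-regulated miRNAs
    frac_regulated_tf_high_indegree: float     # among miRNA-regulated TFs
    mean_tf_regulators_per_regulated_mirna: float
    mean_mirna_regulators_per_regulated_tf: float


def interplay_stats(
    network: RegulatoryNetwork,
    mirna_indeg_cut: int = 5,
    tf_indeg_cut: int = 50,
) -> InterplayStats:
    """Cross-layer regulation fractions (exact; round only for display)."""
    mirnas = network.nodes_of("mirna")
    tfs = network.nodes_of("tf")
    mirna_indeg = {m: network.degree(m, "in") for m in mirnas}
    tf_indeg = {t: network.degree(t, "in") for t in tfs}
    regulated_mirnas = [m for m, d in mirna_indeg.items() if d > 0]
    regulated_tfs = [t for t, d in tf_indeg.items() if d > 0]

    def frac(num: int, den: int) -> float:
        return num / den if den else 0.0

    return InterplayStats(
        n_mirna=len(mirnas),
        n_mirna_tf_regulated=len(regulated_mirnas),
        n_tf=len(tfs),
        n_tf_mirna_regulated=len(regulated_tfs),
        frac_mirna_tf_regulated=frac(len(regulated_mirnas), len(mirnas)),
        frac_tf_mirna_regulated=frac(len(regulated_tfs), len(tfs)),
        frac_regulated_mirna_high_indegree=frac(
            sum(mirna_indeg[m] > mirna_indeg_cut for m in regulated_mirnas),
            len(regulated_mirnas),
        ),
        frac_regulated_tf_high_indegree=frac(
            sum(tf_indeg[t] > tf_indeg_cut for t in regulated_tfs),
            len(regulated_tfs),
        ),
        mean_tf_regulators_per_regulated_mirna=frac(
            sum(mirna_indeg[m] for m in regulated_mirnas), len(regulated_mirnas)
        ),
        mean_mirna_regulators_per_regulated_tf=frac(
            sum(tf_indeg[t] for t in regulated_tfs), len(regulated_tfs)
        ),
    )


def regulation_matrix(network: RegulatoryNetwork) -> pd.DataFrame:
    """Binary miRNA x TF matrix: 1 iff an edge runs m->t or t->m."""
    mirnas = network.nodes_of("mirna")
    tfs = network.nodes_of("tf")
    matrix = pd.DataFrame(0, index=mirnas, columns=tfs, dtype=int)
    for u, v, rel in network.iter_edges():
        if rel == "mir2tf":
            matrix.loc[u, v] = 1
        elif rel == "tf2mir":
            matrix.loc[v, u] = 1
    return matrix


@dataclass
class ClusteringResult:
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    ordered: pd.DataFrame


def _linkage(matrix: np.ndarray, distance: str, linkage: str) -> np.ndarray | None:
    if matrix.shape[0] < 2:
        return None
    dist = pdist(matrix, metric=distance)
    # two all-zero rows have undefined Jaccard distance; treat them as identical
    dist = np.nan_to_num(dist, nan=0.0)
    return hierarchy.linkage(dist, method=linkage)


def cluster_two_way(
    matrix: pd.DataFrame,
    distance: str = "jaccard",
    linkage: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of rows and columns of a binary matrix."""
    if matrix.empty:
        raise ValueError("matrix must be non-empty")
    values = matrix.to_numpy(bool) if distance == "jaccard" else matrix.to_numpy(float)
    row_link = _linkage(values, distance, linkage)
    col_link = _linkage(values.T, distance, linkage)
    row_order = (
        [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
        if row_link is not None
        else list(matrix.index)
    )
    col_order = (
        [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
        if col_link is not None
        else list(matrix.columns)
    )
    return ClusteringResult(
        row_link, col_link, row_order, col_order, matrix.loc[row_order, col_order]
    )


def cluster_leaf_sets(
    linkage_matrix: np.ndarray, labels: list[str]
) -> list[frozenset[str]]:
    """Leaf set of every internal node of a scipy linkage tree.

    A label subset is a monophyletic cluster iff it appears in this list.
    """
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(linkage_matrix):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        out.append(merged)
    return out
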