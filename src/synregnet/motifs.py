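"""Three-node motif census and its degree-preserving randomization null.

A triple (miRNA m, TF t, gene g) is classified by its exact edge
configuration over the four possible edges m->t, t->m, m->g, t->g
(induced matching: edges absent from a template must be absent from the
network). Ten templates qualify as synergistic motifs:

    I    m->t, t->m, m->g, t->g   full regulation (FBL + both on the gene)
    II   m->t,       m->g, t->g   miRNA-leading feed-forward loop
    III        t->m, m->g, t->g   TF-leading feed-forward loop
    IV   m->t, t->m, m->g         feedback loop, miRNA holds the gene
    V    m->t, t->m,       t->g   feedback loop, TF holds the gene
    VI               m->g, t->g   co-regulation (no miRNA-TF edge)
    VII  m->t,       m->g         miRNA simultaneous regulation
    VIII       t->m, m->g         miRNA-mediated cascade (t->m->g)
    IX   m->t,             t->g   TF-mediated cascade (m->t->g)
    X          t->m,       t->g   TF simultaneous regulation

Configurations with no edge onto the gene, or a lone m->g / t->g with no
miRNA-TF edge, are not motifs. Significance of each type is assessed
against random networks that preserve every node's in- and out-degree
within each relation class (repeated double-edge swaps): the empirical
P-value is the fraction of null replicates whose count reaches the observed
count, and the Z-score standardizes the observed count by the null mean and
standard deviation.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .network import RegulatoryNetwork
from .relations import RELATION_CLASSES

logger = logging.getLogger(__name__)

#: edge slots of a (m, t, g) triple, in canonical order
EDGE_SLOTS = ("m2t", "t2m", "m2g", "t2g")

MOTIF_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

MOTIF_TEMPLATES: dict[str, frozenset[str]] = {
    "I": frozenset({"m2t", "t2m", "m2g", "t2g"}),
    "II": frozenset({"m2t", "m2g", "t2g"}),
    "III": frozenset({"t2m", "m2g", "t2g"}),
    "IV": frozenset({"m2t", "t2m", "m2g"}),
    "V": frozenset({"m2t", "t2m", "t2g"}),
    "VI": frozenset({"m2g", "t2g"}),
    "VII": frozenset({"m2t", "m2g"}),
    "VIII": frozenset({"t2m", "m2g"}),
    "IX": frozenset({"m2t", "t2g"}),
    "X": frozenset({"t2m", "t2g"}),
}

MOTIF_NAMES = {
    "I": "full regulation",
    "II": "miRNA-leading FFL",
    "III": "TF-leading FFL",
    "IV": "FBL with miRNA-regulated gene",
    "V": "FBL with TF-regulated gene",
    "VI": "co-regulation",
    "VII": "miRNA simultaneous regulation",
    "VIII": "miRNA-mediated cascade",
    "IX": "TF-mediated cascade",
    "X": "TF simultaneous regulation",
}

#: (has m2t, has t2m, has m2g, has t2g) -> motif type
_CONFIG_TO_TYPE: dict[tuple[bool, bool, bool, bool], str] = {
    tuple(slot in template for slot in EDGE_SLOTS): motif_id
    for motif_id, template in MOTIF_TEMPLATES.items()
}


@dataclass(frozen=True)
class MotifInstance:
    mirna: str
    tf: str
    gene: str
    motif_type: str


@dataclass(frozen=True)
class MotifStats:
    """Observed count of one motif type against its randomization null."""

    motif_type: str
    n_real: int
    n_mean: float
    sd: float
    n_high: int
    n_random: int

    @property
    def p(self) -> float:
        return empirical_p(self.n_high, self.n_random)

    @property
    def z(self) -> float | None:
        """Standardized score, or None when the null has zero spread."""
        if self.sd <= 0:
            return None
        return zscore(self.n_real, self.n_mean, self.sd)


def zscore(n_real: float, n_mean: float, sd: float) -> float:
    """Observed motif count standardized by the null mean and SD."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (n_real - n_mean) / sd


def empirical_p(n_high: int, n_random: int) -> float:
    """Fraction of null replicates with count >= the observed count."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if not 0 <= n_high <= n_random:
        raise ValueError("need 0 <= n_high <= n_random")
    return n_high / n_random


# -- classification and counting ------------------------------------------


def _adjacency(network: RegulatoryNetwork) -> dict[str, dict[str, set[str]]]:
    adj: dict[str, dict[str, set[str]]] = {
        rel: defaultdict(set) for rel in RELATION_CLASSES
    }
    for u, v, rel in network.iter_edges():
        adj[rel][u].add(v)
    return adj


def classify_triple(
    network: RegulatoryNetwork, m: str, t: str, g: str
) -> str | None:
    """Motif type of the exact edge configuration over (m, t, g), or None."""
    if network.kind(m) != "mirna" or network.kind(t) != "tf" or network.kind(g) != "gene":
        raise ValueError("classify_triple expects (miRNA, TF, gene) node classes")
    graph = network.graph
    config = (
        graph.has_edge(m, t),
        graph.has_edge(t, m),
        graph.has_edge(m, g),
        graph.has_edge(t, g),
    )
    return _CONFIG_TO_TYPE.get(config)


def motif_instances(
    network: RegulatoryNetwork, types: tuple[str, ...] | None = None
) -> Iterator[MotifInstance]:
    """Stream every motif instance (optionally restricted to some types)."""
    wanted = set(MOTIF_TYPES if types is None else types)
    adj = _adjacency(network)
    m2t, t2m = adj["mir2tf"], adj["tf2mir"]
    m2g, t2g = adj["mir2gene"], adj["tf2gene"]
    # regulator pairs joined by at least one miRNA-TF edge
    pairs = {(m, t) for m in m2t for t in m2t[m]}
    pairs |= {(m, t) for t in t2m for m in t2m[t]}
    for m, t in sorted(pairs):
        has_mt = t in m2t.get(m, ())
        has_tm = m in t2m.get(t, ())
        for g in sorted(m2g.get(m, set()) | t2g.get(t, set())):
            config = (has_mt, has_tm, g in m2g.get(m, ()), g in t2g.get(t, ()))
            motif_id = _CONFIG_TO_TYPE[config]
            if motif_id in wanted:
                yield MotifInstance(m, t, g, motif_id)
    if "VI" in wanted:
        # co-regulation: both regulators hit the gene, no miRNA-TF edge
        gene_mirnas: dict[str, list[str]] = defaultdict(list)
        for m in m2g:
            for g in m2g[m]:
                gene_mirnas[g].append(m)
        gene_tfs: dict[str, list[str]] = defaultdict(list)
        for t in t2g:
            for g in t2g[t]:
                gene_tfs[g].append(t)
        for g in sorted(set(gene_mirnas) & set(gene_tfs)):
            for m in sorted(gene_mirnas[g]):
                for t in sorted(gene_tfs[g]):
                    if t not in m2t.get(m, ()) and m not in t2m.get(t, ()):
                        yield MotifInstance(m, t, g, "VI")


def count_motifs(network: RegulatoryNetwork) -> dict[str, int]:
    """Counts per motif type over all qualifying triples.

    Equivalent to classifying every (m, t, g) triple exhaustively, but
    enumerates only triples that can qualify: pairs with a miRNA-TF edge
    plus their gene targets, and the co-regulation count in closed form.
    """
    adj = _adjacency(network)
    m2t, t2m = adj["mir2tf"], adj["tf2mir"]
    m2g, t2g = adj["mir2gene"], adj["tf2gene"]
    counts = Counter({motif_id: 0 for motif_id in MOTIF_TYPES})
    pairs = {(m, t) for m in m2t for t in m2t[m]}
    pairs |= {(m, t) for t in t2m for m in t2m[t]}
    for m, t in pairs:
        has_mt = t in m2t.get(m, ())
        has_tm = m in t2m.get(t, ())
        m_genes = m2g.get(m, set())
        t_genes = t2g.get(t, set())
        both = len(m_genes & t_genes)
        n_m = len(m_genes) - both
        n_t = len(t_genes) - both
        if has_mt and has_tm:
            counts["I"] += both
            counts["IV"] += n_m
            counts["V"] += n_t
        elif has_mt:
            counts["II"] += both
            counts["VII"] += n_m
            counts["IX"] += n_t
        else:  # t->m only
            counts["III"] += both
            counts["VIII"] += n_m
            counts["X"] += n_t
    # all (m, t, g) with both gene edges, minus those that have a miRNA-TF edge
    gene_m = Counter()
    gene_pairs_total = 0
    t_count_per_gene: dict[str, int] = Counter()
    for m in m2g:
        for g in m2g[m]:
            gene_m[g] += 1
    for t in t2g:
        for g in t2g[t]:
            t_count_per_gene[g] += 1
    for g, n_m in gene_m.items():
        gene_pairs_total += n_m * t_count_per_gene.get(g, 0)
    counts["VI"] = gene_pairs_total - counts["I"] - counts["II"] - counts["III"]
    return dict(counts)


def census(network: RegulatoryNetwork) -> pd.DataFrame:
    """Per-type instance counts plus distinct participating node counts."""
    counts = Counter()
    mirnas: dict[str, set[str]] = defaultdict(set)
    tfs: dict[str, set[str]] = defaultdict(set)
    genes: dict[str, set[str]] = defaultdict(set)
    for inst in motif_instances(network):
        counts[inst.motif_type] += 1
        mirnas[inst.motif_type].add(inst.mirna)
        tfs[inst.motif_type].add(inst.tf)
        genes[inst.motif_type].add(inst.gene)
    return pd.DataFrame(
        {
            "motif_type": MOTIF_TYPES,
            "name": [MOTIF_NAMES[m] for m in MOTIF_TYPES],
            "n_motifs": [counts.get(m, 0) for m in MOTIF_TYPES],
            "n_genes": [len(genes.get(m, ())) for m in MOTIF_TYPES],
            "n_tfs": [len(tfs.get(m, ())) for m in MOTIF_TYPES],
            "n_mirnas": [len(mirnas.get(m, ())) for m in MOTIF_TYPES],
        }
    )


# -- degree-preserving null -----------------------------------------------


def rewire(
    network: RegulatoryNetwork,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 100,
) -> RegulatoryNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Within each relation class independently, ``swaps_per_edge * n_edges``
    swap attempts replace edge pairs (a->b, c->d) by (a->d, c->b); attempts
    that would duplicate an existing edge are rejected. Per-node in/out
    degree within every class is preserved exactly. Classes with fewer than
    two edges are returned unchanged (logged).
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_edges: list[tuple[str, str, str]] = []
    for rel in RELATION_CLASSES:
        edges = network.edges_of(rel)
        if len(edges) < 2:
            if edges:
                logger.info("relation class %s has < 2 edges; left unchanged", rel)
            new_edges.extend((u, v, rel) for u, v in edges)
            continue
        edge_set = set(edges)
        n_attempts = swaps_per_edge * len(edges)
        picks = rng.integers(0, len(edges), size=(n_attempts, 2))
        for i, j in picks:
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == c or b == d:
                continue
            if (a, d) in edge_set or (c, b) in edge_set:
                continue
            edge_set.discard((a, b))
            edge_set.discard((c, d))
            edge_set.add((a, d))
            edge_set.add((c, b))
            edges[i] = (a, d)
            edges[j] = (c, b)
        new_edges.extend((u, v, rel) for u, v in edges)
    return network.copy_with_edges(new_edges)


def significance(
    network: RegulatoryNetwork,
    n_random: int = 10000,
    seed: int = 0,
    swaps_per_edge: int = 100,
) -> dict[str, MotifStats]:
    """Motif-type significance against the degree-preserving null.

    Each replicate independently rewires the network and recounts all motif
    types; replicate counts are streamed into running moments, never stored.
    The null SD is the population (divide-by-n) standard deviation.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    real = count_motifs(network)
    sums = Counter()
    sumsq = Counter()
    n_high = Counter()
    for child in np.random.SeedSequence(seed).spawn(n_random):
        rng = np.random.default_rng(child)
        null_counts = count_motifs(rewire(network, rng, swaps_per_edge))
        for motif_id in MOTIF_TYPES:
            c = null_counts[motif_id]
            sums[motif_id] += c
            sumsq[motif_id] += c * c
            if c >= real[motif_id]:
                n_high[motif_id] += 1
    stats = {}
    for motif_id in MOTIF_TYPES:
        mean = sums[motif_id] / n_random
        var = max(sumsq[motif_id] / n_random - mean * mean, 0.0)
        stats[motif_id] = MotifStats(
            motif_type=motif_id,
            n_real=real[motif_id],
            n_mean=mean,
            sd=float(np.sqrt(var)),
            n_high=n_high[motif_id],
            n_random=n_random,
        )
    return stats


def stats_frame(stats: Mapping[str, MotifStats]) -> pd.DataFrame:
    """Table-shaped view of per-type significance (Z, P, mean, SD, counts)."""
    rows = []
    for motif_id in MOTIF_TYPES:
        s = stats[motif_id]
        rows.append(
            {
                "motif_type": motif_id,
                "name": MOTIF_NAMES[motif_id],
                "n_real": s.n_real,
                "null_mean": s.n_mean,
                "null_sd": s.sd,
                "z": s.z if s.z is not None else np.nan,
                "p": s.p,
            }
        )
    return pd.DataFrame(rows)


# -- derived structures ----------------------------------------------------


def subnetwork(network: RegulatoryNetwork, motif_type: str) -> RegulatoryNetwork:
    """Union of all instances of one motif type.

    Edge attribute ``n_instances`` records how many instances of the type
    use each edge.
    """
    if motif_type not in MOTIF_TYPES:
        raise ValueError(f"unknown motif type: {motif_type}")
    sub = RegulatoryNetwork()
    template = MOTIF_TEMPLATES[motif_type]
    slot_edges = {
        "m2t": ("mirna", "tf", "mir2tf"),
        "t2m": ("tf", "mirna", "tf2mir"),
        "m2g": ("mirna", "gene", "mir2gene"),
        "t2g": ("tf", "gene", "tf2gene"),
    }
    for inst in motif_instances(network, types=(motif_type,)):
        endpoints = {"mirna": inst.mirna, "tf": inst.tf, "gene": inst.gene}
        for slot in template:
            src_kind, tgt_kind, rel = slot_edges[slot]
            u, v = endpoints[src_kind], endpoints[tgt_kind]
            sub.add_edge(u, v, rel)
            data = sub.graph.edges[u, v]
            data["n_instances"] = data.get("n_instances", 0) + 1
    return sub


def participation(network: RegulatoryNetwork) -> pd.DataFrame:
    """Per-regulator motif instance counts by type.

    One row per miRNA or TF appearing in at least one motif network node
    class, with per-type counts, the total, and the number of types touched.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    kinds: dict[str, str] = {}
    for inst in motif_instances(network):
        counts[inst.mirna][inst.motif_type] += 1
        counts[inst.tf][inst.motif_type] += 1
        kinds[inst.mirna] = "mirna"
        kinds[inst.tf] = "tf"
    regulators = network.nodes_of("mirna") + network.nodes_of("tf")
    rows = []
    for reg in regulators:
        c = counts.get(reg, Counter())
        row = {"regulator": reg, "kind": network.kind(reg)}
        row.update({m: c.get(m, 0) for m in MOTIF_TYPES})
        row["total"] = sum(c.values())
        row["n_types"] = sum(1 for m in MOTIF_TYPES if c.get(m, 0) > 0)
        row["in_all_types"] = row["n_types"] == len(MOTIF_TYPES)
        rows.append(row)
    return pd.DataFrame(rows)
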