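"""Commonality scoring of functional terms across motif subnetworks.

For each motif-type subnetwork i, every miRNA-TF pair's shared target set
(size >= 3) is tested for term over-representation. The per-subnetwork
frequency Frequent_i counts in how many pair sets a term was enriched, and
terms are ranked within each subnetwork by descending frequency. The
network-wide commonality score of a term is

    score = sum_i  Frequent_i / (rank_i * stagenumber_i)

where stagenumber_i is the number of nodes on the longest directed path of
motif template i (3 for the FFL/FBL/cascade templates, 2 for co-regulation
and the simultaneous-regulation templates) and subnetworks where the term
is not enriched contribute 0. The top 5% of scores define the network-wide
common terms; removing them and re-ranking per subnetwork yields each
subnetwork's specific terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import TermAnnotation
from .enrich import EnrichmentInput, bh_adjust, hypergeom_tail
from .motifs import MOTIF_TEMPLATES, MOTIF_TYPES, motif_instances
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


def _longest_path_nodes(template: frozenset[str]) -> int:
    # chains over {m, t, g}: regulator->regulator->gene is the only 3-node path
    if {"m2t", "t2g"} <= template or {"t2m", "m2g"} <= template:
        return 3
    return 2

#: stage number per motif type: nodes on the template's longest directed path
DEFAULT_STAGE_NUMBERS: dict[str, int] = {
    motif_id: _longest_path_nodes(template)
    for motif_id, template in MOTIF_TEMPLATES.items()
}


@dataclass(frozen=True)
class PairTargetSet:
    """Genes synergistically reached by one miRNA-TF pair in a subnetwork."""

    mirna: str
    tf: str
    subnetwork_id: str
    genes: frozenset[str]


def pair_shared_targets(
    subnetwork: RegulatoryNetwork,
    subnetwork_id: str,
    min_genes: int = 3,
) -> list[PairTargetSet]:
    """Per-pair shared target sets within one motif-type subnetwork.

    Enumerates the subnetwork's triples matching the subnetwork's template
    and groups genes by (miRNA, TF) pair; sets smaller than ``min_genes``
    are dropped.
    """
    by_pair: dict[tuple[str, str], set[str]] = {}
    for inst in motif_instances(subnetwork, types=(subnetwork_id,)):
        by_pair.setdefault((inst.mirna, inst.tf), set()).add(inst.gene)
    return [
        PairTargetSet(m, t, subnetwork_id, frozenset(genes))
        for (m, t), genes in sorted(by_pair.items())
        if len(genes) >= min_genes
    ]


def enrich_pair_sets(
    sets: Sequence[PairTargetSet],
    annotation: TermAnnotation,
    M: int,
    alpha: float = 0.005,
    use_adjusted: bool = True,
) -> list[tuple[PairTargetSet, list[str]]]:
    """Terms over-represented in each pair target set.

    Every term is tested hypergeometrically against each set; within a set,
    p-values are BH-adjusted across terms and terms passing ``alpha`` (on
    adjusted values by default) are retained.
    """
    if not annotation.terms:
        raise ValueError("term annotation is empty")
    term_ids = sorted(annotation.terms)
    out = []
    for pair_set in sets:
        pvals = []
        for term in term_ids:
            term_genes = annotation.genes(term)
            x = len(pair_set.genes & term_genes)
            pvals.append(
                hypergeom_tail(
                    EnrichmentInput(
                        M=M, k=len(term_genes), N=len(pair_set.genes), x=x
                    )
                )
            )
        compare = bh_adjust(pvals) if use_adjusted else pvals
        enriched = [t for t, q in zip(term_ids, compare) if q < alpha]
        out.append((pair_set, enriched))
    return out


def rank_frequencies(
    enrichments: Sequence[tuple[PairTargetSet, list[str]]],
) -> pd.DataFrame:
    """Frequency and dense rank of every enriched term in one subnetwork.

    ``frequency`` counts the pair sets in which the term was enriched; terms
    are ranked by descending frequency with dense 1-based ranks (ties share
    the smaller rank; tie groups are logged).
    """
    freq: dict[str, int] = {}
    for _, terms in enrichments:
        for term in terms:
            freq[term] = freq.get(term, 0) + 1
    if not freq:
        return pd.DataFrame(columns=["term", "frequency", "rank"])
    table = pd.DataFrame(
        sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["term", "frequency"],
    )
    table["rank"] = (
        table["frequency"].rank(method="dense", ascending=False).astype(int)
    )
    n_tied = len(table) - table["frequency"].nunique()
    if n_tied:
        logger.info("%d terms share tied frequencies", n_tied)
    return table


def commonality_scores(
    rank_tables: Mapping[str, pd.DataFrame],
    stagenumbers: Mapping[str, int] | None = None,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Network-wide commonality score per term, with the common-term flag.

    ``rank_tables`` maps subnetwork id -> output of :func:`rank_frequencies`.
    A term's score sums frequency / (rank * stagenumber) over the
    subnetworks where it is enriched; the top ``top_fraction`` of terms by
    score are flagged common.
    """
    if stagenumbers is None:
        stagenumbers = DEFAULT_STAGE_NUMBERS
    missing = [s for s in rank_tables if s not in stagenumbers]
    if missing:
        raise ValueError(f"missing stagenumber for subnetworks: {missing}")
    scores: dict[str, float] = {}
    per_sub: dict[str, dict[str, tuple[int, int]]] = {}
    for sub_id, table in rank_tables.items():
        stage = stagenumbers[sub_id]
        for _, row in table.iterrows():
            term = row["term"]
            contribution = row["frequency"] / (row["rank"] * stage)
            scores[term] = scores.get(term, 0.0) + contribution
            per_sub.setdefault(term, {})[sub_id] = (int(row["frequency"]), int(row["rank"]))
    if not scores:
        return pd.DataFrame(columns=["term", "score", "common", "subnetworks"])
    result = pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["term", "score"],
    )
    n_common = math.ceil(top_fraction * len(result))
    result["common"] = [i < n_common for i in range(len(result))]
    result["subnetworks"] = [
        ";".join(
            f"{s}:F={per_sub[term][s][0]},r={per_sub[term][s][1]}"
            for s in MOTIF_TYPES
            if s in per_sub[term]
        )
        for term in result["term"]
    ]
    return result


def specific_terms(
    rank_tables: Mapping[str, pd.DataFrame],
    common_terms: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Per-subnetwork ranked term lists after removing the common terms."""
    common = set(common_terms)
    out = {}
    for sub_id, table in rank_tables.items():
        remaining = table[~table["term"].isin(common)].copy()
        if remaining.empty:
            out[sub_id] = pd.DataFrame(columns=["term", "frequency", "rank"])
            continue
        remaining = remaining.sort_values(
            ["frequency", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        remaining["rank"] = (
            remaining["frequency"].rank(method="dense", ascending=False).astype(int)
        )
        out[sub_id] = remaining
    return out


def analyze_subnetworks(
    network: RegulatoryNetwork,
    annotation: TermAnnotation,
    M: int,
    alpha: float = 0.005,
    top_fraction: float = 0.05,
    min_genes: int = 3,
    stagenumbers: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full term analysis: pair sets -> enrichment -> common/specific terms."""
    from .motifs import subnetwork as build_subnetwork

    rank_tables = {}
    for motif_id in MOTIF_TYPES:
        sub = build_subnetwork(network, motif_id)
        sets = pair_shared_targets(sub, motif_id, min_genes=min_genes)
        enrichments = enrich_pair_sets(sets, annotation, M=M, alpha=alpha)
        rank_tables[motif_id] = rank_frequencies(enrichments)
    common_table = commonality_scores(rank_tables, stagenumbers, top_fraction)
    common = list(common_table.loc[common_table["common"], "term"])
    return common_table, specific_terms(rank_tables, common)
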