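"""Synthetic regulatory systems with known planted structure.

Every downstream stage of the pipeline (disease-gene selection, regulator
enrichment, motif census and significance, family clustering, term
commonality scoring, mutation enrichment) gets a parameter-recovery test by
generating its inputs here with the ground truth recorded alongside:

* four relation tables with configurable size and degree model;
* a disease-gene subset and regulators whose target sets are enriched for
  it at a configurable odds ratio;
* motif triples of any of the ten templates planted with induced-template
  fidelity (required edges inserted, forbidden edges removed);
* miRNA families sharing a prototype TF-target profile up to a per-cell
  flip probability;
* two-group log2 expression matrices with planted fold changes and
  missing-at-random cells;
* binary mutation profiles with elevated rates in chosen genes;
* GMT term annotation with terms planted on the shared-target sets of
  planted motif pairs.

All randomness flows from a single seed; identical (config, seed) produces
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TermAnnotation
from .expression import ExpressionMatrix
from .motifs import MOTIF_TEMPLATES, MOTIF_TYPES
from .mutations import MutationProfile
from .relations import RELATION_CLASSES, RelationTables

logger = logging.getLogger(__name__)


class InfeasibleConfigError(ValueError):
    """The requested synthetic system cannot be constructed."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic regulatory system.

    Defaults mirror the scale of a curated human lung-cancer network:
    252 miRNAs, 174 TFs, 1002 genes, with 29877/1107/1588/207 edges in the
    mir2gene/mir2tf/tf2gene/tf2mir classes. Tests and examples pass smaller
    explicit configs.
    """

    n_mirna: int = 252
    n_tf: int = 174
    n_gene: int = 1002
    n_mir2gene: int = 29877
    n_mir2tf: int = 1107
    n_tf2gene: int = 1588
    n_tf2mir: int = 207
    degree_model: str = "uniform"  # "uniform" | "powerlaw"
    powerlaw_exponent: float = 2.0
    n_disease_genes: int = 0
    n_enriched_regulators: int = 0
    enrichment_odds: float = 1.0
    planted_motifs: Sequence[tuple[str, int]] = ()
    motif_genes_per_pair: int = 1
    n_families: int = 0
    family_size: int = 0
    family_profile_noise: float = 0.0
    family_profile_density: float = 0.3
    de_fraction: float = 0.0
    n_elevated_mutation_genes: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mirna": self.n_mirna,
            "n_tf": self.n_tf,
            "n_gene": self.n_gene,
            "n_mir2gene": self.n_mir2gene,
            "n_mir2tf": self.n_mir2tf,
            "n_tf2gene": self.n_tf2gene,
            "n_tf2mir": self.n_tf2mir,
            "n_disease_genes": self.n_disease_genes,
            "n_enriched_regulators": self.n_enriched_regulators,
            "n_families": self.n_families,
            "family_size": self.family_size,
            "n_elevated_mutation_genes": self.n_elevated_mutation_genes,
        }
        for name, value in counts.items():
            if value < 0:
                raise InfeasibleConfigError(f"{name} must be non-negative")
        capacities = {
            "n_mir2gene": self.n_mirna * self.n_gene,
            "n_mir2tf": self.n_mirna * self.n_tf,
            "n_tf2gene": self.n_tf * self.n_gene,
            "n_tf2mir": self.n_tf * self.n_mirna,
        }
        for name, cap in capacities.items():
            if getattr(self, name) > cap:
                raise InfeasibleConfigError(
                    f"{name}={getattr(self, name)} exceeds capacity {cap}"
                )
        if self.degree_model not in ("uniform", "powerlaw"):
            raise InfeasibleConfigError(f"unknown degree_model {self.degree_model!r}")
        if self.degree_model == "powerlaw" and self.powerlaw_exponent <= 1:
            raise InfeasibleConfigError("powerlaw_exponent must be > 1")
        if self.enrichment_odds < 1:
            raise InfeasibleConfigError("enrichment_odds must be >= 1")
        for prob_name in ("family_profile_noise", "family_profile_density", "de_fraction"):
            value = getattr(self, prob_name)
            if not 0 <= value <= 1:
                raise InfeasibleConfigError(f"{prob_name} must lie in [0, 1]")
        if self.n_disease_genes > self.n_gene:
            raise InfeasibleConfigError("n_disease_genes exceeds n_gene")
        if self.n_enriched_regulators > self.n_mirna + self.n_tf:
            raise InfeasibleConfigError("n_enriched_regulators exceeds regulator count")
        if self.n_families * self.family_size > self.n_mirna:
            raise InfeasibleConfigError("families require more miRNAs than configured")
        if self.motif_genes_per_pair < 1:
            raise InfeasibleConfigError("motif_genes_per_pair must be >= 1")
        for motif_type, count in self.planted_motifs:
            if motif_type not in MOTIF_TYPES:
                raise InfeasibleConfigError(f"unknown motif type {motif_type!r}")
            if count < 0:
                raise InfeasibleConfigError("planted motif counts must be non-negative")
        n_planted_genes = sum(count for _, count in self.planted_motifs)
        if n_planted_genes > self.n_gene:
            raise InfeasibleConfigError("planted motifs need more genes than configured")


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    mirnas: list[str] = field(default_factory=list)
    tfs: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)
    enriched_regulators: list[str] = field(default_factory=list)
    planted_triples: list[tuple[str, str, str, str]] = field(default_factory=list)
    family_membership: dict[str, list[str]] = field(default_factory=dict)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    elevated_mutation_genes: list[str] = field(default_factory=list)
    planted_terms: dict[str, dict] = field(default_factory=dict)
    removed_edges: list[tuple[str, str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        truth = cls(**raw)
        truth.planted_triples = [tuple(t) for t in truth.planted_triples]
        truth.removed_edges = [tuple(e) for e in truth.removed_edges]
        return truth


# -- relation tables --------------------------------------------------------

_SLOT_TO_RELATION = {
    "m2t": ("mir2tf", ("m", "t")),
    "t2m": ("tf2mir", ("t", "m")),
    "m2g": ("mir2gene", ("m", "g")),
    "t2g": ("tf2gene", ("t", "g")),
}


def _source_weights(n: int, degree_model: str, exponent: float) -> np.ndarray | None:
    if degree_model == "uniform":
        return None
    # rank-based weights give an out-degree distribution with tail exponent
    # close to the configured value
    weights = np.arange(1, n + 1, dtype=float) ** (-1.0 / (exponent - 1.0))
    return weights / weights.sum()


def _sample_degrees(
    rng: np.random.Generator,
    n_sources: int,
    n_targets: int,
    n_edges: int,
    weights: np.ndarray | None,
) -> np.ndarray:
    draws = rng.choice(n_sources, size=n_edges, p=weights)
    counts = np.bincount(draws, minlength=n_sources)
    counts = np.minimum(counts, n_targets)
    # redistribute overflow to sources with spare capacity
    while counts.sum() < n_edges:
        spare = np.flatnonzero(counts < n_targets)
        extra = rng.choice(spare)
        counts[extra] += 1
    return counts


def _sample_class(
    rng: np.random.Generator,
    sources: list[str],
    targets: list[str],
    n_edges: int,
    degree_model: str,
    exponent: float,
    enriched_sources: frozenset[str] = frozenset(),
    favored_targets: frozenset[str] = frozenset(),
    odds: float = 1.0,
) -> set[tuple[str, str]]:
    if n_edges == 0 or not sources or not targets:
        if n_edges > 0:
            raise InfeasibleConfigError("edges requested for an empty node class")
        return set()
    weights = _source_weights(len(sources), degree_model, exponent)
    degrees = _sample_degrees(rng, len(sources), len(targets), n_edges, weights)
    favored_mask = np.array([t in favored_targets for t in targets], dtype=float)
    edges: set[tuple[str, str]] = set()
    for i, source in enumerate(sources):
        d = int(degrees[i])
        if d == 0:
            continue
        if source in enriched_sources and odds > 1 and favored_mask.any():
            target_weights = np.where(favored_mask > 0, odds, 1.0)
            target_weights = target_weights / target_weights.sum()
            picked = rng.choice(len(targets), size=d, replace=False, p=target_weights)
        else:
            picked = rng.choice(len(targets), size=d, replace=False)
        edges.update((source, targets[j]) for j in picked)
    return edges


def generate_relations(config: SynthConfig) -> tuple[RelationTables, GroundTruth]:
    """Sample the four relation tables and record the planted ground truth.

    Background edges are drawn per class without replacement; enriched
    regulators draw their gene targets with the configured odds in favor of
    disease genes; families copy a prototype TF-target row with per-cell
    noise; planted motif triples are inserted last, removing any background
    edge that an induced template forbids (removals are logged and recorded
    in the ground truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirnas = [f"miR-{i:04d}" for i in range(config.n_mirna)]
    tfs = [f"TF-{i:03d}" for i in range(config.n_tf)]
    genes = [f"G-{i:05d}" for i in range(config.n_gene)]

    truth = GroundTruth(mirnas=mirnas, tfs=tfs, genes=genes)
    if config.n_disease_genes:
        truth.disease_genes = sorted(
            rng.choice(genes, size=config.n_disease_genes, replace=False)
        )
    regulators = mirnas + tfs
    if config.n_enriched_regulators:
        truth.enriched_regulators = sorted(
            rng.choice(regulators, size=config.n_enriched_regulators, replace=False)
        )
    n_de = round(config.de_fraction * config.n_gene)
    if n_de:
        de_picks = rng.choice(genes, size=n_de, replace=False)
        truth.de_genes = {
            g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(sorted(de_picks))
        }
    if config.n_elevated_mutation_genes:
        truth.elevated_mutation_genes = sorted(
            rng.choice(genes, size=config.n_elevated_mutation_genes, replace=False)
        )

    enriched = frozenset(truth.enriched_regulators)
    disease = frozenset(truth.disease_genes)
    edge_sets: dict[str, set[tuple[str, str]]] = {}
    class_args = {
        "mir2gene": (mirnas, genes, config.n_mir2gene, True),
        "mir2tf": (mirnas, tfs, config.n_mir2tf, False),
        "tf2gene": (tfs, genes, config.n_tf2gene, True),
        "tf2mir": (tfs, mirnas, config.n_tf2mir, False),
    }
    for rel in RELATION_CLASSES:
        sources, targets, n_edges, gene_targeted = class_args[rel]
        edge_sets[rel] = _sample_class(
            rng,
            sources,
            targets,
            n_edges,
            config.degree_model,
            config.powerlaw_exponent,
            enriched_sources=enriched if gene_targeted else frozenset(),
            favored_targets=disease if gene_targeted else frozenset(),
            odds=config.enrichment_odds,
        )

    # miRNA families: members copy one prototype TF-target row, cells flip
    # with family_profile_noise
    if config.n_families and config.family_size:
        members = rng.choice(
            mirnas, size=config.n_families * config.family_size, replace=False
        )
        for f in range(config.n_families):
            family_id = f"FAM-{f:02d}"
            fam_members = sorted(
                members[f * config.family_size : (f + 1) * config.family_size]
            )
            truth.family_membership[family_id] = fam_members
            prototype = rng.random(config.n_tf) < config.family_profile_density
            for member in fam_members:
                flips = rng.random(config.n_tf) < config.family_profile_noise
                row = prototype ^ flips
                edge_sets["mir2tf"].difference_update(
                    {(member, t) for t in tfs}
                )
                edge_sets["mir2tf"].update(
                    (member, tfs[j]) for j in np.flatnonzero(row)
                )

    # planted motif triples, inserted after background sampling
    required: dict[tuple[str, str, str], str] = {}  # (rel, src, tgt) -> motif type
    forbidden: dict[tuple[str, str, str], str] = {}
    if config.planted_motifs:
        total_genes_needed = sum(count for _, count in config.planted_motifs)
        planted_gene_pool = list(
            rng.choice(genes, size=total_genes_needed, replace=False)
        )
        used_pairs: set[tuple[str, str]] = set()
        for motif_type, count in config.planted_motifs:
            template = MOTIF_TEMPLATES[motif_type]
            n_pairs = math.ceil(count / config.motif_genes_per_pair)
            remaining = count
            for _ in range(n_pairs):
                for _attempt in range(10000):
                    m = mirnas[int(rng.integers(config.n_mirna))]
                    t = tfs[int(rng.integers(config.n_tf))]
                    if (m, t) not in used_pairs:
                        break
                else:
                    raise InfeasibleConfigError("could not find a free miRNA-TF pair")
                used_pairs.add((m, t))
                n_genes_here = min(config.motif_genes_per_pair, remaining)
                remaining -= n_genes_here
                for _ in range(n_genes_here):
                    g = planted_gene_pool.pop()
                    nodes = {"m": m, "t": t, "g": g}
                    for slot, (rel, (src_role, tgt_role)) in _SLOT_TO_RELATION.items():
                        edge = (rel, nodes[src_role], nodes[tgt_role])
                        if slot in template:
                            if edge in forbidden:
                                raise InfeasibleConfigError(
                                    f"required edge {edge} forbidden by a "
                                    f"type-{forbidden[edge]} plant"
                                )
                            required[edge] = motif_type
                        else:
                            if edge in required:
                                raise InfeasibleConfigError(
                                    f"forbidden edge {edge} required by a "
                                    f"type-{required[edge]} plant"
                                )
                            forbidden[edge] = motif_type
                    truth.planted_triples.append((m, t, g, motif_type))
        for rel, src, tgt in required:
            edge_sets[rel].add((src, tgt))
        for rel, src, tgt in forbidden:
            if (src, tgt) in edge_sets[rel]:
                edge_sets[rel].discard((src, tgt))
                truth.removed_edges.append((src, tgt, rel))
                logger.info(
                    "removed background edge %s->%s (%s) conflicting with an "
                    "induced template", src, tgt, rel,
                )

    tables = RelationTables.from_pairs(
        {rel: sorted(edge_sets[rel]) for rel in RELATION_CLASSES}
    ).sorted()
    return tables, truth


# -- expression -------------------------------------------------------------


def generate_expression(
    truth: GroundTruth,
    n_case: int = 20,
    n_control: int = 20,
    log_fc: float = 1.0,
    noise_sd: float = 0.5,
    missing_rate: float = 0.0,
    n_profiles: int = 2,
    seed: int = 0,
) -> list[ExpressionMatrix]:
    """Two-group log2 expression matrices with planted fold changes.

    Each gene gets a profile-specific baseline; case samples of the planted
    DE genes are shifted by +/- ``log_fc`` (sign from the ground truth);
    Gaussian noise with ``noise_sd`` is added throughout and cells go
    missing completely at random at ``missing_rate``.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_samples = n_case + n_control
    groups = ["case"] * n_case + ["control"] * n_control
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        direction = truth.de_genes.get(g)
        if direction == "up":
            shift[i] = log_fc
        elif direction == "down":
            shift[i] = -log_fc
    matrices = []
    for p in range(n_profiles):
        baseline = rng.normal(8.0, 2.0, size=len(genes))
        values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
        values[:, :n_case] += shift[:, None]
        if missing_rate > 0:
            mask = rng.random(values.shape) < missing_rate
            values = np.where(mask, np.nan, values)
        frame = pd.DataFrame(
            values, index=genes, columns=[f"P{p}_S{j:03d}" for j in range(n_samples)]
        )
        frame.index.name = "gene_id"
        matrices.append(ExpressionMatrix(frame, groups))
    return matrices


# -- mutations ---------------------------------------------------------------


def generate_mutations(
    truth: GroundTruth,
    n_samples: int = 100,
    base_rate: float = 0.01,
    elevated_rate: float = 0.2,
    seed: int = 0,
) -> MutationProfile:
    """Binary mutation calls; planted genes mutate at ``elevated_rate``."""
    if not (0 <= base_rate < elevated_rate <= 1):
        raise ValueError("need 0 <= base_rate < elevated_rate <= 1")
    rng = np.random.default_rng(seed)
    elevated = set(truth.elevated_mutation_genes)
    rates = np.array([elevated_rate if g in elevated else base_rate for g in truth.genes])
    calls = (rng.random((len(truth.genes), n_samples)) < rates[:, None]).astype(int)
    frame = pd.DataFrame(
        calls, index=truth.genes, columns=[f"S{j:04d}" for j in range(n_samples)]
    )
    frame.index.name = "gene_id"
    return MutationProfile(frame)


# -- annotation --------------------------------------------------------------


def _pair_sets_by_type(truth: GroundTruth) -> dict[str, dict[tuple[str, str], set[str]]]:
    out: dict[str, dict[tuple[str, str], set[str]]] = {}
    for m, t, g, motif_type in truth.planted_triples:
        out.setdefault(motif_type, {}).setdefault((m, t), set()).add(g)
    return out


def generate_annotation(
    truth: GroundTruth,
    n_terms: int = 100,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    n_common_terms: int = 0,
    n_specific_terms: int = 0,
) -> TermAnnotation:
    """Background terms plus terms planted on planted-motif pair target sets.

    Background terms draw member genes uniformly. Each planted *common*
    term covers the planted pair-set genes of every motif type, so it is
    recoverable as a network-wide common function; each planted *specific*
    term covers one motif type's planted genes only. Planted terms are
    recorded in ``truth.planted_terms``.
    """
    lo, hi = size_range
    if lo > hi:
        raise ValueError("size_range minimum exceeds maximum")
    if hi > len(truth.genes):
        raise ValueError("size_range maximum exceeds the gene universe")
    rng = np.random.default_rng(seed)
    ann = TermAnnotation()
    by_type = _pair_sets_by_type(truth)
    if (n_common_terms or n_specific_terms) and not by_type:
        raise ValueError("planted terms need planted motif triples in the truth")
    all_planted_genes = sorted(
        {g for pairs in by_type.values() for gs in pairs.values() for g in gs}
    )
    for c in range(n_common_terms):
        term = f"COMMON-{c:02d}"
        ann.add(term, all_planted_genes, "planted common term")
        truth.planted_terms[term] = {
            "subnetworks": sorted(by_type),
            "genes": all_planted_genes,
        }
    types_cycle = sorted(by_type)
    for s in range(n_specific_terms):
        motif_type = types_cycle[s % len(types_cycle)]
        type_genes = sorted({g for gs in by_type[motif_type].values() for g in gs})
        term = f"SPECIFIC-{motif_type}-{s:02d}"
        ann.add(term, type_genes, f"planted specific term of subnetwork {motif_type}")
        truth.planted_terms[term] = {"subnetworks": [motif_type], "genes": type_genes}
    for b in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(truth.genes, size=size, replace=False)
        ann.add(f"TERM-{b:04d}", sorted(members), "background term")
    return ann
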