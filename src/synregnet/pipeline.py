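"""End-to-end pipeline: inputs -> network -> motifs -> functions.

Mirrors the study workflow: select disease genes from expression plus a
curated list, keep regulators whose targets are enriched for them, build
the typed network, census and test the ten motif types, derive subnetwork /
hub / interplay statistics, and score functional terms. Every stage writes
plain TSV/JSON artifacts plus a manifest recording the configuration and
seed; a rerun with the same configuration and seed is bit-identical.

All randomness flows from one root seed through named substreams, so e.g.
changing the bootstrap replicate count does not perturb the motif null.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich, expression, functions, motifs, network, syndata
from .annotation import TermAnnotation
from .mutations import MutationProfile
from .relations import RelationTables, read_gene_list, write_gene_list

logger = logging.getLogger(__name__)

#: fixed order of the named seed substreams
_STREAMS = ("syndata", "expression", "bootstrap", "validation", "motif_null", "mutations", "annotation")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Exactly one of ``synth`` (synthetic mode) or ``relations_path`` must be
    set. Threshold defaults follow the study: fold change > 1.5 at FDR <
    0.01 for differential expression, enrichment alpha 0.01, term alpha
    0.005, top 5% hubs, 5% mutation-rate cutoff, and in-degree cutoffs 5
    (miRNAs) / 50 (TFs).
    """

    synth: syndata.SynthConfig | None = None
    relations_path: str | None = None
    curated_genes_path: str | None = None
    expression_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    mutations_path: str | None = None

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.01
    de_mode: str = "intersect"
    enrich_alpha: float = 0.01
    term_alpha: float = 0.005
    hub_fraction: float = 0.05
    mutation_rate_threshold: float = 0.05
    mirna_indeg_cut: int = 5
    tf_indeg_cut: int = 50
    top_term_fraction: float = 0.05

    n_boot: int = 100
    validation_reps: int = 1000
    motif_null_reps: int = 10000
    swaps_per_edge: int = 100
    filter_to_significant: bool = True

    # synthetic-mode generation knobs (ignored with real inputs)
    synth_expression: bool = False
    synth_annotation: bool = False
    synth_mutations: bool = False
    n_case: int = 20
    n_control: int = 20
    log_fc: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    n_annotation_terms: int = 100
    annotation_size_range: tuple[int, int] = (10, 50)
    n_common_terms: int = 0
    n_specific_terms: int = 0
    n_mutation_samples: int = 100
    mutation_base_rate: float = 0.01
    mutation_elevated_rate: float = 0.2

    seed: int = 0

    def validate(self) -> None:
        if (self.synth is None) == (self.relations_path is None):
            raise ValueError("set exactly one of synth / relations_path")
        if self.synth is None and (
            self.synth_expression or self.synth_annotation or self.synth_mutations
        ):
            raise ValueError("synthetic stages require synthetic mode")
        for name in ("fc_threshold",):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        for name in (
            "fdr_threshold", "enrich_alpha", "term_alpha", "hub_fraction",
            "mutation_rate_threshold", "top_term_fraction",
        ):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def _stream_seed(streams: dict, name: str) -> int:
    return int(streams[name].generate_state(1)[0] % (2**31))


def target_gene_map(tables: RelationTables, regulator_class: str) -> dict[str, set[str]]:
    """Gene targets per regulator (mir2gene for miRNAs, tf2gene for TFs)."""
    rel = "mir2gene" if regulator_class == "mirna" else "tf2gene"
    out: dict[str, set[str]] = {}
    for source, target in tables.edge_pairs(rel):
        out.setdefault(source, set()).add(target)
    return out


def filter_tables(
    tables: RelationTables,
    keep_mirnas: set[str],
    keep_tfs: set[str],
    keep_genes: set[str],
) -> RelationTables:
    """Restrict the relation tables to selected regulators and genes."""
    frame = tables.edges
    src_ok = pd.Series(False, index=frame.index)
    tgt_ok = pd.Series(False, index=frame.index)
    keep = {"mirna": keep_mirnas, "tf": keep_tfs, "gene": keep_genes}
    from .relations import RELATION_ENDPOINTS

    for rel, (src_kind, tgt_kind) in RELATION_ENDPOINTS.items():
        mask = frame["relation_class"] == rel
        src_ok |= mask & frame["source_id"].isin(keep[src_kind])
        tgt_ok |= mask & frame["target_id"].isin(keep[tgt_kind])
    return RelationTables(frame[src_ok & tgt_ok].reset_index(drop=True))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every enabled stage and write artifacts plus a manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = _substreams(config.seed)
    artifacts: dict[str, str] = {}

    def save_frame(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, **kwargs)
        artifacts[name.split(".")[0]] = name

    # ---- inputs ----
    truth = None
    expr_matrices: list[expression.ExpressionMatrix] = []
    annotation: TermAnnotation | None = None
    mutation_profile: MutationProfile | None = None
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=_stream_seed(streams, "syndata"))
        tables, truth = syndata.generate_relations(synth_cfg)
        curated = set(truth.disease_genes) or set(truth.genes)
        tables.to_tsv(outdir / "relations.tsv")
        truth.to_json(outdir / "truth.json")
        artifacts["relations"] = "relations.tsv"
        artifacts["truth"] = "truth.json"
        if config.synth_expression:
            expr_matrices = syndata.generate_expression(
                truth,
                n_case=config.n_case,
                n_control=config.n_control,
                log_fc=config.log_fc,
                noise_sd=config.noise_sd,
                missing_rate=config.missing_rate,
                seed=_stream_seed(streams, "expression"),
            )
        if config.synth_annotation:
            annotation = syndata.generate_annotation(
                truth,
                n_terms=config.n_annotation_terms,
                size_range=config.annotation_size_range,
                seed=_stream_seed(streams, "annotation"),
                n_common_terms=config.n_common_terms,
                n_specific_terms=config.n_specific_terms,
            )
            annotation.to_gmt(outdir / "annotation.gmt")
            artifacts["annotation"] = "annotation.gmt"
        if config.synth_mutations:
            mutation_profile = syndata.generate_mutations(
                truth,
                n_samples=config.n_mutation_samples,
                base_rate=config.mutation_base_rate,
                elevated_rate=config.mutation_elevated_rate,
                seed=_stream_seed(streams, "mutations"),
            )
    else:
        tables = RelationTables.from_tsv(config.relations_path)
        if config.curated_genes_path is None:
            raise ValueError("real-input mode requires curated_genes_path")
        curated = set(read_gene_list(config.curated_genes_path))
        for path in config.expression_paths:
            expr_matrices.append(expression.ExpressionMatrix.from_tsv(path))
        if config.annotation_path:
            annotation = TermAnnotation.from_gmt(config.annotation_path)
        if config.mutations_path:
            mutation_profile = MutationProfile.from_tsv(config.mutations_path)

    universe = sorted({t for _, t in tables.edge_pairs("mir2gene")}
                      | {t for _, t in tables.edge_pairs("tf2gene")}
                      | curated)
    if truth is not None:
        universe = truth.genes

    # ---- stage 1: disease genes ----
    if expr_matrices:
        de_sets = []
        for matrix in expr_matrices:
            table = expression.differential_genes(
                expression.preprocess(matrix),
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            de_sets.append(expression.selected_genes(table))
        disease_genes = expression.select_disease_genes(curated, de_sets, config.de_mode)
        ratios = expression.bootstrap_overlap(
            expression.preprocess(expr_matrices[0]),
            curated,
            n_boot=config.n_boot,
            seed=_stream_seed(streams, "bootstrap"),
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        save_frame(pd.DataFrame({"replicate": range(len(ratios)), "overlap_ratio": ratios}),
                   "bootstrap_overlap.tsv")
    else:
        disease_genes = frozenset(curated)
    write_gene_list(disease_genes, outdir / "disease_genes.txt")
    artifacts["disease_genes"] = "disease_genes.txt"

    # ---- stage 2: regulator enrichment ----
    results = {}
    for regulator_class in ("mirna", "tf"):
        target_map = target_gene_map(tables, regulator_class)
        results[regulator_class] = enrich.significant_regulators(
            target_map, disease_genes, M=len(universe), alpha=config.enrich_alpha
        )
        save_frame(results[regulator_class], f"enrichment_{regulator_class}.tsv")
    sig_mirnas = set(results["mirna"].loc[results["mirna"]["significant"], "regulator"])
    sig_tfs = set(results["tf"].loc[results["tf"]["significant"], "regulator"])

    # ---- stage 3: network ----
    if config.filter_to_significant:
        tables_used = filter_tables(tables, sig_mirnas, sig_tfs, set(disease_genes))
    else:
        tables_used = tables
    net = network.build_network(tables_used)
    summary = network.summarize(net)
    save_frame(summary.to_frame(), "network_summary.tsv")
    interplay = network.interplay_stats(net, config.mirna_indeg_cut, config.tf_indeg_cut)
    (outdir / "interplay.json").write_text(
        json.dumps(dataclasses.asdict(interplay), indent=1, sort_keys=True) + "\n"
    )
    artifacts["interplay"] = "interplay.json"
    hub_rows = []
    for node_class, direction in (("mirna", "out"), ("tf", "out"), ("gene", "in"),
                                  ("mirna", "in"), ("tf", "in")):
        for node in network.hubs(net, node_class, direction, config.hub_fraction):
            hub_rows.append(
                {"node_class": node_class, "direction": direction,
                 "node": node, "degree": net.degree(node, direction)}
            )
    save_frame(pd.DataFrame(hub_rows), "hubs.tsv")

    # ---- stage 4: motif census and significance ----
    census_table = motifs.census(net)
    save_frame(census_table, "motif_census.tsv")
    if net.n_edges >= 2 and config.motif_null_reps >= 1:
        stats = motifs.significance(
            net,
            n_random=config.motif_null_reps,
            seed=_stream_seed(streams, "motif_null"),
            swaps_per_edge=config.swaps_per_edge,
        )
        save_frame(motifs.stats_frame(stats), "motif_significance.tsv",
                   float_format="%.6g")
    participation = motifs.participation(net)
    save_frame(participation, "motif_participation.tsv")
    for motif_id in motifs.MOTIF_TYPES:
        sub = motifs.subnetwork(net, motif_id)
        sub.to_tables().to_tsv(outdir / f"subnetwork_{motif_id}.tsv")
        artifacts[f"subnetwork_{motif_id}"] = f"subnetwork_{motif_id}.tsv"

    # ---- stage 5: term analysis ----
    if annotation is not None:
        common_table, specific = functions.analyze_subnetworks(
            net, annotation, M=len(universe),
            alpha=config.term_alpha, top_fraction=config.top_term_fraction,
        )
        save_frame(common_table, "term_commonality.tsv", float_format="%.6g")
        for sub_id, table in specific.items():
            save_frame(table, f"specific_terms_{sub_id}.tsv")

    # ---- stage 6: mutation enrichment ----
    if mutation_profile is not None:
        rows = []
        for motif_id in motifs.MOTIF_TYPES:
            sub = motifs.subnetwork(net, motif_id)
            rows.append(
                enrich.mutation_enrichment(
                    sub.nodes_of("gene"), mutation_profile,
                    rate_threshold=config.mutation_rate_threshold,
                    subject=f"subnetwork_{motif_id}",
                )
            )
        save_frame(pd.concat(rows, ignore_index=True), "mutation_enrichment.tsv")

    manifest = {
        "package": "synregnet",
        "version": _pkg_version("synregnet"),
        "seed": config.seed,
        "config": _config_dict(config),
        "artifacts": dict(sorted(artifacts.items())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["annotation_size_range"] = list(raw["annotation_size_range"])
    if raw["synth"] is not None:
        raw["synth"]["planted_motifs"] = [list(p) for p in raw["synth"]["planted_motifs"]]
    return raw
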