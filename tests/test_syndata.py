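"""Synthetic-data generator: determinism, feasibility, planted structure."""

import numpy as np
import pytest
from scipy.stats import binom, binomtest

from synregnet.motifs import MOTIF_TEMPLATES
from synregnet.syndata import (
    GroundTruth,
    InfeasibleConfigError,
    SynthConfig,
    generate_annotation,
    generate_expression,
    generate_mutations,
    generate_relations,
)


class TestGenerateRelations:
    def test_empty_config_gives_empty_tables(self):
        config = SynthConfig(n_mirna=5, n_tf=5, n_gene=5, n_mir2gene=0,
                             n_mir2tf=0, n_tf2gene=0, n_tf2mir=0)
        tables, truth = generate_relations(config)
        assert len(tables) == 0
        assert not truth.planted_triples

    def test_same_seed_byte_identical(self, tmp_path, small_synthetic):
        config, tables, _ = small_synthetic
        tables2, _ = generate_relations(config)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        tables.to_tsv(p1)
        tables2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_class_counts_match_config(self, small_synthetic):
        config, tables, _ = small_synthetic
        assert tables.class_counts() == {
            "mir2gene": config.n_mir2gene, "mir2tf": config.n_mir2tf,
            "tf2gene": config.n_tf2gene, "tf2mir": config.n_tf2mir,
        }
        assert not tables.edges.duplicated().any()

    def test_full_regulation_plants_have_all_edges(self):
        config = SynthConfig(n_mirna=10, n_tf=5, n_gene=50, n_mir2gene=30,
                             n_mir2tf=5, n_tf2gene=15, n_tf2mir=5,
                             planted_motifs=[("I", 5)], seed=3)
        tables, truth = generate_relations(config)
        edges = {
            rel: set(tables.edge_pairs(rel))
            for rel in ("mir2gene", "mir2tf", "tf2gene", "tf2mir")
        }
        assert len(truth.planted_triples) == 5
        for m, t, g, motif_type in truth.planted_triples:
            assert motif_type == "I"
            assert (m, t) in edges["mir2tf"]
            assert (t, m) in edges["tf2mir"]
            assert (m, g) in edges["mir2gene"]
            assert (t, g) in edges["tf2gene"]

    def test_forbidden_template_edges_absent(self):
        config = SynthConfig(n_mirna=10, n_tf=5, n_gene=40, n_mir2gene=100,
                             n_mir2tf=20, n_tf2gene=80, n_tf2mir=15,
                             planted_motifs=[("VII", 8), ("VI", 4)], seed=9)
        tables, truth = generate_relations(config)
        edges = {
            rel: set(tables.edge_pairs(rel))
            for rel in ("mir2gene", "mir2tf", "tf2gene", "tf2mir")
        }
        slot_edges = {
            "m2t": ("mir2tf", lambda m, t, g: (m, t)),
            "t2m": ("tf2mir", lambda m, t, g: (t, m)),
            "m2g": ("mir2gene", lambda m, t, g: (m, g)),
            "t2g": ("tf2gene", lambda m, t, g: (t, g)),
        }
        for m, t, g, motif_type in truth.planted_triples:
            template = MOTIF_TEMPLATES[motif_type]
            for slot, (rel, make) in slot_edges.items():
                present = make(m, t, g) in edges[rel]
                assert present == (slot in template)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_mir2gene": 10_000},          # exceeds capacity 5*5
            {"enrichment_odds": 0.5},
            {"family_profile_noise": 1.5},
            {"n_families": 3, "family_size": 3},  # needs 9 of 5 miRNAs
            {"planted_motifs": [("XI", 1)]},
            {"n_disease_genes": 99},
        ],
    )
    def test_infeasible_configs_rejected(self, overrides):
        base = dict(n_mirna=5, n_tf=5, n_gene=5, n_mir2gene=5, n_mir2tf=5,
                    n_tf2gene=5, n_tf2mir=5)
        base.update(overrides)
        with pytest.raises(InfeasibleConfigError):
            generate_relations(SynthConfig(**base))

    def test_enrichment_plant_raises_disease_fraction(self):
        """Pooled over 200 runs, enriched regulators' targets hit disease
        genes above the background rate (one-sided binomial, alpha 0.01)."""
        hits = draws = 0
        base_fraction = 20 / 100
        for seed in range(200):
            config = SynthConfig(n_mirna=6, n_tf=3, n_gene=100, n_mir2gene=60,
                                 n_mir2tf=3, n_tf2gene=20, n_tf2mir=2,
                                 n_disease_genes=20, n_enriched_regulators=3,
                                 enrichment_odds=4.0, seed=seed)
            tables, truth = generate_relations(config)
            disease = set(truth.disease_genes)
            enriched = set(truth.enriched_regulators)
            for rel in ("mir2gene", "tf2gene"):
                for source, target in tables.edge_pairs(rel):
                    if source in enriched:
                        draws += 1
                        hits += target in disease
        test = binomtest(hits, draws, base_fraction, alternative="greater")
        assert test.pvalue < 0.01

    def test_family_members_share_profiles_at_zero_noise(self):
        config = SynthConfig(n_mirna=20, n_tf=10, n_gene=10, n_mir2gene=20,
                             n_mir2tf=30, n_tf2gene=10, n_tf2mir=5,
                             n_families=2, family_size=4,
                             family_profile_noise=0.0, seed=2)
        tables, truth = generate_relations(config)
        targets = {}
        for m, t in tables.edge_pairs("mir2tf"):
            targets.setdefault(m, set()).add(t)
        for members in truth.family_membership.values():
            profiles = {frozenset(targets.get(m, set())) for m in members}
            assert len(profiles) == 1


class TestGenerateExpression:
    @staticmethod
    def truth(n_gene=200, de_fraction=0.1, seed=1):
        config = SynthConfig(n_mirna=2, n_tf=2, n_gene=n_gene, n_mir2gene=2,
                             n_mir2tf=1, n_tf2gene=2, n_tf2mir=1,
                             de_fraction=de_fraction, seed=seed)
        return generate_relations(config)[1]

    def test_zero_log_fc_is_a_null_dataset(self):
        from synregnet.expression import differential_genes, selected_genes

        truth = self.truth(n_gene=500)
        matrix = generate_expression(truth, log_fc=0.0, n_profiles=1, seed=4)[0]
        hits = selected_genes(differential_genes(matrix))
        assert len(hits) <= 0.01 * 500 + 5

    def test_zero_missing_rate_is_complete(self):
        matrix = generate_expression(self.truth(), missing_rate=0.0, seed=0)[0]
        assert not matrix.values.isna().any().any()

    def test_missing_rate_one_rejected(self):
        with pytest.raises(ValueError):
            generate_expression(self.truth(), missing_rate=1.0)

    def test_shapes_and_labels(self):
        truth = self.truth()
        out = generate_expression(truth, n_case=4, n_control=3, n_profiles=2, seed=5)
        assert len(out) == 2
        for matrix in out:
            assert matrix.values.shape == (len(truth.genes), 7)
            assert matrix.n_case == 4 and matrix.n_control == 3

    def test_round_trip_tsv(self, tmp_path):
        from synregnet.expression import ExpressionMatrix

        matrix = generate_expression(self.truth(n_gene=20), missing_rate=0.1, seed=6)[0]
        path = tmp_path / "expr.tsv"
        matrix.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        assert back.groups == matrix.groups
        np.testing.assert_allclose(back.values, matrix.values, rtol=1e-6)


class TestGenerateMutations:
    @staticmethod
    def truth(n_elevated=5, seed=1):
        config = SynthConfig(n_mirna=2, n_tf=2, n_gene=50, n_mir2gene=2,
                             n_mir2tf=1, n_tf2gene=2, n_tf2mir=1,
                             n_elevated_mutation_genes=n_elevated, seed=seed)
        return generate_relations(config)[1]

    def test_zero_base_rate_only_elevated_mutate(self):
        truth = self.truth()
        profile = generate_mutations(truth, n_samples=50, base_rate=0.0,
                                     elevated_rate=0.3, seed=2)
        mutated = set(profile.calls.index[profile.calls.sum(axis=1) > 0])
        assert mutated <= set(truth.elevated_mutation_genes)

    def test_elevated_rate_one_saturates(self):
        truth = self.truth()
        profile = generate_mutations(truth, n_samples=10, base_rate=0.0,
                                     elevated_rate=1.0, seed=3)
        rates = profile.mutation_rates()
        assert all(rates[g] == 1.0 for g in truth.elevated_mutation_genes)

    def test_elevated_rates_within_binomial_bounds(self):
        truth = self.truth(n_elevated=10)
        profile = generate_mutations(truth, n_samples=500, base_rate=0.01,
                                     elevated_rate=0.2, seed=4)
        lo, hi = binom.ppf([0.005, 0.995], 500, 0.2) / 500
        rates = profile.mutation_rates()
        for g in truth.elevated_mutation_genes:
            assert lo <= rates[g] <= hi

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            generate_mutations(self.truth(), base_rate=0.5, elevated_rate=0.2)


class TestGenerateAnnotation:
    @staticmethod
    def truth_with_plants(seed=1):
        config = SynthConfig(n_mirna=10, n_tf=6, n_gene=200, n_mir2gene=40,
                             n_mir2tf=10, n_tf2gene=20, n_tf2mir=5,
                             planted_motifs=[("I", 6), ("VII", 6)],
                             motif_genes_per_pair=3, seed=seed)
        return generate_relations(config)[1]

    def test_empty_annotation(self):
        truth = GroundTruth(genes=["g1", "g2"])
        ann = generate_annotation(truth, n_terms=0, size_range=(1, 2))
        assert len(ann) == 0

    def test_same_seed_identical_gmt(self, tmp_path):
        truth = self.truth_with_plants()
        paths = []
        for name in ("a.gmt", "b.gmt"):
            ann = generate_annotation(truth, n_terms=20, size_range=(5, 15), seed=7,
                                      n_common_terms=1)
            path = tmp_path / name
            ann.to_gmt(path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_planted_terms_cover_planted_genes(self):
        truth = self.truth_with_plants()
        ann = generate_annotation(truth, n_terms=10, size_range=(5, 15), seed=2,
                                  n_common_terms=1, n_specific_terms=2)
        planted_genes = {g for _, _, g, _ in truth.planted_triples}
        assert ann.genes("COMMON-00") == frozenset(planted_genes)
        for term, meta in truth.planted_terms.items():
            assert set(meta["genes"]) <= planted_genes

    def test_bad_size_range_rejected(self):
        truth = GroundTruth(genes=["g1", "g2"])
        with pytest.raises(ValueError):
            generate_annotation(truth, n_terms=1, size_range=(3, 2))
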