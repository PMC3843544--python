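"""Motif classification, census, degree-preserving null, and significance."""

from collections import Counter

import numpy as np
import pytest

from conftest import brute_force_counts
from synregnet import SynthConfig, generate_relations
from synregnet.motifs import (
    MOTIF_TEMPLATES,
    MOTIF_TYPES,
    census,
    classify_triple,
    count_motifs,
    empirical_p,
    motif_instances,
    participation,
    rewire,
    significance,
    subnetwork,
    zscore,
)
from synregnet.network import build_network, summarize
from synregnet.relations import RelationTables


def network_from(pairs):
    return build_network(RelationTables.from_pairs(pairs))


class TestClassifyTriple:
    @pytest.mark.parametrize(
        "slots, expected",
        [
            ({"m2t", "t2m", "m2g", "t2g"}, "I"),
            ({"m2t", "m2g", "t2g"}, "II"),
            ({"t2m", "m2g", "t2g"}, "III"),
            ({"m2t", "t2m", "m2g"}, "IV"),
            ({"m2t", "t2m", "t2g"}, "V"),
            ({"m2g", "t2g"}, "VI"),
            ({"m2t", "m2g"}, "VII"),
            ({"t2m", "m2g"}, "VIII"),
            ({"m2t", "t2g"}, "IX"),
            ({"t2m", "t2g"}, "X"),
            ({"m2g"}, None),
            ({"t2g"}, None),
            ({"m2t", "t2m"}, None),
            (set(), None),
        ],
    )
    def test_template_lookup(self, slots, expected):
        slot_pairs = {
            "m2t": ("mir2tf", ("m1", "t1")),
            "t2m": ("tf2mir", ("t1", "m1")),
            "m2g": ("mir2gene", ("m1", "g1")),
            "t2g": ("tf2gene", ("t1", "g1")),
        }
        # anchor edges so m1, t1, g1 exist with the right classes regardless
        # of which slots the tested configuration fills
        pairs = {"mir2gene": [("m1", "g0"), ("m9", "g1")], "tf2gene": [("t1", "g0")]}
        for slot in slots:
            rel, edge = slot_pairs[slot]
            pairs.setdefault(rel, []).append(edge)
        net = network_from(pairs)
        assert classify_triple(net, "m1", "t1", "g1") == expected

    def test_wrong_node_classes_rejected(self, toy_network):
        with pytest.raises(ValueError):
            classify_triple(toy_network, "t1", "m1", "g1")


class TestCountMotifs:
    def test_two_triple_example(self, toy_network):
        # edges m1->t1, t1->m1, m1->g1, t1->g1, m1->g2
        counts = count_motifs(toy_network)
        assert counts == {**{m: 0 for m in MOTIF_TYPES}, "I": 1, "IV": 1}

    def test_disjoint_union_adds(self):
        a = {"mir2tf": [("m1", "t1")], "mir2gene": [("m1", "g1")],
             "tf2gene": [("t1", "g1")]}
        b = {"tf2mir": [("t2", "m2")], "mir2gene": [("m2", "g2")]}
        merged = {k: a.get(k, []) + b.get(k, []) for k in set(a) | set(b)}
        ca, cb = count_motifs(network_from(a)), count_motifs(network_from(b))
        cm = count_motifs(network_from(merged))
        assert all(cm[t] == ca[t] + cb[t] for t in MOTIF_TYPES)

    def test_matches_bruteforce_on_random_networks(self):
        for seed in range(10):
            config = SynthConfig(n_mirna=8, n_tf=6, n_gene=30,
                                 n_mir2gene=50, n_mir2tf=20, n_tf2gene=35,
                                 n_tf2mir=12, seed=seed)
            net = build_network(generate_relations(config)[0])
            assert count_motifs(net) == brute_force_counts(net)

    def test_instance_stream_consistent_with_counts(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        stream = Counter(inst.motif_type for inst in motif_instances(net))
        counts = count_motifs(net)
        assert all(stream.get(t, 0) == counts[t] for t in MOTIF_TYPES)


class TestRewire:
    def test_degrees_and_summary_preserved(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        null = rewire(net, seed=1, swaps_per_edge=5)
        for rel in ("mir2gene", "mir2tf", "tf2gene", "tf2mir"):
            out_deg = Counter(u for u, _ in net.edges_of(rel))
            in_deg = Counter(v for _, v in net.edges_of(rel))
            assert Counter(u for u, _ in null.edges_of(rel)) == out_deg
            assert Counter(v for _, v in null.edges_of(rel)) == in_deg
        assert summarize(null) == summarize(net)

    def test_tiny_class_returned_unchanged(self):
        net = network_from({"mir2gene": [("m1", "g1")]})
        null = rewire(net, seed=0)
        assert null.edges_of("mir2gene") == [("m1", "g1")]

    def test_toy_state_space_sampled(self):
        # out-degrees a=2, b=2; in-degrees x=2, y=1, z=1 admit exactly two
        # simple graphs; the swap chain should visit both roughly equally
        net = network_from(
            {"mir2gene": [("a", "x"), ("a", "y"), ("b", "x"), ("b", "z")]}
        )
        states = Counter()
        for seed in range(1000):
            null = rewire(net, seed=seed, swaps_per_edge=25)
            states[tuple(null.edges_of("mir2gene"))] += 1
        assert len(states) == 2
        for freq in states.values():
            assert 0.4 <= freq / 1000 <= 0.6


class TestSignificance:
    def test_degenerate_network_p_one_z_undefined(self):
        net = network_from({"mir2tf": [("m1", "t1")], "mir2gene": [("m1", "g1")]})
        stats = significance(net, n_random=20, seed=0)
        assert stats["VII"].p == 1.0
        assert stats["VII"].z is None

    def test_p_range_and_z_sign(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        stats = significance(net, n_random=50, seed=3, swaps_per_edge=3)
        for s in stats.values():
            assert 0 <= s.p <= 1
            if s.z is not None:
                assert np.sign(s.z) == np.sign(s.n_real - s.n_mean)

    def test_planted_motifs_detected(self):
        config = SynthConfig(n_mirna=15, n_tf=8, n_gene=40,
                             n_mir2gene=90, n_mir2tf=45, n_tf2gene=60,
                             n_tf2mir=30, planted_motifs=[("I", 30)], seed=21)
        net = build_network(generate_relations(config)[0])
        stats = significance(net, n_random=300, seed=4, swaps_per_edge=5)
        assert stats["I"].z > 3
        assert stats["I"].p <= 0.01


class TestZscoreEmpiricalP:
    @pytest.mark.parametrize(
        "n_real, mean, sd, expected",
        [(86, 27.0475, 11.8268, 4.9847), (148647, 114787.3, 1225.9080, 27.6201)],
    )
    def test_printed_motif_table_rows(self, n_real, mean, sd, expected):
        assert zscore(n_real, mean, sd) == pytest.approx(expected, abs=1e-3)

    def test_zero_at_the_mean(self):
        assert zscore(5.0, 5.0, 2.0) == 0.0

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore(1, 0, 0)

    @pytest.mark.parametrize(
        "n_high, n_random, expected",
        [(0, 10000, 0.0), (10000, 10000, 1.0), (97, 10000, 0.0097)],
    )
    def test_empirical_p_values(self, n_high, n_random, expected):
        assert empirical_p(n_high, n_random) == pytest.approx(expected)

    def test_empirical_p_invalid(self):
        with pytest.raises(ValueError):
            empirical_p(1, 0)
        with pytest.raises(ValueError):
            empirical_p(5, 3)


class TestSubnetworkAndParticipation:
    def test_single_coregulation_instance_shape(self):
        net = network_from({"mir2gene": [("m1", "g1")], "tf2gene": [("t1", "g1")]})
        sub = subnetwork(net, "VI")
        assert sub.graph.number_of_nodes() == 3
        assert sub.n_edges == 2

    def test_subnetwork_contained_in_parent(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        for motif_id in ("VI", "VII", "IX"):
            sub = subnetwork(net, motif_id)
            assert set(sub.graph.nodes) <= set(net.graph.nodes)
            assert set(sub.graph.edges) <= set(net.graph.edges)

    def test_census_distinct_counts_match_subnetworks(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        table = census(net).set_index("motif_type")
        for motif_id in MOTIF_TYPES:
            sub = subnetwork(net, motif_id)
            assert table.loc[motif_id, "n_mirnas"] == len(sub.nodes_of("mirna"))
            assert table.loc[motif_id, "n_tfs"] == len(sub.nodes_of("tf"))
            assert table.loc[motif_id, "n_genes"] == len(sub.nodes_of("gene"))

    def test_per_class_counts_conserved(self, small_synthetic):
        _, tables, _ = small_synthetic
        net = build_network(tables)
        table = participation(net)
        counts = count_motifs(net)
        for motif_id in MOTIF_TYPES:
            mirna_sum = table.loc[table["kind"] == "mirna", motif_id].sum()
            tf_sum = table.loc[table["kind"] == "tf", motif_id].sum()
            assert mirna_sum == counts[motif_id]
            assert tf_sum == counts[motif_id]

    def test_regulator_outside_all_instances_has_zero_row(self):
        net = network_from(
            {
                "mir2tf": [("m1", "t1")],
                "mir2gene": [("m1", "g1"), ("m2", "g9")],  # m2: no TF partner
                "tf2gene": [("t1", "g1")],
            }
        )
        table = participation(net).set_index("regulator")
        assert table.loc["m2", "total"] == 0
        assert table.loc["m2", "n_types"] == 0

    def test_all_types_flag(self):
        pairs = {"mir2gene": [], "tf2gene": [], "mir2tf": [], "tf2mir": []}
        # one instance of every template around a single miRNA
        for i, motif_id in enumerate(MOTIF_TYPES):
            t, g = f"t{i}", f"g{i}"
            template = MOTIF_TEMPLATES[motif_id]
            if "m2t" in template:
                pairs["mir2tf"].append(("m0", t))
            if "t2m" in template:
                pairs["tf2mir"].append((t, "m0"))
            if "m2g" in template:
                pairs["mir2gene"].append(("m0", g))
            if "t2g" in template:
                pairs["tf2gene"].append((t, g))
        net = network_from(pairs)
        table = participation(net).set_index("regulator")
        assert bool(table.loc["m0", "in_all_types"])
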