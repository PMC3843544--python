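import pytest

from synregnet import SynthConfig, build_network, generate_relations
from synregnet.relations import RelationTables


@pytest.fixture
def toy_tables():
    """Two regulators and three genes covering several motif templates."""
    return RelationTables.from_pairs(
        {
            "mir2tf": [("m1", "t1")],
            "tf2mir": [("t1", "m1")],
            "mir2gene": [("m1", "g1"), ("m1", "g2")],
            "tf2gene": [("t1", "g1")],
        }
    )


@pytest.fixture
def toy_network(toy_tables):
    return build_network(toy_tables)


@pytest.fixture
def small_synthetic():
    """Seeded mid-size synthetic system exercising all four edge classes."""
    config = SynthConfig(
        n_mirna=20, n_tf=10, n_gene=100,
        n_mir2gene=150, n_mir2tf=25, n_tf2gene=60, n_tf2mir=15,
        seed=42,
    )
    tables, truth = generate_relations(config)
    return config, tables, truth


def brute_force_counts(network):
    """O(n^3) motif census by classifying every (miRNA, TF, gene) triple."""
    from collections import Counter

    from synregnet.motifs import MOTIF_TYPES, classify_triple

    counts = Counter({m: 0 for m in MOTIF_TYPES})
    for m in network.nodes_of("mirna"):
        for t in network.nodes_of("tf"):
            for g in network.nodes_of("gene"):
                motif_type = classify_triple(network, m, t, g)
                if motif_type is not None:
                    counts[motif_type] += 1
    return dict(counts)
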