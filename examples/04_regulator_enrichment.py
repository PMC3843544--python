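"""Find regulators whose targets are enriched for disease genes.

Plants 12 regulators that pick disease-gene targets at odds 5, runs the
hypergeometric test with BH adjustment over all regulators, and compares
the called set with the planted truth.
"""

from synregnet import SynthConfig, generate_relations, significant_regulators
from synregnet.pipeline import target_gene_map

config = SynthConfig(
    n_mirna=40, n_tf=20, n_gene=1000,
    n_mir2gene=4000, n_mir2tf=80, n_tf2gene=2000, n_tf2mir=40,
    n_disease_genes=100, n_enriched_regulators=12, enrichment_odds=5.0,
    seed=11,
)
tables, truth = generate_relations(config)
target_map = {**target_gene_map(tables, "mirna"), **target_gene_map(tables, "tf")}

table = significant_regulators(target_map, truth.disease_genes, M=1000, alpha=0.01)
called = set(table.loc[table["significant"], "regulator"])
planted = set(truth.enriched_regulators)

print(table.sort_values("q_value").head(12).to_string(index=False))
print(f"\nsensitivity: {len(called & planted) / len(planted):.2f} "
      f"({len(called & planted)} of {len(planted)} planted regulators called)")
print(f"false positives: {len(called - planted)} of {len(table) - len(planted)} "
      "unplanted regulators")
# Each row tests overlap x between a regulator's N targets and the k
# disease genes in a universe of M; q is the BH-adjusted p within the
# regulator family, and significance means q < 0.01.
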