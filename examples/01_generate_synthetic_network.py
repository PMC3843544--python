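"""Generate a synthetic regulatory system with planted structure.

Builds a small miRNA/TF/gene system with a disease-gene subset, planted
full-regulation motifs, and miRNA families, then prints what was planted.
"""

from synregnet import SynthConfig, generate_relations

config = SynthConfig(
    n_mirna=30, n_tf=15, n_gene=200,
    n_mir2gene=400, n_mir2tf=60, n_tf2gene=120, n_tf2mir=25,
    n_disease_genes=40,
    planted_motifs=[("I", 5), ("VII", 6)], motif_genes_per_pair=3,
    n_families=2, family_size=4, family_profile_noise=0.05,
    seed=1,
)
tables, truth = generate_relations(config)

print("edges per relation class:", tables.class_counts())
print(f"disease genes planted: {len(truth.disease_genes)}")
print(f"motif triples planted: {len(truth.planted_triples)} "
      f"(types {sorted({t for *_, t in truth.planted_triples})})")
for family, members in truth.family_membership.items():
    print(f"family {family}: {', '.join(members)}")
# The relation table is the input every later stage consumes; the truth
# object records what a recovery analysis should find.
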