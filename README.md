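# synregnet

Analysis of miRNA–transcription-factor (TF) synergistic regulation in
disease gene networks. Transcription factors act on promoters and miRNAs
act post-transcriptionally on 3′-UTRs; most disease genes are controlled by
both layers at once. `synregnet` builds the typed directed network over
{miRNA, TF, gene} from four regulator→target relation tables, selects
disease-relevant genes and regulators, finds the three-node regulatory
motifs that couple the two layers, tests them against a degree-preserving
random-network null, and scores the functional terms those motifs regulate.
It is aimed at computational biologists who already have regulator–target
relation tables (from target prediction and TF-binding databases) and want
the network, motif, and function analysis on top of them — plus a synthetic
data generator with planted ground truth to validate every stage.

## The method

**Regulator enrichment.** A regulator with `N` targets in a universe of `M`
genes, `k` of which are disease genes, and `x` targets overlapping the
disease set is scored by the hypergeometric upper tail

    P = P(X ≥ x),  X ~ Hypergeometric(M, k, N)

with Benjamini–Hochberg adjustment across regulators and a q < 0.01 cutoff.

**Motif census.** Every (miRNA m, TF t, gene g) triple is classified by its
exact edge configuration over {m→t, t→m, m→g, t→g} (induced matching:
template-absent edges must be absent). Ten configurations qualify,
from full regulation (all four edges) through feed-forward and feedback
loops to co-regulation (m→g, t→g only) and the two cascades (m→t→g,
t→m→g).

**Significance.** Null networks preserve every node's in- and out-degree
within each relation class (repeated double-edge swaps). With `N_real` the
observed count of a motif type and `N_mean`, `SD` the null mean and
standard deviation over `N_random` replicates,

    Z = (N_real − N_mean) / SD        P = N_high / N_random

where `N_high` counts replicates whose motif count reaches `N_real`.

**Function commonality.** Within each motif-type subnetwork *i*, every
miRNA–TF pair's shared target set (≥ 3 genes) is tested for term
enrichment (hypergeometric + BH, α = 0.005); `Frequent_i` counts the pair
sets in which a term is enriched and `rank_i` orders terms by frequency.
The network-wide commonality score of a term is

    score = Σ_i  Frequent_i / (rank_i × stagenumber_i)

with `stagenumber_i` the length (in nodes) of the template's longest
directed path; the top 5% of terms are the network's common functions, the
re-ranked remainder each subnetwork's specific functions.

## Worked example

Plant 30 full-regulation triples on a random background and test all ten
motif types against 1000 degree-preserving randomizations
(`examples/03_motif_census_significance.py`):

```text
planted type I: observed 94 vs null 54.9 +/- 7.2 -> Z = 5.46, empirical P = 0
```

The planted type stands far outside the null (none of the 1000 randomized
networks reached the observed count), while unplanted types stay
unremarkable or depleted. Planting 12 regulators whose targets favor
disease genes at odds 5 and running the enrichment test
(`examples/04_regulator_enrichment.py`):

```text
sensitivity: 1.00 (12 of 12 planted regulators called)
false positives: 0 of 48 unplanted regulators
```

The `examples/` directory holds one short script per capability:
generation, network statistics, motif significance, regulator enrichment,
term commonality, and expression/family recovery. A thin CLI mirrors the
stages (`synregnet simulate|genes|enrich|network|motifs|run`); the full
pipeline runs from a YAML config with `synregnet run --config cfg.yaml
--out dir/` and writes TSV/JSON artifacts plus a manifest.

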