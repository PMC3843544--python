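# Methods

## The regulatory system

The object of study is a simple directed heterogeneous graph over three
node classes — miRNAs, transcription factors (TFs), and genes — with four
edge classes: miRNA→gene and miRNA→TF (post-transcriptional repression),
TF→gene and TF→miRNA (transcriptional regulation). Genes are pure sinks; a
relation line that would give a gene out-edges is rejected rather than
silently reclassified, because the motif templates assume regulators and
targets are distinct roles. Duplicate edges collapse: the census assumes a
simple graph.

## Disease-gene selection

Expression matrices are log2-scale intensities with case/control labels.
Rows with more than 5% missing values are dropped; remaining gaps are
imputed as the mean of the K nearest rows (default K = 10) under
nan-Euclidean distance over co-observed columns (scikit-learn's
`KNNImputer`); probes of one gene are averaged. Differential expression
uses Welch's t-test on the log2 values with BH adjustment; a gene is
selected when its linear fold change `2^(Δmean)` exceeds 1.5 (either
direction) and q < 0.01. Selection is two-sided on the linear ratio; the
fold-change scale and sidedness are conventions of this package, exposed
as parameters. DE sets from multiple profiles combine by intersection
(default) or union — both conventions appear in practice, so the mode is a
flag — and then intersect with the curated disease list. Stability is
measured by bootstrap: samples are resampled with replacement *within*
each group (preserving the design), the gene set is recomputed, and the
overlap ratio with the original set recorded; 100 replicates by default.

A permutation-based microarray statistic (SAM-style) would be an
alternative selector; Welch + BH was chosen because it is fully specified,
fast, and calibrated — the pipeline needs a controlled selector, not a
particular test statistic.

## Regulator enrichment

The hypergeometric upper tail P(X ≥ x) is used for over-representation,
computed through scipy's log-scale survival function (stable for
M ~ 10^4). The tail *includes* the observed overlap; the variant that
sums only past it assigns p = 0 to a perfect overlap, which breaks the BH
step, so the conventional inclusive tail is used. x = 0 returns exactly 1.
miRNAs and TFs are adjusted as separate BH families, since they are
selected as separate regulator sets. M defaults to the size of the
supplied universe rather than a hard-coded genome size. The
random-gene-set validation repeats the whole enrichment with uniformly
drawn gene sets of the disease-list size and reports, per regulator, the
frequency of null significance — a direct false-positive calibration for
hubs. No pass/fail verdict is attached; the frequency is the result.

## Motif census

A triple (m, t, g) is classified by the 4-bit configuration
(m→t, t→m, m→g, t→g). Matching is induced: a configuration maps to a
template only if it equals it exactly, so the ten templates partition all
qualifying configurations and every triple belongs to at most one type.
The six non-qualifying configurations are those with no edge onto the
gene, and a lone m→g or t→g with no miRNA–TF edge (no synergy to speak
of). The fast census enumerates only miRNA–TF pairs joined by an edge
(plus their gene targets) and obtains the co-regulation count in closed
form as Σ_g |M_g||T_g| minus the gene-sharing counts of the three
templates with a miRNA–TF edge; it is tested for exact equality against
O(n³) brute-force classification.

Stage numbers for the commonality score are defined as the number of nodes
on the template's longest directed path: 3 for the FFL/FBL/cascade
templates (I–V, VIII, IX), 2 for co-regulation and the two
simultaneous-regulation templates (VI, VII, X). "Stages" is read as the
depth of the regulatory chain; the mapping is configurable per type and
recorded in output metadata.

## Randomization null

Null networks are generated by double-edge swaps within each relation
class independently: (a→b, c→d) → (a→d, c→b), rejecting swaps that would
duplicate an existing edge. This preserves every node's in- and out-degree
per class exactly — the rewired network has the identical summary table.
Default 100 swap attempts per edge; the tests use 1–5 attempts per edge on
small networks, where the toy-state-space test shows the chain already
mixes across the attainable graphs. Each replicate rewires independently
from the observed network with its own spawned seed, so replicates are
exchangeable and reproducible. Replicate counts are streamed into running
moments; nothing is stored per replicate. SD is the population
(divide-by-n) standard deviation. The empirical P uses the ≥ convention
(count reaching the observed value) and is reported as N_high/N_random
without a continuity correction; with a zero-spread null (SD = 0) Z is
reported as undefined while P remains valid.

## Commonality scoring

Pair target sets are the genes a miRNA–TF pair reaches together within one
motif-type subnetwork; sets below 3 genes are discarded as too small to
enrich. Terms are tested per pair set (hypergeometric + BH within the
set's term family, α = 0.005 on adjusted values; a flag switches to raw
p). Frequencies are ranked per subnetwork with dense 1-based ranks, ties
sharing the smaller rank. Subnetworks where a term is not enriched
contribute 0 to its score (no rank exists there; imputing a worst rank
would reward sheer annotation size). The top 5% by score are flagged
common — a count-based cutoff, so exact score ties straddling the boundary
are truncated in lexicographic order — and specific lists are the
per-subnetwork re-ranked remainders.

## Synthetic data generator

The generator emulates the study's input universe at configurable scale.
Defaults mirror the curated lung-cancer network (252 miRNAs, 174 TFs,
1002 genes; 29877/1107/1588/207 edges per class); tests and examples pass
smaller explicit configs and state their sizes below. Edges are sampled
without replacement per class (no multi-edges — the census assumes simple
graphs), with uniform or rank-weighted ("powerlaw", exponent a free knob)
source degrees. Enriched regulators draw gene targets with weight equal to
the configured odds on disease genes; sampling without replacement
depletes the favored pool slightly, so the realized target fraction sits a
little below odds·k/(odds·k + (M−k)).

Planted motif triples are inserted after background sampling on
plant-disjoint (miRNA, TF) pairs and globally distinct genes; required
template edges are added and forbidden ones removed (removals logged and
recorded in the ground truth), guaranteeing each planted triple classifies
to its type under induced matching. Plants and families therefore add
edges beyond the configured background budgets; the emitted table is
authoritative. Families copy one prototype TF-target row per family with
per-cell flip noise, which makes family recovery by two-way clustering
(Jaccard distance, average linkage — the matrix is binary; both are flags)
a testable property. Expression baselines are Gaussian per gene
(mean 8, SD 2 on the log2 scale), case samples shifted ±log-FC for planted
DE genes; missing cells are completely at random, as nothing more
structured is assumed. Mutation calls are independent Bernoulli per
gene × sample. Annotation terms are uniform background draws, plus planted
terms covering the planted pair-set genes of all types (common) or one
type (specific).

What the generator does *not* emulate: correlated expression between
co-regulated genes, probe-level artifacts, informative missingness,
sequence-level structure, or annotation term overlap/hierarchy. Passing
recovery tests therefore show the pipeline's statistics are calibrated and
powerful under clean planted signal — not that real microarray or
annotation data meet these assumptions.

## Study sizes used by the tests and the acceptance script

- Census-vs-oracle: 100 seeded networks of ≤ 60 nodes (exact equality).
- Rewiring conservation: 1000 seeded rewires of a 500-edge network.
- Null calibration: 20 configuration-model networks (63 nodes, 225 edges),
  500 replicates each, 5 swap attempts per edge; per-type empirical P
  tested for uniformity (KS, α = 0.01). Planted-motif detection: 30
  full-regulation triples, 1000 replicates.
- Regulator recovery: 60 regulators with ~100-gene target sets over a
  1000-gene universe (the real network's miRNAs average ~119 gene
  targets), 100 disease genes, odds 5. At this scale the test's power is
  decisive (sensitivity 1.0 over repeated seeds); with ~30-gene target
  sets the same pipeline averages ~0.82 sensitivity — small target sets,
  not the implementation, are the limit.
- DE recovery: 500 genes (10% DE at log2 FC 2, noise SD 0.5), 20 + 20
  samples; bootstrap with 100 replicates.
- Commonality recovery: 10 planted triples of each type, 5 genes per
  pair, one planted common term against 100 background terms.
- Family recovery: 6 families × 5 miRNAs over 30 TFs at 3% profile noise.

## Known limitations

- The empirical P is granular at 1/N_random and conservative at its
  atoms; Z complements it for ranking, as in the reference analysis.
- The census is exact only on simple graphs; duplicate input lines are
  collapsed silently by construction.
- The swap chain's mixing is verified exhaustively only on toy state
  spaces; for large sparse classes the default 100 attempts per edge
  follows common practice rather than a mixing proof.
- The commonality cutoff is count-based; ties at the boundary are
  truncated deterministically rather than expanded.
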