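# Methods

`cmlight` reimplements, as a tested library, the network-and-transcriptome
workflow used to find light-responsive transcription factors (TFs) in
*Cordyceps militaris*: an expanded gene regulatory network (eGRN) is
reconstructed by interolog transfer from fungal template species, a
light-vs-dark differential-expression contrast is overlaid on it, and the
TFs central to the resulting subnetwork are ranked by normalised
betweenness. Genome-scale inputs (proteome alignments, curated PPI
databases, raw reads) are replaced by synthetic generators with recorded
ground truth, so every stage is verifiable; the desk-scale published
numbers (sequencing summaries, metabolite assays) are carried as small
built-in tables.

## Orthology and interolog transfer

Orthologs between a template proteome and the target proteome are
reciprocal best BLASTp hits (BBH). Hits are first filtered at sequence
identity >= 25 % and E-value <= 1e-10; the E-value comparator is
configurable (`inclusive=False` gives the strict `<` form) because both
conventions occur in practice. Per query, the winner has minimal E-value,
ties broken by maximal bitscore, then lexicographically smallest subject —
the tie-break is our convention, chosen to make results deterministic;
multiple HSPs per query/subject pair fall out of the same ordering.

A caveat worth stating: BBH is *not* monotone in the thresholds. Tightening
identity or E-value can remove a non-reciprocal best hit and promote a
reciprocal second-best hit, creating a pair that did not exist under the
looser thresholds. The tests assert the correct conditional form (a pair
found under tight thresholds whose winning hits also win under the loose
thresholds must persist).

Template PPI edges (P, Q) transfer to (p, q) when both endpoints have
ortholog targets; self-loops (p = q, possible only from template
self-interactions, since the BBH map is injective) are dropped and
duplicates collapsed. Interolog edges are **undirected** (physical
interaction), while prior-network and ChIP edges are **directed**
(regulation); the eGRN stores a per-edge `directed` flag so neither
semantics is lost, and the interaction total counts each unordered node
pair once. A node is a TF iff it is on the supplied TF list (ChIP
regulators missing from it are promoted with a warning); it is "regulated"
iff it has an incoming directed edge or is the non-TF endpoint of a TF
interaction.

## Expression processing

FPKM is `counts * 1e9 / (length_bp * library_size)` with library sizes
defaulting to the column sums of the *filtered* count matrix (the
pre-/post-filter choice is not fixed by convention; column sums of what is
analysed is the simplest self-consistent reading). Genes with fewer than
5 reads in every sample are removed first. Replicates are summarised per
condition by the geometric mean, with zeros propagating to a zero mean (no
pseudocount; one is configurable in the stand-in statistics instead).
Expression categories are the half-open bins [0,1), [1,10), [10,100),
[100,inf), so a mean of exactly 10 is "moderate" and exactly 100 "high";
a gene is expressed in a condition iff its mean FPKM >= 1, and the
two-condition Venn partition covers exactly the genes expressed somewhere.

Reported summary tables use round-half-up to two decimals. Dispersions are
reported as both sample (ddof = 1) and population (ddof = 0) standard
deviations, because published summary tables are inconsistent about which
is printed; only the means are treated as reproducible quantities.

## Differential expression

The significance gate is |log2FC| >= 1 (inclusive) together with
FDR < 0.001 (strict). The per-gene statistics are an input — in the
original workflow they come from DESeq2, which this package deliberately
does not reimplement. For self-contained runs two labelled stand-ins are
provided, both operating on log2(FPKM + 1):

* `welch_deg_stats` — a plain per-gene Welch t-test with BH adjustment.
  With 5 replicates per condition its ~8 degrees of freedom impose a
  p-value floor near 1e-5, so after BH adjustment it cannot push true
  effects below FDR 0.001 reliably: on planted |log2FC| = 2 effects it
  recovers only about half. It is kept as the transparent baseline.
* `moderated_deg_stats` — the pipeline default: a pooled-variance t-test
  with empirical-Bayes variance moderation in the style of limma. The
  prior df d0 and scale s0² are fitted by matching the moments of
  log s_g² to a scaled F distribution (Fisher's-z moments, trigamma
  inversion); the posterior variance is (d0 s0² + d s_g²)/(d0 + d) and the
  moderated t has d + d0 df. This is the field-standard small-replicate
  statistic and recovers ~99 % of planted |log2FC| = 2 effects at
  FDR < 0.001 with 5 replicates.

Term enrichment is the hypergeometric upper tail P(X >= k) for a query of
n genes against a term annotating K of N universe genes
(`scipy.stats.hypergeom.sf(k-1, N, K, n)`; K = 0 gives p = 1 by
convention). Significance follows the raw p < 0.05 rule of the original
workflow; BH-adjusted p-values are always reported alongside for stricter
use.

## Subnetwork and TF ranking

The light-responsive subnetwork keeps, by default, edges whose **both**
endpoints are significant DEGs (`both_endpoints`); this is the only rule
under which the subnetwork is an induced DEG structure, and a
`target_only` alternative (edge kept when the regulated gene is a DEG) is
exposed because the narrative description of the original analysis is
ambiguous. Isolated nodes are dropped.

Betweenness is computed on the undirected, unweighted view of the
subnetwork (matching the default of the Cytoscape/cytoHubba workflow this
mirrors), summing over unordered pairs, with disconnected pairs
contributing zero; a directed option exists. The ordered/unordered pair
convention only rescales B(n) and cancels under the min-max normalisation

    b_norm(n) = (B(n) - min B) / (max B - min B),

so the ranking is unaffected either way. When all scores are equal the
normalisation is degenerate; all scores are set to 0 with a warning. TFs
with b_norm strictly greater than 0.1 are potential regulators, ranked by
their number of distinct regulated targets in the subnetwork (ties by
b_norm, then id). The regulated fraction is the union of the top TFs'
targets over the subnetwork node count, as a half-up-rounded percentage.

networkx's `betweenness_centrality(normalized=False)` supplies the raw
scores; the test suite checks it node-for-node against a hand-written
all-shortest-paths enumeration on small random graphs, plus exact closed
forms on paths, stars and trees.

## Assay formulas

Glucosamine content is (C · V_f · V_e) / (W_e · V_a · 1000) in mg/gDW —
the only grouping of the published expression that is dimensionally
consistent with C in µg/mL (the 1000 converts µg to mg); the grouping is
implemented as a single documented function so an alternative reading
would be a one-line change. Biomass is G · W_f / W_s in g/kg. Light/dark
comparisons use the equal-variance Student's t-test (Welch available via
`equal_var=False`), with the light/dark ratio rounded to one decimal.
Where only mean ± sd summaries (n = 3) are available, replicate triples
(mean − sd, mean, mean + sd) are reconstructed; they reproduce the stated
mean and sample sd exactly, which is sufficient for the ratio and for a
t-test on the published precision.

## Synthetic data: what it emulates, and what passing tests show

The generators define the study conditions for every benchmark:

* **Template PPIs** — uniform random simple graphs. Defaults in the
  pipeline: 150 proteins, 400 edges per template, two templates.
* **Hit tables** — planted orthologs appear as reciprocal best hits with
  identity in [40, 95] % and E-values log-uniform in [1e-180, 1e-11];
  decoys (default rate 0.2 per query) are either threshold-failing
  (identity < 25 % or E-value in [1e-9, 1]) or threshold-passing but
  non-reciprocal, exercising both BBH filters. By construction BBH
  recovers exactly the planted pairs, which is what the precision/recall
  benchmarks assert.
* **Counts** — negative binomial with variance mu + phi·mu², the standard
  RNA-seq count model; phi defaults to 0.05, a typical value for clonal
  fungal cultures grown as controlled biological replicates. Baseline
  means are log-normal (ln 500, sigma 1.0); planted DEGs (half up, half
  down) have the light mean multiplied/divided by 2^effect, effect 2 by
  default; gene lengths are uniform in [300, 10000] bp. Benchmarks use
  2000 genes and 5 replicates per condition.
* **Regulatory networks** — planted hub TFs with out-degree 60 (40 in the
  benchmark GRNs) against background TFs with out-degree 2.

What the synthetic data does **not** model: mapping bias, GC and length
effects on counts, correlated genes, batch effects, partial orthology
(paralog families), or circadian structure in the light response. Passing
benchmarks therefore demonstrate the correctness of the algorithms under
their stated assumptions, not the biological error rates to expect on real
sequencing data.

## Problem sizes and determinism

The end-to-end pipeline (`cmlight.pipeline.run_pipeline`) uses a
desk-scale network (40 TFs, 400 genes, 5 hubs) so a full run takes about a
second. All randomness flows from a single integer seed through
`numpy.random.default_rng`; two runs with the same seed write byte-identical
TSV/JSON/GraphML outputs, which the test suite asserts with file-level
comparison. When expression ids are mapped onto network nodes, planted hub
TFs are placed on planted upregulated slots — light-responsive regulators
are themselves differentially expressed — so the planted regulatory signal
survives the DEG filter by design rather than by chance.

## Known limitations

* The eGRN deduplication convention (directed and undirected records
  between the same pair stay distinct but count once as an "interaction")
  is a defined convention; published interaction totals may count
  differently.
* `moderated_deg_stats` is a substitute for a count-model fit; on real
  data DESeq2/edgeR output should be supplied to `call_degs` directly.
* Betweenness on the subnetwork (rather than the full eGRN) is the
  default; computing it on the full network before extraction is possible
  by calling `betweenness` on the eGRN's edges but changes the ranking.
* The printed dispersions of published summary tables are not asserted
  anywhere: they match neither sample nor population SD of the per-sample
  values in all columns, so only the means are treated as reproducible.
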