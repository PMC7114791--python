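# Methods

## Scoring model

The package summarizes WGBS evidence gene by gene. Input is a per-cytosine
call table (the Bismark cytosine/CX report dialect: chromosome, 1-based
position, strand, methylated count, unmethylated count, context,
trinucleotide). All coordinates are converted to 0-based half-open
internally; GFF3/GTF annotations are read as 1-based inclusive, BED as
0-based half-open. A cytosine on a region boundary belongs to the region
iff start ≤ pos < end.

For every gene two regions are derived: the **body**, the full annotated
gene extent, and the **promoter**, `promoter_length` bases immediately
upstream of the TSS (upstream of `start` on +, downstream of `end` on −),
clipped at the chromosome edges. The default promoter length is **2000 bp**
— a common gene-centric default; no canonical value exists, so it is
configurable everywhere (`--promoter-length`). Transcript isoforms,
alternative TSSs and exon structure are out of scope: the body is the full
gene extent. Overlapping genes are scored independently; a cytosine inside
two genes' regions contributes to both.

The score per (gene, region, context) is the **coverage-weighted
methylation level** Σmᵢ / Σ(mᵢ+uᵢ) over sites with coverage ≥
`min_coverage` (default 1 — uncovered sites carry no evidence). The
weighted level was chosen over the mean of per-site fractions because it
is invariant to record order and to splitting one site's counts across
rows, and it is the maximum-likelihood estimate under the binomial
sampling model below; the per-site mean is available behind `--site-mean`
for comparison with tools that report it. An empty denominator yields a
missing score, serialized as `NA`.

Strands are not merged by default: for a summed ratio, symmetric CG pairs
contribute identically whether merged or not. `--destrand` merges + / −
CG pairs at adjacent positions for parity with destranding tools.

## The mtable format

One row per gene, exactly seven tab-separated columns in the fixed order
`gene_id, promoter_CG, promoter_CHG, promoter_CHH, body_CG, body_CHG,
body_CHH`; scores printed with 6 decimals, `NA` for missing. Files carry
`#`-prefixed header lines recording the sample name and the parameters the
scores were computed with, so every output is self-describing; headerless
consumers can skip `#` lines. Reading validates the column count and the
[0, 1] score range.

## DMG calling

Differential methylation is assessed per (region, context) score column by
plain arithmetic: pairwise, a gene is called when |level_A − level_B| ≥ δ;
with a background panel, the adjusted score is the target level minus the
**mean** of the background levels present for that gene (median or a fixed
reference were alternatives; the mean is the documented choice), clamped
to [−1, 1]. The default δ = **0.2** is a conventional effect size for
methylation differences; it is always echoed into the output metadata.
There is deliberately no p-value: replicate-aware DMR/DMC statistics are a
different tool's job, and the gene-centric difference is meant as a
broad-scale signal. Genes missing a score in either condition are skipped
and counted, never imputed.

## Enrichment

Over-representation of a term with K genes (after intersection with the
universe) in a query of n genes from a universe of N uses the upper-tail
hypergeometric probability P[X ≥ k] (the observed overlap included —
the standard over-representation convention), computed with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`. The default universe is the set
of genes actually measured (the mtable), conditioning on measurability;
`--universe` overrides. Terms smaller than `min_term_size` (default 2)
after universe intersection are skipped. Mappings are used flat — no GO
graph propagation. Benjamini–Hochberg step-up q-values
(q₍ᵢ₎ = minⱼ≥ᵢ p₍ⱼ₎·m/j, capped at 1) are computed over all tested terms;
p-values must lie in (0, 1].

## Network centralities

Interaction graphs are simple and undirected: duplicate/reversed pairs
collapse, self-interactions are dropped and counted. Five centralities per
node v in a graph of N nodes:

- degree; degree / (N−1);
- closeness restricted to v's connected component of r nodes,
  (r−1)/Σd(v,·), zero for isolated nodes — finite on disconnected graphs
  without infinite-distance conventions;
- normalized closeness with the Wasserman–Faust factor, closeness·(r−1)/(N−1),
  comparable across components;
- Freeman betweenness (endpoints excluded), normalized by (N−1)(N−2)/2.

Graphs with fewer than two nodes score 0 everywhere. Exports are
Cytoscape.js elements JSON (nodes carry the centralities as data
attributes) and a two-column edge TSV; layout is a rendering concern and
is not computed.

## Gene sets and Venn analysis

Batch queries match identifiers case-insensitively against gene ids first,
then symbols; an id match wins on collision because ids are the primary
key. Venn analysis accepts 2–4 sets and partitions their union into the
2^k − 1 exclusive membership regions (disjoint, covering). Sets persist as
JSON with the full provenance log (operation, parameters, inputs,
timestamp per entry, append-only); plain one-per-line text is supported
for interoperability.

## Synthetic data generator

The simulator emulates exactly the sampling process the scoring model
assumes: genes packed left-to-right with alternating strands on one
chromosome (the inter-gene gap defaults to twice the default promoter
length plus 1 kb so promoter and body regions stay disjoint); per region
and context, a fixed number of cytosine sites (default 10) placed
uniformly; per-site coverage 1 + Poisson(mean − 1) (default mean 20, so
every site has evidence); methylated counts Binomial(coverage, p) with p
drawn once per (gene, region, context) from Uniform(0.05, 0.95). Condition
pairs shift p by Δ for designated effect genes in one score column; a
shift leaving [0, 1] is an error, and the dataset writer rescales effect
genes' base levels into the feasible band. An optional ε flips read calls
to mimic bisulfite conversion error (default 0). Everything is
deterministic given a seed, byte-identically for the file writers.

What the simulator does **not** emulate — realistic genome sequence and
context density, spatial autocorrelation of methylation along a region,
read-level errors and mapping bias, biological replicate variance —
bounds what passing tests show: they validate the estimator and callers
under their own sampling model, not robustness to artifacts of real
libraries.

Under this model the scored level has standard error ≈ √(p(1−p)/n) for n
total reads in a region, which is what the recovery checks use: with 100
genes × 2 regions × 3 contexts (600 measurements, ~200 reads each),
estimates fall within 3 SE ≥ 99% of the time; DMG calling at δ = 0.2
recovers |Δp| = 0.4 effects at region coverage ≥ 100 reads with
sensitivity ≥ 0.95 over 100 replicate pairs (the acceptance suite uses 20
genes, 5 effect genes, coverage mean 15 → ~150 reads/region), with a
false-call rate among unchanged genes far below 1%. These problem sizes
keep the full suite and the acceptance script within seconds while leaving
the statistical margins wide.

## Numerical and design notes

- Scoring accumulates integer numerators/denominators; no tolerance issues
  arise beyond float division at the end. Equality tests against the
  brute-force oracle use 1e−12; centrality comparisons use 1e−9.
- The mtable's 6-decimal fixed formatting makes write→read round-trips
  exact to printed precision.
- BH adjustment is implemented directly from the step-up definition (and
  cross-checked against statsmodels in the tests) because the library
  routine does not enforce the (0, 1] p-value domain this API promises.
- GFF3/GTF/BED gene parsing is a narrow in-package reader (gene features
  only) so malformed lines can be reported by line number.
- The CX reader streams; per-record state is constant, so memory does not
  grow with file length. Scoring keeps one interval tree over regions and
  two counters per (gene, region, context).

## Known limitations

- Promoter definition and gene body = full extent are conventions, not
  biology; results shift with `--promoter-length`.
- The DMG caller has no replicate model; users needing statistical DMRs
  should use a dedicated DMR tool.
- Enrichment treats annotations as flat sets; GO ancestor propagation, if
  wanted, must happen upstream of the mapping file.
- The Bismark "coverage" format (no context column) is not accepted:
  context-stratified scores require the cytosine/CX report.
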