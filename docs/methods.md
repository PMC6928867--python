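# Methods

## Scope and model

`cordhox` re-implements, on local files, a cross-database inference chain
that links region-specific homeobox expression to a gliosis-associated
regulatory module: signature crossing, exact over-representation, median
expression filtering, two-group differential expression, protein-interaction
first-shell crossing with a TF catalog, GO co-occurrence screening, and
typed network assembly. Gene identity throughout is the normalized HGNC-style
symbol (uppercase, whitespace-stripped); no identifier-mapping service is
used, so inputs must already be symbol-keyed. Each ingestion path
normalizes exactly once, and re-reading written output is a no-op.

## Statistics

**Over-representation.** The one-sided Fisher exact test for enrichment is
the hypergeometric upper tail P(X ≥ k) with universe N, annotated class K,
draw n and overlap k. Binomial coefficients are evaluated with log-gamma and
the tail summed via log-sum-exp, so genome-scale universes (N ≈ 20,000) are
handled without overflow; the result is clamped to [0, 1] and k = 0 returns
exactly 1. A two-sided Fisher test is deliberately not offered — every use
in this pipeline asks only about over-representation.

**Fold enrichment** is (k/n)/(K/N), zero iff k = 0. On the module-overlap
contingency (k=2, n=7, K=12, N=1211) this gives 28.83, whereas the published
report prints 31.74 for the same counts; no denominator consistent with the
printed counts reproduces 31.74, so the factor is treated as a reporting
discrepancy, fold is defined as above, and only the tail probability
(0.0018, printed 0.002) is treated as reproducible. The same report's
p-value also identifies n = 7 (HOXA5's own TF partners) rather than n = 14
(all HOX TF partners, which would give p ≈ 0.008) as the draw size.

**Multiple testing.** Benjamini–Hochberg is the standard step-up rule:
ascending p, q₍ᵢ₎ = p₍ᵢ₎·m/i, running minimum from the largest rank down,
capped at 1, restored to input order; a final elementwise max with the raw p
guards the mathematical invariant q ≥ p against one-ulp division error at
rank m. Bonferroni is min(1, p·m). Both validate inputs to (0, 1].

**Welch differential expression.** Per gene, t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂)
with Welch–Satterthwaite degrees of freedom and a two-sided p (scipy's
unequal-variance t-test), Bonferroni-corrected across all genes tested.
Genes with zero variance in both groups and equal means get t = 0, p = 1 by
convention. Fold ratios are ratios of linear-scale group means; a zero
denominator with a positive numerator is reported as infinite, 0/0 as NaN.
Replicate columns can be averaged onto their biological specimen via a
replicate map before testing; absent a map, columns are treated as
independent samples (how the original two-group comparison handled its
three replicate spinal-cord arrays is not recorded, so both behaviours are
available and the default makes no collapsing assumption).

**Region filter.** A gene passes when its target-region median is
≥ `min_target` (default 5 TPM, inclusive) and every other region is
< `max_other` (exclusive). The 1.0 TPM default for `max_other` cleanly
separates the published worked example's off-target maximum (0.54 TPM) from
its on-target minimum (5.37 TPM) while implementing "not or only very
poorly expressed"; both thresholds are configurable. The filter is monotone:
raising `min_target` or lowering `max_other` never admits a gene.

**GO co-occurrence.** Two terms co-occur when they share ≥ 1 annotated
protein. Similarity is percent Jaccard, S% = 100·c_ab/(c_a+c_b−c_ab), and
the probability ratio PR = (c_ab/c_b)/(c_a/N) compares the conditional
frequency of the query among the other term's proteins to its marginal
frequency. Co-occurring terms are ranked by similarity (ties: PR, then term
id), ranks 1..n. These definitions are a reconstruction: the web service
whose listings motivated the screen does not document its statistic, so
ranks observed on public corpora are corpus- and formula-dependent
expectations, not targets. The antagonism screen examines the four
cross-pathway pairs of two (positive, negative) regulation-term pairs and
returns "antagonism-only" when every observed overlap joins opposite
polarities.

GAF 2.x ingestion uses Biopython's GAF iterator; "NOT"-qualified rows are
dropped, evidence codes are kept unless a whitelist is supplied, and protein
identity is the DB object ID (column 2) to avoid symbol ambiguity. Term
names travel in a sidecar id→name table because GAF carries none.
Annotation propagation to is_a/part_of ancestors (obonet ontology graph) is
off by default, since the original screen's propagation behaviour is
unknown; enabling it requires an explicit ontology file.

## Synthetic data: what it emulates

The generators produce every input class with planted structure, as pure
functions of (config, seed) — per-generator independent substreams of one
seeded PCG64 generator; identical configs give byte-identical files.

* **Median matrix** (29 genes × 4 regions by default): the 10 published
  homeobox rows verbatim, plus 19 distractor genes whose target-region TPM
  is uniform below 5 and whose other regions are below 1 — the filter's
  decision boundary is therefore exercised from both sides.
* **Sample matrix** (10 vs 10): group means set by the planted fold ratios
  (published values, e.g. 234.9 for the strongest gene); per-sample values
  are lognormal with σ = 0.25 on the natural-log scale, mean-corrected by
  exp(−σ²/2) so expectations equal the group means exactly and the
  noiseless limit recovers folds exactly. The 0.25 default (~25%
  donor-to-donor coefficient of variation) is the noise magnitude consistent
  with Bonferroni-adjusted p-values of order 10⁻⁵ at n = 10 for folds in the
  hundreds, as in the comparison being emulated. Null genes share one mean
  across groups.
* **Interactome**: the 15 curated HOX–TF edges (14 distinct TFs), 71 non-TF
  decoy partners spread over the 10 queries (85 first-shell partners in
  total), second-shell edges from SMAD1/SOX2 into the module, and random
  background edges confined to background proteins so the queries' first
  shell is exactly the planted structure. The TF catalog is padded to 1211
  members; the module holds the 5 named TFs plus catalog decoys up to 12.
* **GO corpus**: four polarity-named terms (30 proteins each) over two
  pathway concepts; the planted antagonistic pair shares 5 proteins, all
  other pairwise intersections among the four are empty (mirroring the
  published screen, where one antagonistic pair overlapped and the other
  three pairs did not); 200 background terms draw freely from a 2000-protein
  universe and may co-occur with anything.
* **Signatures / annotation library**: an "SC" signature containing the
  planted genes plus synthetic SC-specific genes, a "Brain" signature, a
  shared block, and an annotation library whose "HOMEOBOX" term holds the
  planted genes plus decoy homeobox genes; decoy family terms draw only from
  brain/shared genes so they are not enriched in the SC-specific query.

What the generators do **not** emulate: count-level RNA-seq properties
(library size, overdispersion), microarray probe effects, correlated genes,
incomplete interactome coverage, or GO term-size distributions. Passing
recovery tests therefore demonstrates correctness of the statistics and the
pipeline plumbing under the stated effect sizes — not robustness to the
technical artefacts of real datasets.

## Numerical and design choices

* Tail probabilities are exact to ≤ 10⁻¹² relative error against rational
  enumeration over all parameterizations with N ≤ 30, and agree with
  scipy's survival function at genome scale.
* Enrichment rows sort by adjusted p, ties by raw p then term name;
  co-occurrence ranks break ties by probability ratio then term id — all
  orderings are total, so outputs are deterministic.
* Interactome edges store endpoints lexicographically; the edge set is
  invariant to input row order. Species filter defaults to taxon 9606 and
  the six-column dialect can be remapped via a column map for pre-projected
  exports.
* Degenerate inputs: empty signatures, empty queries after universe
  intersection, empty partner sets and sub-2-sample groups are errors;
  isolated queries and missing single screen terms degrade to warnings or
  "no overlap" entries.
* The pipeline's module-enrichment stage tests each query's TF partners and
  reports the strongest (smallest-p) overlap; with the bundled structure
  that is always the HOXA5-like query.
* Network edges: repression and predicted-binding are directed TF→target;
  physical edges are undirected and order-normalized. The physical layer of
  the bundled curated network is an editable fixture (the underlying figure
  does not enumerate its grey edges in text), not hard-coded truth.

## Problem sizes

Default test and acceptance runs use the bundled study-scale conditions:
29-gene matrices, 10-vs-10 groups (200 seeded recovery replicates), a
~1500-protein interactome with a 1211-TF catalog, and 204-term GO corpora
(100 seeded replicates). The full suite completes in well under a minute on
one CPU.

## Known limitations

* Symbol-keyed only; no probe-to-gene or cross-species mapping.
* One-sided enrichment only; no GSEA-style ranked statistics or permutation
  nulls.
* The GO co-occurrence statistic is a documented reconstruction (see
  above); published ranks from the original web service are not
  reproducible targets.
* Differential expression is a plain Welch test — no count models,
  moderation or normalization; inputs are assumed already normalized.
* Externally published set sizes that depend on live database snapshots
  (signature-specific gene counts, interactor totals on current interactome
  releases) are documented expectations, not assertions.
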