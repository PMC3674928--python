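# Methods

## Genomic categories

The unit of annotation is the *gene model*: one record per gene, with a
strand, a span, and the union of all its transcripts' exons (overlapping
exons merged). Working at the gene level keeps the category set small and
the partition unambiguous; UTR/CDS structure and alternative transcripts
are deliberately ignored. All internal coordinates are 0-based half-open;
GTF/GFF3 (1-based inclusive) are converted on read, BED passes through.

Each base of each chromosome receives exactly one of seven categories.
Candidate labels per gene are:

| label | definition (gene orientation) |
|---|---|
| exon | inside any exon |
| intron | inside the gene span but not an exon |
| 5' near | within `near_limit` upstream of the 5' end (TSS) |
| 3' near | within `near_limit` downstream of the 3' end (TES) |
| 5' far | between `near_limit` and `far_limit` upstream of the TSS |
| 3' far | between `near_limit` and `far_limit` downstream of the TES |
| distant | none of the above, for every gene |

`near_limit` and `far_limit` are in bp, defaults 5 000 and 25 000, with
`0 < near ≤ far`. Where candidates from any genes overlap, the
highest-precedence label wins (exon > intron > 5' near > 3' near > 5' far >
3' far > distant); within one tier, membership from *any* gene suffices —
no per-gene bookkeeping survives into the map. Flanks are truncated at
chromosome boundaries, never wrapped. When chromosome lengths are unknown
(e.g. BED12 input with no sizes file) each length defaults to the maximum
annotated coordinate plus `far_limit`, which is the furthest point at which
the partition can still be non-distant.

The flattening is implemented as a boundary sweep: all candidate interval
endpoints partition the chromosome into elementary segments, each segment
takes the highest-precedence covering category, and adjacent same-category
segments are merged into runs. The runs tile `[0, chrom_length)` exactly;
this partition property and agreement with a brute-force per-gene
precedence scan are asserted by tests.

## Per-locus context

A locus is categorised at its midpoint, `floor((start + end) / 2)`. The
categories must be mutually exclusive per locus for the homogeneity test to
apply, and a wide peak can straddle several categories; the midpoint is the
simplest point summary that preserves exclusivity. The nearest gene
minimises the unsigned distance from the midpoint to the gene *span*
(0 inside); ties break to the smallest gene start, then gene id, which
makes outputs reproducible but is otherwise arbitrary. Signed distances to
the nearest gene's 5' and 3' ends are measured along the gene's
orientation: positive = the midpoint lies downstream (3'-ward) of that end.
Under this convention `dist5 − dist3` always equals the gene span length,
and inside a gene `dist5 ≥ 0 ≥ dist3`.

Edge policies: loci on chromosomes absent from the annotation count as
distant (logged, never silently dropped); loci beyond the mapped extent of
a known chromosome are likewise distant (they are farther than `far_limit`
from every gene); a locus on a chromosome that carries no genes gets no
nearest-gene fields, since a cross-chromosome distance is undefined.

Distance histograms default to ±100 kb in 5 kb half-open bins; values at or
beyond the bounds are tallied out of range, and the in-range counts plus
the out-of-range tally always equal the number of loci with a defined
distance.

## Comparing category distributions

The Brandt–Snedecor statistic

    chi2 = n^2/(n1 n2) [ Σ_i n1i^2/(n1i + n2i) − n1^2/n ]

is an algebraic rearrangement of the Pearson chi-square of the 2 × k
contingency table (verified to 1e−9 against an independent Pearson
computation on random tables). Categories empty in both sets carry no
information and make the formula 0/0; they are dropped and the degrees of
freedom reduced to `k_eff − 1`. Proportional counts give statistic 0 and
p = 1. The test assumes independent observations, exhaustive and mutually
exclusive categories, and a background at least twice the foreground; the
size assumption is reported as a warning rather than an error, as are
expected cell counts below 5.

One caveat the package documents rather than hides: when the foreground is
a *subset* of the background (a common design — a subset of peaks against
all peaks), the shared observations make the two columns dependent and the
test conservative. Simulation (500 replicates of a uniform 25% subsample,
asserted in the test suite) shows the rejection rate at α = 0.05 falls well
below nominal, so a significant result in the nested design is trustworthy,
while a non-significant one is weak evidence. With independent samples the
test is well calibrated (type-I error 5% ± 1.5% at n1 = 500, n2 = 1000 over
2 000 replicates, asserted in the suite).

Per category, the 2 × 2 table of the category against the union of the
others is tested with the plain log-likelihood G-test, `G = 2 Σ O ln(O/E)`
with `0·ln(0/E) = 0`, 1 df, and no Williams or Yates correction. The
enrichment ratio is the foreground/background frequency ratio, undefined
when the background count is 0. Because seven dependent tests are reported
together, raw and Bonferroni-adjusted p-values (m = 7) are both given and
the significance stars (`***` < 0.001, `**` < 0.01, `*` < 0.05) use the
adjusted values — a conservative, transparent choice. p-values print in
scientific notation with 4 significant digits; values below the
double-precision floor print as `< 2.2e-16`.

## GO enrichment

The study set is the deduplicated nearest-gene set of the foreground loci;
the population that of the background loci (or any gene universe). Both are
intersected with the genes that carry annotations; study genes outside the
population are dropped with a warning. Annotations propagate to ancestors
along `is_a` edges only — the smallest defensible closure; `part_of` and
other relations are ignored. Each term with at least one population carrier
is tested with the one-sided hypergeometric upper tail
`P(X ≥ study_hits)`, and Benjamini–Hochberg adjustment is applied across
tested terms. Term-for-term testing ignores the dependence between related
GO terms; model-based alternatives (parent–child, MGSA) are out of scope.
Any species' gene→term mapping is accepted as a two-column TSV plus an
OBO 1.2 file.

## Synthetic data generator

The generator emulates the study conditions the package is designed for: a
small genome (default two chromosomes of 1 Mb) with 40 non-overlapping,
strand-annotated multi-exon genes (2–6 exons, spans 2–20 kb, first and
last exon flush with the span), written as Ensembl-dialect GTF, and locus
sets with a *known* category composition. Loci are drawn category-first:
one multinomial draw fixes the per-category counts, then each locus
midpoint is sampled uniformly within that category's territory and written
as midpoint ± 25 bp (shrunk symmetrically at chromosome edges so the
midpoint is preserved). By construction each locus categorises exactly as
drawn, so pipeline recovery tests measure the categoriser, not generator
noise, and the recovered counts deviate from the target probabilities only
by multinomial sampling error. The default category mix (exon 0.10, intron
0.35, 5' near 0.12, 3' near 0.08, 5' far 0.10, 3' far 0.07, distant 0.18)
is shaped like a transcription-factor ChIP peak set: gene-body heavy with a
promoter-proximal component and an intergenic tail.

What the generator does *not* emulate: overlapping and nested genes
(covered separately by randomised oracle tests), unassembled contigs,
chromosome-scale variation in gene density, peak-width and summit-offset
structure, and any correlation between locus positions. Passing tests
therefore demonstrate correctness of the categorisation and statistics, not
robustness to every artefact of real annotations.

All randomness flows from one explicit integer seed; fixture outputs are
byte-identical across runs with the same spec.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick desk runs: genomes of
2 × 1 Mb, tens of genes, locus sets of 300–2 000, 500–2 000 test
replicates, 200-table oracle sweeps. Statistics use scipy's chi-square and
hypergeometric survival functions and statsmodels' multiple-testing
routines; the flattening and the shortcut statistic are exact integer/float
arithmetic with a single guard clamping tiny negative round-off of chi2 and
G to 0. Degenerate inputs fail loudly: empty distributions, fewer than two
non-empty categories, invalid limits, infeasible generator specs, and
malformed file lines are rejected (files line-wise with logged warnings,
parameters with exceptions).

## Known limitations

- Gene-level categories only; no UTR/CDS or transcript-aware labels.
- Element tracks are reported as per-locus overlap flags, not folded into
  the seven-way partition (their precedence against gene categories is
  undefined).
- The nested-design conservatism described above.
- GO results depend entirely on the supplied mapping and ontology files;
  no evidence-code filtering or GO-slim mapping.
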