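# Methods

This note records the models and procedures behind `syntelink`, the
parameters that matter, the numerical conventions, and what the synthetic
data does and does not establish.

## Sequence identity and homolog clustering

Identity between two gene sequences is defined through an optimal global
alignment with match +1, mismatch −1, gap open −2 (charged on the first
base of a gap) and gap extension −1. Because several alignments can share
the optimal score while differing in matched columns, the dynamic program
maximises lexicographically (score, matches, aligned columns); the reported
identity — matches divided by the shorter sequence length (default) or by
the alignment length — is therefore a well-defined function of the pair,
not of an arbitrary co-optimal traceback. The kernel is a numba-jitted
three-state affine DP with the three objectives packed into one int64 per
cell; sequences up to ~1 Mb fit the field widths.

Clustering is greedy and incremental in the CD-HIT style: sequences sorted
longest-first (ties broken by identifier) each join the *first* existing
cluster whose representative they match at identity ≥ the cutoff, else
found a new cluster. Consequences worth noting: members of one cluster are
each within the cutoff of the representative but not necessarily of each
other, and the partition depends on the scan order, which the sort plus
tie-break makes deterministic. The cutoff default is 0.95, inclusive;
the identity denominator defaults to the shorter sequence, matching the
convention of the greedy-clustering tools this stage emulates.

A candidate prefilter counts shared *k*-mers (default *k* = 8): a pair at
identity *p* over shorter length *L* has at most (1−p)·L mismatches, each
destroying at most *k* of the L−k+1 words, so any pair reaching the cutoff
shares at least L − k·(1−p)·L − k + 1 words. Rejection happens only below
that bound, so the filter can speed clustering up but never change its
output; this admissibility is asserted both directly (random mutated pairs)
and end-to-end (clustering with and without the filter is identical on
small inputs).

## Anchors and synteny blocks

Cross-genome homolog groups fan out into anchors: one per (A-gene, B-gene)
pair, positioned by each gene's 0-based ordinal along its chromosome.
One-to-many groups produce several anchors; the chainer decides which copy
is the syntenic one. An anchor's identity is the smaller of its two
members' identities to the group representative — a cheap lower bound; the
alternative of re-aligning every cross pair would duplicate the clustering
cost without changing any downstream decision at the tested divergences.
Anchors can instead be imported from a precomputed hit table (BLAST-style
TSV), which also carries e-values and coverages for the quality filters.
A filter that is set drops anchors lacking the corresponding attribute;
unset filters pass everything.

Chaining works per chromosome pair in ordinal space. The longest strictly
monotone chain — ordinals rising on both genomes (forward) or rising on A
while falling on B (inverted) — is found by O(n²)
longest-increasing-subsequence dynamic programming, subject to a gap cap:
consecutive anchors may differ by at most `max_gap_genes` ordinals (default
10, i.e. up to 9 intervening genes) on either genome. The best chain is
extracted as a block, its anchors removed, and the search repeats until no
chain reaches `min_block_anchors` (default 3). Ties between equal-length
chains prefer the smaller starting A-ordinal, then forward orientation,
then the lexicographically smallest anchor sequence, making the whole
decomposition byte-deterministic. On ≤ 10-anchor instances the first
extracted chain is verified against an exhaustive subset oracle.

Two behaviours of the greedy decomposition are deliberate and documented
rather than corrected. First, a single anchor at the edge of an inversion
can be absorbed by the surrounding forward chain (its B-ordinal still rises
relative to the flanks), so a planted k-gene inversion typically surfaces
as an inverted block of k−1 anchors; the inversion is still reported as one
inverted block, and no anchor is lost. Second, the forward-before-inverted
tie-break is not mirror-symmetric: reversing B's gene order maps every
chain to an opposite-orientation chain of the same length, and the best
chain length is mirror-invariant, but on instances with an exact
forward/inverted length tie the extraction order may differ between a
genome pair and its mirror.

The window view centers a 0.2 Mbp interval (default) on the target gene's
midpoint, clipped to [1, chromosome length]; the partner region is the
containing block's B-span (the highest-scoring block if several). Genes
overlapping each interval get relative indices …, −1, 0, +1, … by gene
order, with 0 at the target on A and at its anchor partner on B.

## Chromosome pairing and classification

Chromosome correspondence between genomes is not assumed from naming: each
A chromosome is paired with the B chromosome sharing the most block
anchors (ties to the lexicographically smaller name; anchor-free
chromosomes pair with nothing and are logged). The pairing can be
overridden by the caller. Every A gene then receives exactly one category:
`same_chromosome` if any of its group partners lies on the paired
chromosome, `different_chromosome` if it has partners only elsewhere,
`no_homology` if its group contains no B member. `in_synteny` additionally
flags membership in any block. The "significance cutoff" governing what
counts as a homolog is exactly the clustering cutoff plus any anchor
filters applied upstream; no separate statistic is introduced.

Search is exact and case-insensitive on gene IDs *and aliases* (so
transcript or protein identifiers of annotations that use distinct ID
schemes, such as potato's, resolve to their gene), case-insensitive
substring on descriptions, and closed-interval overlap on positions.

## SNP markers

MAF is computed per site over non-missing alleles only (each diploid call
contributes two); missing genotypes leave both numerator and denominator —
the standard complete-case convention, chosen because imputing either way
would bias panels with structured missingness. The MAF is the largest
non-major allele frequency, which for a biallelic site is the second
allele's frequency and is bounded by 0.5; multiallelic sites are retained
and flagged. The marker-pool filter keeps sites with MAF strictly greater
than the threshold (default 0.2) — a site at exactly 0.2 is dropped. The
filter is idempotent and monotone in the threshold, and sub-matrix views
recompute MAF on the selected samples only.

Flanking extraction validates that the reference base at the site equals
the VCF REF, then emits up to `flank_bp` (default 1000) uppercase bases per
side, truncated at chromosome edges, as `LEFT[REF/ALT1(/ALT2…)]RIGHT`.
Gene–SNP association uses the closed gene interval with an optional
flank (default 0: strictly within the gene). Indel records are carried
through the matrix but excluded from marker text by default.

## The simulator

The generator emulates the regime the pipeline targets: two genomes with
nearly identical gene content and order, separated by point divergence and
a small number of structural events. Genome A is uniform random sequence
with single-exon genes of fixed length laid out with fixed intergenic
spacers; genome B copies A's genes, applies per-base substitutions at the
divergence rate (uniform across sites, no transition bias — adequate for
identity-threshold behaviour), then the configured inversions (gene order
and strand reversed in a window), cross-chromosome translocations, gene
losses and tandem duplications, each recorded in a truth object. Planted
windows are disjoint and a translocation never splits a planted inversion,
so each event has an unambiguous expected signature. Defaults — 2
chromosomes × 200 genes of 1 kb, 2% divergence, two 8-gene inversions, one
5-gene translocation — are the conditions at which the planted-truth
acceptance checks run; at 2% divergence and 1 kb genes the probability of
an ortholog pair falling below the 95% cutoff is a negligible binomial
tail, which the suite asserts empirically.

Genotypes are drawn at planted allele frequencies under Hardy–Weinberg
sampling (two independent Bernoulli alleles per sample), with whole
genotypes masked missing at a configurable rate. Real breeding panels —
cultivar collections and RILs — deviate from HWE; an inbred mode (one
allele drawn per sample, doubled) models the fully homozygous RIL limit,
and an exact mode plants `round(2Nf)` alternate alleles so realized
frequencies match planted ones to rounding, which makes filter checks
exact rather than statistical. All randomness flows from one seed, and
emitted FASTA/GFF3/VCF/JSON files are byte-identical across runs.

What passing on synthetic data does *not* show: robustness to fragmented
or mis-annotated gene models, tandem arrays and large gene families (the
simulator plants at most single duplicates), repeat-rich intergenic
sequence, unequal gene lengths, or alignment-free divergence patterns such
as indel-rich evolution. Those affect clustering sensitivity and anchor
fan-out, not the chaining or filtering logic that the planted checks pin
down.

## Published-count arithmetic

The desk-scale consistency check on the published per-crop annotation
summaries divides each crop's homologous-gene count by its gene total:
tomato 22 831/34 727 = 65.7%, potato 34 369/39 028 = 88.06%, Arabidopsis
12 715/35 386 = 35.9%, each reproducing its printed percentage. The pepper
row is arithmetically inconsistent as published (18 554/34 915 = 53.1%
versus a printed 52.1%) and is excluded from the reproduction check. The
combined 17 635-group total was produced from the full multi-gigabase gene
sets and is treated as a non-desk diagnostic: the clustering layer reports
both the all-groups and multi-genome-groups counts needed to compare
against it, but the number itself is not re-derived offline.

## Numerical and degenerate-input conventions

All coordinates are 1-based inclusive (GFF3/VCF convention); any half-open
arithmetic is internal. Empty sequences, duplicate identifiers, REF = ALT
records, sample-less VCFs, all-missing sites (undefined MAF), unknown
chromosomes and unresolvable gene IDs are hard errors; a GFF3 feature
without an ID is skipped with a logged count rather than failing the whole
file. Gene-length ties in catalogs sort by (start, end, gene_id). Problem
sizes in the test suite and acceptance script (tens to hundreds of genes,
10⁴ genotype sites) were chosen as the smallest scales at which every
planted signature is unambiguous.
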