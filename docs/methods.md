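# Methods

This note records the models, conventions and numerical choices behind
`strandqc`, and what the simulation-based validation does and does not
establish about real data.

## Coordinate and format conventions

All internal coordinates are 0-based, half-open. SAM (1-based) and GTF
(1-based, end-inclusive) are converted once at the parsing boundary.
Only CIGAR operations M, I, D, N and S are accepted; hard clips and
padding are rejected with an explicit error rather than silently skipped,
because a silently mishandled clip would corrupt mismatch and coverage
accounting. Unmapped reads retain sequence and qualities so the spike-in
path can run from a single alignment file.

## Library orientation

`orientation` describes how the strand of the originating RNA fragment is
inferred from flags:

* `reverse` (default): dUTP second-strand chemistry — the first-in-pair
  read maps antisense to the transcript, the second-in-pair maps sense.
* `forward`: the mirror image.
* `unstranded`: no inference possible; strand-specificity is reported as
  null.

## Strand-specificity

Per junction, sense and antisense spanning-read counts are accumulated;
the statistic is the fraction of junctions with zero antisense reads.
Two choices deserve justification:

* **Junction matching is exact**: an N-skip counts only when both skip
  coordinates equal an annotated intron and the flanking M blocks each
  cover at least `min_overhang` (default 3) reference bases. This is the
  strictest reading of "reads spanning exon–exon junctions" and avoids
  crediting misaligned skips or genomic-DNA background. The overhang
  default suppresses 1–2-base spurious flanks; it is configurable.
* **The denominator is the set of observed junctions** (those with at
  least one spanning read). Over *all* annotated junctions the statistic
  would reward shallow libraries, since unobserved junctions trivially
  have zero antisense reads; restricting to observed junctions makes it
  depth-robust. The literal all-junctions variant is available via
  `literal_denominator=True`.

Because strand is derived from flags, not sequence, substitution errors
cannot move this statistic — a property the test suite checks explicitly.

## Read classification and expression

A read is classified by majority of its aligned (M) reference bases:
exonic if ≥50% fall in the merged exon union, else intronic if ≥50% fall
within a gene span, else intergenic. The precedence order makes the rule
deterministic for boundary reads. A read is assigned to a gene only when
all of its exon-overlapping bases belong to that single gene; reads
shared between genes are counted in the category percentages but excluded
from expression, preventing double counting. Expression is RPKM over the
per-gene exon-union length; cross-library correlation uses Pearson r of
log2(RPKM + 0.1) over genes detected in at least one library. The 0.1
pseudocount keeps undetected genes finite; at shallow depth the
detection boundary (0 ↔ 1 read) dominates the correlation, which is why
replicate-concordance checks are run at depth.

## Duplicate marking and down-sampling

The fragment key is (contig, unclipped 5′ position, strand) of each
mapped mate, with soft clips backed out, read1 first; the fragment with
the highest summed base quality survives, ties broken by query name.
Optical-duplicate detection is omitted (synthetic names carry no tile
coordinates). Fragments with no mapped mate cannot be coordinate-keyed
and are excluded from the rate.

Down-sampling selects an exact number of distinct fragment names
uniformly, keeping mates together, from a seeded generator. The default
stage order is down-sample, then mark: the duplicate rate is
depth-dependent (a duplicate is only detectable when its coordinate twin
is also sampled), so depth-matched comparisons must re-mark after
down-sampling. The reverse order is available behind a flag; the test
suite demonstrates the systematic gap between the two.

## Coverage bias

Per gene, only the longest transcript contributes (shared exons would
otherwise be double-counted). Eligible transcripts (spliced length ≥ 500,
mean exonic coverage ≥ 5 by default) are mean-normalized, rebinned to 100
bins, and averaged; the 5′/3′ ratio is the mean of bins 1–20 over bins
81–100. The 20% windows are a stability compromise: narrower windows are
noisier at moderate depth, wider ones dilute end effects. Per-transcript
normalization stops highly expressed transcripts from dominating the
profile. Near transcript ends coverage ramps over roughly a fragment
length because fragments must fit inside the transcript; the effect is
symmetric and cancels in the ratio for unbiased libraries, but it adds
variance at low eligibility thresholds — the unbiased-ratio band
[0.9, 1.1] is therefore asserted at ≥50× mean coverage.

## Error rates and the spike-in analysis

Base error rates count substitutions only, over M-operation bases with
base quality ≥ `min_baseq` (default 0), excluding soft-clipped, inserted,
deleted and N-skipped bases and reference N positions from both numerator
and denominator. Known-variant positions can be excluded via a BED mask
instead of calling variants: the statistic is used for *relative*
comparisons between libraries, where the SNP contribution is a shared
offset. Indels are not profiled.

The spike-in pool is every pair with at least one unmapped mate. The
panel matcher is a gapless seed-and-extend aligner: an exact 20-mer
shared with a panel sequence (either orientation) anchors a full-read
ungapped extension; the read is assigned to the highest-identity panel
member subject to identity ≥ 0.95 and span ≥ 90% of the read, ties broken
by span then id. With 92 random panel sequences a 20-mer collision is
negligible, and the simulator emits substitutions only, so a gapless
matcher is exact for the data it is validated on. Dose-response is the
Pearson correlation of log2 observed abundance (assigned reads per
kilobase) against log2 expected concentration over detected members.
Because only detected members enter, no pseudocount is needed; the
default of 0 keeps a perfectly proportional input at r = 1 exactly, and a
`"half_min"` option (half the smallest nonzero abundance) is provided for
users who want shrinkage at very low counts.

## Insert sizes

Estimated from proper pairs on the mitochondrial contig — deeply covered
and unspliced, so the outer template length is the fragment length
without splicing artifacts. Pairs with an N operation, zero template
length or template length above `max_insert` (default 2000) are excluded;
the insert is taken once per pair from the leftmost mate. The standard
deviation uses the n−1 denominator.

## The simulator

The generator emulates a dUTP-chemistry paired-end library on a toy
genome and is the package's validation instrument. Defaults were chosen
once, as the study conditions for all recovery tests:

| parameter | default | rationale |
|---|---|---|
| genes / exons / exon length / intron length | 300 / 2–6 / 150–400 nt / 200–800 nt | compact spliced transcriptome; at 20k fragments the per-junction spanning depth is moderate (~5–10×), which keeps the junction statistic informative across contamination rates rather than saturating |
| read length | 75 nt | paired-end 75 chemistry |
| fragment length | Normal(300, 30), truncated to [read length, template length] | a 280–400 bp size-selected library |
| expression | log-normal weights, σ = 1 | a realistic dynamic range without making most genes undetectable at desk-scale depth |
| category fractions | rRNA 2%, mitochondrial 5%, intronic 15%, intergenic 3%, spike-in 3%, remainder exonic | a well-behaved poly(A) library |
| spike-in panel | 92 members, lengths 250–2000 nt, concentrations log-uniform over 4 decades | the standard synthetic-RNA panel geometry |
| PCR duplication | 1 + Geometric extra copies, mean `duplication_mean_extra` | a single-parameter duplication knob; each copy gets fresh substitutions and qualities |
| 3′ bias | fragment starts weighted ∝ exp(b·x) along the transcript, b = `three_prime_bias` | 0 is exactly uniform; the exponential gives a smooth, monotone dial |

Reads are emitted as already-aligned records with correct spliced CIGARs
(mapping is not under study); spike-in fragments are emitted as unmapped
pairs, a configurable fraction with exactly one mapped (genomic) mate so
the pool-extraction rule is exercised on both its branches. Substitutions
are i.i.d. per emitted read copy; antisense contamination flips the
fragment's RNA strand, which under the configured chemistry swaps the
read1/read2 roles without moving coordinates. Expression weights can be
pinned across libraries (`expression_seed`) to simulate technical
replicates from one expression truth. Everything is drawn from seeded
generators: identical configs give byte-identical output files.

What the simulator deliberately does not model: sequencing-quality
structure, indels, GC or hexamer-priming bias, alignment errors,
multimapping, overlapping genes and isoform mixtures. Recovery tests
therefore validate the *estimators* — that each metric measures its
generative parameter correctly under the stated model — not robustness of
those estimators to artefacts the model excludes. On real libraries the
absolute values of, e.g., the 5′/3′ ratio depend on definition details
that differ between in-house tools, so cross-tool comparisons should be
made on trends, not absolute values.

## Validation design

Every metric is validated two ways: parameter recovery against the
simulator's truth records (exact for degenerate settings, binomial or
sampling-theory intervals for stochastic ones), and a dual-route
equivalence check in which an independent brute-force script — plain
text parsing, sorted lists, no shared code — recomputes the whole scalar
report from the written SAM/GTF/FASTA files and must agree exactly on
every deterministic quantity. Problem sizes in the test suite (2k–20k
fragments, 40–300 genes) were chosen so the full validation runs in a
couple of minutes on a single CPU while keeping each statistical check
comfortably powered.
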