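# Methods

This note documents the models and procedures behind `plantrrbs`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot demonstrate.

## Reduced representation by double digestion

A cut-site specification is an IUPAC recognition pattern with a dash at
the cut position (`C-CGG`, `-GATC`, `G-CWGC`). Digestion is modelled as
complete: every occurrence of every pattern is cut, overlapping matches
included, and fragments are the intervals between consecutive pooled cut
positions on a contig. Choices behind this model:

- **Forward-strand scan.** The three enzymes relevant here recognize
  degenerate palindromes (CCGG, GATC, GCWGC), so scanning the reverse
  strand adds nothing. Non-palindromic patterns are nevertheless
  supported: the reverse-complement pattern is scanned with the mirrored
  cut offset.
- **Blunt coordinates.** The cut coordinate is recognition start plus
  cut offset on the forward strand. The double-stranded stagger left by
  the enzyme is ignored because end repair blunts fragment ends before
  ligation; for coverage accounting the distinction is immaterial.
- **Terminal segments** (before the first and after the last cut of a
  contig) carry only one ligatable end and are excluded by default
  (`include_terminal` restores them).
- **Size selection** keeps fragments with length in `[min_len, max_len]`
  *inclusive*, defaults 150 and 420 bp — the insert range a paired-end
  library would be size-selected to.
- **Coverage denominator** is the full reference length including N
  bases, so percentages are relative to the nominal genome size.
- Whether a fragment must derive from two *different* enzymes is not
  constrained: any adjacent pair of cuts forms a fragment.

## Synthetic data generator

The generator emulates a directional (methylated-adapter) bisulfite
protocol on a reduced representation:

- **Genome**: i.i.d. random nucleotides at a configurable GC content
  (default 0.43, rice-like). Restriction sites then occur at their
  binomial background densities, giving realistic fragment-length
  distributions without repeat structure.
- **Contexts**: every cytosine on both strands is CG, CHG or CHH
  (H = A/T/C). Positions whose downstream bases run off the contig or hit
  an N — and that are not already CG — are excluded rather than guessed.
- **Truth**: one Bernoulli draw per cytosine from its context probability
  (defaults CG 0.7, CHG 0.4, CHH 0.05, the high-CG/moderate-CHG/sparse-CHH
  ordering typical of cereal methylomes), with optional per-position
  overrides. The methylation state is a fixed 0/1 property of a position,
  not a per-read rate — so a deeply covered position has a level near 0
  or 1, and *population-level* probabilities appear only as averages over
  positions. An epiline is derived by redrawing states inside chosen
  regions at a new probability.
- **Conversion control**: a dedicated contig whose cytosines are forced
  unmethylated stands in for the chloroplast genome; it carries its own
  cut sites simply because it is random sequence, so it enters the
  reduced representation and its pooled level estimates conversion
  failure.
- **Reads**: per fragment the copy number is Poisson(`mean_depth`,
  default 30); each copy derives from the original top or bottom strand
  with probability 0.5; unmethylated C reads as T with probability
  `conversion_efficiency` (default 0.99), methylated C as T with
  `inappropriate_conversion` (default 0); read 1 is the first `read_len`
  (default 50) nucleotides of the converted strand, read 2 the reverse
  complement of its last `read_len`; substitution errors are applied per
  base; qualities are constant Q40.

Not emulated: PCR duplicates (real libraries showed well under 1% and
ignored them), indels, adapter read-through, quality decay,
bisulfite-induced fragmentation, repeat structure and satellite DNA, and
methylation-sensitive or partial digestion. Consequently, passing tests
demonstrate the *computational* chain is correct and self-consistent;
they say nothing about coverage percentages on real genomes, which
depend on repeat content and lab-step efficiencies.

## Alignment

Because RRBS inserts are fragment-sized and begin at cut sites, the
aligner indexes only the digestion fragments (size-unfiltered by
default — size selection already happened upstream, and mapping should
not re-filter), each in two converted spaces: C→T (original top strand)
and G→A (original bottom strand). The 20-mers at the fragment ends form
the seed table; a pair is aligned by exact-seeding read 1 (C→T
converted) and read 2 (G→A converted) at opposite fragment ends and
counting mismatches in converted space over the full reads. Acceptance
requires: both mates on the same fragment in proper orientation, at most
2 mismatches per mate, fragment length at most 500 bp (the insert
ceiling), and a unique best-scoring location — ties are dropped as
ambiguous, mirroring unique-mapping practice. Preprocessing first
truncates reads to a uniform 50 nt, trims 3′ bases below Q20 and drops
pairs with a mate shorter than 20 nt.

Only substitutions are modelled (no gapped or local alignment, no
mapping-quality model). Overlapping mate spans are clipped after
alignment — mate 2 keeps only sub-intervals outside mate 1 — so a pair
never contributes twice to a pileup position.

## Calling

Positions are strand-specific throughout: "+" calls sit on reference Cs
and collect C/T evidence from top-strand molecules, "−" calls on
reference Gs collect G/A evidence from bottom-strand molecules; the two
strands of a CG pair are never merged, matching both-strand totals in
the reported statistics. Any other observed base is non-informative.
Levels are Ci/(Ci+Ti); the call floor is 10 informative nucleotides.
Sequencing errors at cytosine positions create informative miscalls
(C↔T) and are accepted as-is; no base-quality filter is applied beyond
preprocessing. Call files are CGmap-like TSVs, 1-based on disk and
0-based in memory with conversion at the I/O boundary.

## Replicate statistics

Position identity is the strand-specific key (contig, position, strand).
Union, intersection and Jaccard (= 100·|∩|/|∪|) are computed per context
over replicate position sets. Intra-line homogeneity counts intersection
positions whose max−min replicate level spread is *strictly* below the
25-point threshold. Percentages are reported to one decimal; internal
values keep full precision. The genome-wide cytosine denominator is the
C+G count of the FASTA unless a published constant is supplied for table
replication.

## Differential methylation

The unite step inner-joins all replicates of both lines at positions
reaching the 10-informative floor in *every* replicate. Coverage is then
median-normalized: each replicate's counts are scaled by (median of all
replicates' median depths) / (own median depth), rounded half-up, with
the guard that a covered position keeps at least one count; levels are
preserved to within rounding. With a single sample there is nothing to
normalize and the matrix passes through unchanged.

Counts are pooled per line (ΣCi/Σ(Ci+Ti), not the mean of per-replicate
levels) and each position is tested with a two-sided Fisher exact test,
defined as the sum of hypergeometric probabilities (margins fixed) of
all tables at most as probable as the observed one. The implementation
enumerates with exact integer weights C(r₁,k)·C(r₂,K−k), so tied table
probabilities need no floating-point tolerance; the test suite checks it
against an independent rational-arithmetic oracle and against exhaustive
library enumeration for all tables with row margins ≤ 30 (agreement
< 1e-12).

Multiple testing uses Benjamini–Hochberg. The upstream method used the
SLIM q-value estimator inside methylKit; its algorithm is not specified
by our sources, so the standard, conservative BH procedure is used and
exposed as a config switch (`adjust`) should another estimator be added.
A DMC must satisfy q < 0.01 **and** |Δ| > 25 points (both strict);
"hypo" means the epiline is lower. Because the simulator's truth is a
per-position 0/1 state, a region redrawn from probability 0.9 to 0.1
changes the state of ~82% of its positions; power is therefore measured
over the positions whose state actually changed (≈99% of changed CG
positions are recovered at depth 30 with 5 replicates per line), and the
pooled level difference over a whole region averages ≈80 points.

## Annotation

GFF3 is 1-based inclusive on disk, converted to 0-based half-open at the
parser boundary. Genes are protein-coding vs non-coding by their
`biotype` attribute, falling back to the presence of CDS children.
Introns are the gaps between consecutive exons within the transcript
span. Promoters are the 2000 nt upstream of the TSS, strand-aware and
clipped at contig bounds but *not* at neighbouring gene boundaries (the
convention is a fixed window). A position keeps every overlapping label;
when it lies in both a non-coding and a protein-coding gene the shared
child labels (transcript, exon, CDS) are discarded — except intron,
always retained — so protein-coding feature counts are not inflated by
identical non-coding children. In category summaries a position may be
counted several times; "promoter" is reported inside the not-annotated
superset, a deliberately literal (if counterintuitive) reporting
convention. Level histograms use ten 10%-bins with the top bin closed so
a level of exactly 1 is representable.

## Pipeline

The `run` command derives fixed per-stage, per-replicate seeds from one
global seed (`stage_seed`), so any stage can be reproduced in isolation
and a rerun is byte-identical. Stages communicate only through their
documented file formats (BED, FASTQ, TSV, GFF3, JSON), so any stage is
replaceable by an external tool producing the same format. A failing
stage aborts with the stage named; partial outputs are retained.

## Problem sizes

The bundled checks run on deliberately small instances chosen to make
the statistics decisive while keeping runs quick: 50-kb genomes with an
8-kb control contig and the size window widened to [40, 420] bp so that
toy-scale fragments survive selection (~7,000 read pairs at mean depth
30); 26-kb genomes with 5 replicates per line (~10,000 united positions)
for the differential tests; 200 random genomes up to 5 kb for the
digestion oracle; all 2×2 tables with row margins ≤ 30 for the exact
test. Published coverage percentages for real reference genomes
(e.g. ~37%/25% in silico coverage for rice with the two enzyme
combinations), read-data-derived table counts and the 96.8% intra-line
homogeneity figure require the real genome and sequencing data and are
not reproduced here; the corresponding operations are instead verified
by the oracle and round-trip suites above.

## Known limitations

- The aligner assumes reads anchor at fragment ends; arbitrarily
  positioned reads (as WGBS would produce) are out of scope.
- Whole-genome bisulfite alignment is not implemented; WGBS-derived call
  files are accepted by the downstream statistics.
- No DMR (region-level) aggregation, logistic-regression testing,
  overdispersion correction, SNP-aware calling or per-position binomial
  state testing.
- Transposable elements are absent from both the synthetic annotation
  and the feature vocabulary.
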