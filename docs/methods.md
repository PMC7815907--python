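# Methods

This note records the models, conventions and numerical choices behind
`isodie`, in the order data flows through the package.

## Coordinates and identities

All internal coordinates are 0-based half-open; GTF input/output converts
at the boundary. An intron is `(donor, acceptor)` = (first intronic base,
one past the last); biological donor/acceptor roles follow the annotated
strand, and motif checks reverse-complement on the minus strand. An isoform
identity is the triple (TSS peak id, exact intron chain, polyA peak id).
Peak ids rather than raw end coordinates are used so that end wobble within
the 50 bp completeness window does not fragment one isoform into many; a
raw-coordinate mode would only change the granularity of TSS/polyA tests,
not the splice-structure tests, and was not needed.

## The CSMM filter cascade

Filters run in a fixed order — alignment selection, rRNA overlap, spliced
check, splice-motif consensus, gene assignment, end completeness, barcode
deconvolution — and every read is accounted to exactly one fate, so the
stage tallies always sum to the input. Choices within stages:

- *Alignment selection*: a single alignment needs mapq ≥ 20; with several,
  the best must outscore the runner-up by ≥ 20, otherwise the read is
  dropped as ambiguous.
- *Consensus*: every intron must read GT‑AG, GC‑AG or AT‑AC after strand
  correction; one bad intron disqualifies the molecule. Unspliced reads are
  excluded (the pipeline quantifies spliced isoforms).
- *Gene assignment* counts annotated splice sites shared per gene and keeps
  the argmax set. Ties are dropped by default to avoid double counting in
  the statistics; `drop_ambiguous=False` restores once-per-tied-gene
  counting for users who prefer completeness over strict independence.
- *Completeness*: distance from a read end to a peak is 0 inside the
  interval, else the gap to the nearest boundary; ties resolve to the more
  5′ peak for the TSS and the more 3′ peak for the polyA site. The window
  is 50 bp, configurable.
- *Deconvolution* is exact barcode lookup (error correction is assumed
  upstream); unmapped barcodes stay in bulk-level analyses only.
- Read strand is taken from the assigned gene, never inferred from the
  alignment flag alone.
- rRNA genes are flagged by transcript/gene biotype `rRNA` plus a
  configurable gene-name regex (default `"rRNA"`), since annotations differ
  in how they mark them.

## Differential usage tests

The gene-level test compares isoform counts between two cell groups. Genes
need ≥ 25 reads in **each** group ("25 reads per gene per category");
counts collapse to at most 11 × 2 (ten most abundant isoforms by pooled
count, ties broken by canonical string order, plus a remainder row that
preserves column sums) before a Pearson χ² with no continuity correction
and df = rows − 1. All-zero rows are dropped; fewer than two surviving
rows, or an empty column, makes the gene untestable.

ΔΠ is computed on the *uncollapsed* per-isoform Π vectors: per-isoform
δ = Π_A − Π_B, the positive candidate sums the two largest positive δ, the
negative candidate the two most negative, and the larger magnitude wins
with its sign and contributing isoforms. Note the constraint Σδ = 0: for a
pure swap of two isoforms the two directions tie exactly, so the reported
sign is a labeling convention, not biology (ties return the positive
direction). TSS and polyA tests aggregate the same tables by peak id and
reuse the machinery.

BH (gene-level families, independent tests) and BY (exon-level, dependent)
are standard step-ups, written here so the per-feature correction factor
adjusted/raw can be reported *before* clamping at 1; tests cross-check both
against statsmodels on random vectors. Each pairwise comparison is
corrected as its own family.

Exon calls: an internal exon is included when the read has an intron
acceptor within ± tol of the exon start *and* an intron donor within ± tol
of the exon end (tol = 2 bp PacBio, 3 bp ONT, reflecting residual alignment
error around junctions); a read whose alignment span covers the exon
without such junctions excludes it — this deliberately counts both
exon-skipping and junction-mismatch/intron-retention reads as exclusion,
which is the convention the 2 × 2 test assumes; a read ending inside the
exon is uninformative. Terminal exons use coverage instead: included only
when completely covered, spanned-by-intron excludes, partial coverage is
discarded. Exon tests require pooled Ψ in [0.1, 0.9] (else constitutive)
and min(rowSums)·min(colSums)/Total ≥ 5 on the 2 × 2 table.

## Attribution through the hierarchy

For a gene significant at a parent node, each of the two children
"participates" when it is testable, |ΔΠ| ≥ 0.1, and its sign matches the
parent's: both → Both-Cell-Types, one → Single-Cell-Type, none with both
testable → No-Cell-Type (expression/abundance shifts only), otherwise
insufficient depth. Ratios ΔΠ_child/ΔΠ_parent are emitted on magnitudes
with matched sign (an opposite-sign child never "explains" its parent) and
are undefined at ΔΠ_parent = 0.

Because a symmetric swap has no intrinsic ΔΠ sign (see above), comparing
independently estimated parent and child scalars would randomize the sign
match. The workflow therefore projects the child's per-isoform Π changes
onto the *parent's* contributing isoforms (`directed_delta_pi`) before
classification; this fixes a common direction and makes the ratios
well-defined. With this projection, planting DIE in exactly one child is
recovered as Single-Cell-Type in ≥ 99 % of genes at depth 500 per child
per region; at depth 100 the limit is statistical, not algorithmic — a
truly null child's ΔΠ estimate (SD ≈ 0.12) crosses the 0.1 participation
threshold by noise alone in roughly a sixth of genes, so no estimator can
reach 99 % there.

Concurrence between two sibling groups is a 2 × 2 Fisher exact test over
genes testable in both, observed joint-hit percentage vs the product of
the marginals. TSS directionality reports both the exact binomial point
probability C(n, k)·0.5ⁿ and the one-sided tail, since summary statistics
of this kind are quoted both ways; upstream is strand-aware.

## Novel isoforms

Candidates are complete spliced CSMM chains absent from the annotation.
"Truncated version" is formalized as *contiguous subsequence* of an intron
chain — internal deletions are novel, missing flanking introns are
truncations. Rules apply in order (novelty; internal-exon support; intron
support; non-redundancy against longer novel chains) and a rejection
carries the first failed rule. Both support rules read the same short-read
junction table (chrom, intron_start, intron_end, strand, unique_count);
internal-exon support means both flanking junctions ≥ 2, so it can only
fail where an intron flanks an internal exon — weak terminal-adjacent
introns of two-exon chains surface as the intron-support rule instead.
Accepted isoforms take their genomic extent from the modal read span and
are written with source tag `isodie_novel`.

## Spatial concordance

Exons flagged as overlapping alternative donor/acceptor variants are only
comparable across platforms when strictly more than 90 % of reads
overlapping the exon map to that exact exon. Concordance counts strict
same-sign ΔΨ pairs (zero counts as discordant — a conservative choice for
a directional claim), reports the exact binomial point probability at
chance 0.5, and the Pearson r of the paired ΔΨ. A `min_abs_dpsi` floor is
available because very small ΔΨ carry no reliable direction.

## The synthetic generator

Each simulated gene has six exons; isoform 0 uses all of them and isoform
k skips internal exon k, so isoforms differ by single cassette exons and
each gene exposes one Ψ-shifting exon per non-reference isoform. Reads are
drawn multinomially per (gene, region, cell type) from a Π vector (default
(0.5, 0.2, 0.2, 0.1), four isoforms); differential usage is planted by
swapping the two major isoforms in the second region for chosen cell
types, giving a true top-two ΔΠ equal to Π₀ − Π₁ = 0.3. The default
fixture is 50 genes × 4 cell types × 2 regions at depth 60, which runs in
seconds; calibration runs scale to 1000 genes at depth 100 per region.
Outputs are byte-identical for identical seeds.

Corruptions model specific failure modes, each with a known expected fate
recorded in the truth ledger: splice-motif corruption shifts one donor
into intron interior sequence (fails the consensus filter), 5′ truncation
removes the first intron and read start (fails completeness), and bounded
junction wobble models residual misalignment — wobbled junctions land off
the genomic motifs and are removed by the consensus filter, exactly as
misaligned junctions are in real data. Because of that, full-pipeline
recovery tests run at wobble 0, and the ± 2/± 3 bp tolerance behavior is
tested directly at the exon-call level where the tolerance is defined.
The generator does not model sequencing error in base space, chimeras,
barcode errors, or non-uniform coverage; passing tests therefore certify
the statistics and bookkeeping, not robustness to upstream alignment
artifacts.

Novel-isoform scenarios plant one chain per rule in the first four genes
(merged-intron chains absent from the annotation, a truncation of an
annotated chain with its own CAGE peak so it survives completeness, weak
short-read support variants, and a truncation of another novel chain), so
discovery must reproduce the accept/reject pattern exactly.

The truth ledger records every read's gene, cell type, isoform and
expected filter fate; expected exon counts are derived structurally from
isoform membership (an exon at a read edge that is internal in the
annotation counts as excluded, mirroring the junction rule's view of a 5′
truncated molecule), independently of the caller's junction arithmetic.

## Problem sizes and tolerances

Calibration checks use: type-I error on 1000 null genes at depth 100 per
region (accept [0.03, 0.07] at nominal 0.05); power ≥ 0.8 over 500 planted
replicates at depth 100 and monotone over depths 25–200; Π recovery exact
(equality of identical integer ratios) in the zero-noise limit; CSMM pass
rate within 3 binomial SEs of the planted corruption rate; Ψ recovery
within 3 binomial SEs for ≥ 97 % of exons under within-tolerance wobble.
Chi-square p-values match the closed-form Pearson statistic to 1e-9
relative error; Fisher p-values match hypergeometric enumeration; BH/BY
match an independent step-up reference to 1e-12.
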