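# Methods

This note documents the models, rules and numerical choices behind
`exonpipe`, and what the synthetic cohorts do and do not establish.

## Coordinates, annotation and phases

Internal coordinates are 0-based half-open; GTF I/O converts at the file
boundary (1-based inclusive). Exons are deduplicated by
(chrom, start, end, strand) so exon-level counting sees one record per
genomic exon; the annotation's `exon_id` is kept when present.

Phases are computed per transcript from CDS features: the first coding
exon starts at phase 0, each exon's end phase is the cumulative CDS
length mod 3, and the next coding exon starts at the previous end phase.
A transcript whose CDS length is not a multiple of 3 is flagged
frame-inconsistent and contributes no phases; UTR-only exons keep
undefined phases and never enter phase-based junction pairing. When
several frame-consistent transcripts cover the same exon, the first in
sorted id order assigns its phases (generated annotations always agree).

## Aligner

The contract is: report *all* ungapped alignments of an L-nt read with at
most m substitutions (defaults L = 36, m = 2). Pigeonhole seeding with
k = ⌊L/(m+1)⌋ = 12 guarantees completeness: with ≤ m mismatches at least
one of the m + 1 disjoint k-mers is exact. Candidate diagonals from exact
k-mer lookup are verified by full Hamming comparison, deduplicated, and
ordered deterministically by (read, reference, offset). `N` never
matches (it always costs a mismatch); reads with more than m Ns are
discarded since no alignment could satisfy the bound. Transcript and
junction references are sense-strand only; the genome stage aligns both
orientations. The test suite asserts equivalence with an exhaustive
Hamming-scan oracle on random reads.

Hierarchical alignment consumes each read at the first stage with ≥ 1
hit: gene level uses [transcriptome]; exon level uses
[genome → known junctions → novel junctions].

## Counting and units

* Gene level: pass 1 counts uniquely mapped reads per transcript; pass 2
  assigns each multiread to its hit transcript with the highest pass-1
  count, ties to the lexicographically smallest id. Gene count = sum over
  its transcripts; per-sample gene counts always sum to the aligned read
  count (asserted).
* Exon level: a genome-stage read with ≤ 30 total alignment hits adds one
  count to every exon it overlaps (≥ 1 nt overlap; 36-nt reads make a
  minimum overlap unnecessary); beyond 30 hits the read is discarded as
  repeat-derived. The threshold is interpreted on total alignment hits
  (the alternative exon-overlap reading differs only for reads straddling
  many exons and is not implemented as a separate mode). A junction read
  adds one count to the donor and one to the acceptor exon.
* RPKM divides by feature length and total mapped reads of the sample's
  own pipeline. The gene length is the per-sample major (highest-count)
  transcript's length, consistent with the assign-to-most-abundant rule;
  union-exon length is available behind `length_mode="union"`. Junction
  expression uses tags per million (count·10⁶/total), the historical
  junction unit, not the modern transcripts-per-million.

## Junction databases

Known junctions: one record per adjacent exon pair in any transcript,
deduplicated across transcripts within a gene. Novel candidates: ordered
within-gene coding exon pairs (donor before acceptor in transcription
order), unannotated as adjacencies, with donor end phase equal to
acceptor start phase — exactly the condition under which splicing the two
exons together preserves the reading frame. Any unannotated in-phase
ordered pair qualifies; skipping at least one exon is not additionally
required. Inter-gene (fusion) junctions are out of scope.

Flanks are read_length − min_overhang per side (28 nt for 36/8),
truncated to the exon when shorter: the minimal sequence such that every
read satisfying the two-sided ≥ 8-nt overhang rule aligns fully inside
the junction sequence. The 8 is inclusive. For full 28+28 flanks exactly
L − 2·8 + 1 = 21 read start offsets satisfy the rule.

## Differential testing

Tests run on log2(RPKM + 1); the log stabilizes the t-test across the
expression range and the pseudocount only protects zeros
(`log_transform=False` gives raw-RPKM mode). Per feature:

* paired t: t = mean(d)/(sd(d)/√n), df = n − 1, two-sided. Zero-variance
  differences give (0, 1) at zero mean and (±∞, 0) with a warning
  otherwise.
* exact Wilcoxon signed-rank: zeros dropped, average ranks for tied |d|,
  the null of W⁺ built by dynamic programming over doubled (hence
  integer) ranks — equivalent to full 2ⁿ enumeration but O(n²·max-sum);
  exact for n ≤ 25. Two-sided p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))).
  With n pairs below 6 the smallest attainable two-sided p (2/2ⁿ⁻¹·…)
  exceeds 0.05, so cohorts need ≥ 6 pairs for any call at α = 0.05.
* significance: t p < α AND Wilcoxon p < α AND BH-FDR ≤ 0.05 on the t
  p-values. The third criterion is a stand-in for an external
  count-model FDR; `external_fdr=` accepts a per-feature q table to
  reproduce a three-way conjunction with such a package. The conjunction
  (not union) of criteria is used.

Fold changes are computed from condition-pooled counts,
log2(ΣT/ΣNT), with a 0.5 pseudocount substituted only for zero pools so
nonzero ratios stay exact; the MA "concentration" axis is the sum of the
feature's raw count fractions in the two pooled conditions, and features
with a zero pool on either side carry a flag (plotted as their own class
by convention). Pearson correlations between samples are computed on
log2(RPKM + 1); constant samples yield missing values.

## Pattern classification

Formalizing what is usually judged from coverage plots: an exon is
expressed when mean RPKM exceeds a floor (default 1) in ≥ 1 condition.
Among expressed exons with ≥ 1 DEE: both directions present → pattern 3;
all expressed exons DEE (one direction) → pattern 1; otherwise
pattern 2. The all-exons rule for pattern 1 is one explicit formalization
of an empirical distinction; `pattern1_fraction=0.9` relaxes it for noisy
data. The exon-ratio contrast (per-sample log2 ratio of two exons,
compared between conditions by the paired t) cancels gene-level shifts,
so it is flat for pattern-1 genes and shifted for isoform switches;
samples with a zero numerator or denominator are excluded and counted.

## Synthetic cohorts: what they emulate

Defaults describe a paired study of 10 patients, 36-nt single-end reads,
200k reads per sample over a 150-gene mini genome (4–10 exons per gene,
90–240 nt exons, random strands). Exon lengths are arbitrary — not
multiples of 3 — so boundary phases take all three values and the phase
filter is non-trivial; every transcript's total CDS and every planted
skip block is padded to a multiple of 3, making the skip-flanking exons
phase-compatible by construction.

Expression: gene baselines are log-normal (log2 mean 5, sd 1.5);
patient effects (log2 sd 0.5) are shared within a pair, inducing the
pairing the tests exploit; samples add log2 sd 0.15 noise and tumor
samples an extra 0.2. Reads are drawn multinomially with weight
abundance × (transcript length − L + 1), positions uniform, and
independent per-base substitution errors (0.5%); counts are therefore
overdispersed (negative-binomial-like) without committing to a specific
count model.

Planted effects:

* 8% of genes are DEGs at |log2FC| = 2, directions alternating;
* pattern-2 genes carry two annotated isoforms, one lacking an exon
  block; only the skip isoform rises in tumor (shared exons up, block
  flat);
* pattern-3 genes have mutually exclusive exon blocks whose isoform
  shares switch (0.7/0.3 → 0.3/0.7) at constant gene output;
* novel-skip genes (the exon 6–8 archetype) express an *unannotated*
  in-frame skip isoform only in tumor (inclusion 1.0 by default).

Three deliberate design choices keep the cohort statistically honest:

1. **Output balance.** Multinomial sampling is compositional: planted
   up-shifts would depress every null gene's count expectation. Baselines
   of down-shifted genes are scaled so planted shifts cancel exactly in
   expected total *read yield* (length-weighted, including the
   unannotated skip isoform) — biologically, tumor-down genes are the
   highly expressed normal-tissue genes. The truth table records each
   gene's expected read-level log2FC (e.g. a tumor-only skip isoform is
   ~30% shorter and genuinely yields ~0.5 log2 fewer gene-level reads).
2. **Mid-range planted genes.** Planted-effect genes draw baselines with
   narrow spread (sd 0.5) so recovery measures the effect, not the luck
   of an extreme baseline, and no single compensating gene dominates
   cohort output. Skip genes sit 1.5 log2 units above the mean so the
   junction is covered by thousands of reads per sample (miss
   probability per tumor sample far below 10⁻⁶).
3. **Moderate tumor heterogeneity.** Under share normalization,
   log-normal heterogeneity biases every gene's log-share by
   −(σ²_T − σ²_N)·ln2/2; at the historical tumor-vs-normal variance gap
   this is indistinguishable from signal for a paired t on RPKM. The
   default keeps the gap moderate (0.2 vs 0.15 extra log2 sd, preserving
   the expected ordering NT–NT > T–T > T–NT of mean sample correlations);
   analyses of the correlation contrast configure a larger gap
   explicitly.

What passing recovery tests does **not** show about real data: no indel
or quality structure, no fragmentation/GC/positional bias, no unannotated
transcription outside the planted skips, genes do not overlap, and the
mini genome lacks repeats — so multiread pressure is far below real
genomes and the ≤ 30-hit rule is exercised mainly by dedicated fixtures.

## Saturation analysis

The raw-read pool (not the mapped reads) of one sample is aligned once;
each bin is a without-replacement draw of raw reads, and a gene counts as
detected when ≥ 1 sampled read hits it. Since alignment is per-read
deterministic this equals aligning the sampled bins. Three replicates
per bin by default (seeds seed+replicate). The Monte-Carlo curve is
checked against the occupancy expectation Σ_g (1 − (1 − p_g)ⁿ) with p_g
estimated from the full pool; the formula is the with-replacement
approximation, accurate here because every expressed gene has many pool
reads and the bins are large.

## Numerical and reporting conventions

Printed percentages round half-up (Decimal arithmetic), so a reported
figure is always recomputable from its numerator and denominator.
Deterministic tie-breaks everywhere (lexicographic ids, stable sorts);
all randomness flows from explicit integer seeds via SeedSequence
spawning, and identical config + seed reproduces byte-identical FASTA,
GTF, FASTQ and result files (content-hash manifest). Problem sizes used
by the validation suite — 150-gene cohorts, 200k reads per sample, 50 kb
oracle references, 2000-feature calibration — are the package's default
study conditions and run in about a minute each on one CPU.

## Known limitations

Ungapped alignment only (no indels, no soft clips); junction discovery is
restricted to annotated exon boundaries within one gene; no TMM or
count-model normalization (composition effects are a property of RPKM by
design); the exact Wilcoxon is limited to n ≤ 25 pairs; the pattern
classifier assumes exon-level calls are trustworthy and does not model
exon-level multimapping ambiguity.
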