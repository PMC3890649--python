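# Methods

This note documents the models, parameter choices and numerical
conventions behind `gslkit`, and what the synthetic-data generator does
and does not emulate.

## Coordinate system

All user-facing positions are anchored at the transcription start site
(TSS): the first transcribed base is +1, the base immediately upstream is
−1, and position 0 does not exist.  Internally every computation uses
0-based half-open array offsets; `coords.py` is the only bridge.  The
"linearized" scale (`lin(−1) = 0`, `lin(+1) = 1`) turns the no-zero
convention into ordinary integer arithmetic for distances and interval
logic.  Region annotation follows the feature scheme used for SNP-density
accounting: the promoter is split into bins counted backwards from −1
(most-upstream bin may be short), the 5'UTR is its own region, "exon 1"
begins at the ATG, and the 3'UTR begins after the stop codon.

## Haplotype variant discovery

Alleles are compared to the reference by global pairwise alignment with
affine gap penalties (Gotoh three-state dynamic program).  Defaults:
match +2, mismatch −3, gap open 5, gap extend 2, a length-L gap run
costing open + L·extend.  The tool the original workflow used for
two-sequence comparison is a general multiple aligner; for the pairwise
case an exact dynamic program is preferable because its optimum and
tie-breaking can be specified: traceback prefers the diagonal move, then
a gap in the second sequence, then a gap in the first, and direct
transitions between opposite-side gap runs are permitted (adjacent
insertion/deletion pairs can be optimal when mismatches are expensive).
Correctness is pinned by two independent oracles in the test suite: a
memoized top-down recursion and, at tiny sizes, full enumeration of all
alignments.

From the alignment, each mismatch column yields one SNP and each maximal
contiguous gap run one indel event regardless of length — the event
counting that makes "four indels of 1–7 nt" style tallies well defined.
An indel is reported at the first affected reference base; a pure
insertion carries the coordinate of the reference base it precedes with
'-' as its reference allele, and region assignment uses that first
affected base.

## Pileup SNP calling

Reads are consumed from a documented TSV dialect (read id, TSS coordinate
of the leftmost covered base, strand, read-oriented sequence, phred-33
qualities, unique-mapping flag); minus-strand reads contribute their
reverse complement.  The caller applies three filters, literally: an
observation passes only from a uniquely mapped read (configurable) and
only with base quality **strictly** above phred 15; an alternate base is
called only with at least three passing observations.  The minimum
alternate-allele fraction defaults to 0 because a simplex allele in an
autotetraploid is expected in ~25% of reads and any fraction filter would
interact badly with the count threshold at moderate coverage.  Raising
the support threshold can only remove calls and adding a passing
observation can only add them (monotonicity, property-tested).  The
short-read path calls SNPs only; the indel inventory comes from the
allele workflow.

## Gene structure inference

The cDNA must be an exact concatenation of in-order genomic substrings
with every skipped segment at least `min_intron` (default 50) nt,
starting GT and ending AG.  The default guards against spurious GT..AG
micro-introns in random backgrounds.  Among valid placements the
leftmost (earliest donor, then earliest acceptor, recursively) is
returned, which makes the result deterministic; an exhaustive placement
oracle checks this on small instances.  No mismatches or alternative
isoforms are modelled.

## Promoter analysis

Motif matching is exact per position against IUPAC degenerate patterns on
both strands — no scoring matrices, no mismatches.  Hits follow the
reporting convention of the printed motif tables: coordinates run along
the motif's own 5'→3' orientation, so minus-strand hits have start > end;
a normalized (lo, hi) span is kept for interval logic.  A pattern that
equals its own reverse complement is reported once, on the plus strand.

TSS prediction uses the plant YR rule: every pyrimidine→purine
dinucleotide whose purine lies within a window (default 120 nt) upstream
of the ATG is a candidate; candidates with a TATA consensus (TATAWA)
ending 20–50 nt upstream rank above unsupported ones, then proximity to
the ATG decides.  The 20–50 nt band was chosen to cover both annotated
GSL promoters, whose TATA boxes end 27 and 45 nt upstream of their
predicted starts; narrower textbook bands would reject the second.

Core elements are located in windows relative to the TSS (all
configurable): TATA = downstream-most exact TATAWA in −60..−20; Y patch =
longest run of ≥5 pyrimidines in −60..−10 **excluding the TATA-box
span** — without that exclusion an abutting TATA box's leading T fuses
with the tract and shifts the reported boundary; CAAT = exact CCAAT in
−80..−30, else the best ≤1-mismatch match flagged "hypothetical", ties
resolved downstream-most.  These operationalizations reproduce both
genes' published annotations and are stated rather than learned.

A motif occurrence is "disrupted" in a genotype when any variant
footprint intersects its span; insertions count only when the insertion
point falls strictly inside the span (an insertion flush against a motif
boundary leaves the motif sequence intact).

## Allele dosage estimation

Clone counts per allele are modelled as one multinomial draw with
category probabilities dosage_i/ploidy — the formalization of estimating
copy number "from the frequency of clones".  The log-likelihood is
Σ c_i·ln(d_i/ploidy) with 0·ln 0 = 0 and −∞ when an observed allele gets
zero copies.  Estimation enumerates every integer vector with entries ≥
`min_copies` (default 1: a sequenced allele exists at least once) summing
to the ploidy; ties are detected with a small tolerance because permuted
dosage vectors accumulate identical log terms in different orders, and
are reported via `ml_unique=False`.  A likelihood-ratio against the
runner-up is printed for transparency.  No clone/PCR bias model and no
prior are applied.

## The synthetic-data generator

The generator is first-class, tested code that defines the study
conditions the pipeline is validated under.

**Reference construction.** A gene is built from ordered region lengths
(promoter ≥600 nt, 5'UTR, 2–3 exons with GT..AG introns, 3'UTR) over an
i.i.d. background with configurable GC (default 0.38, a typical plant
genomic value).  Fixed anatomy is overwritten onto the background: a TG
(YR) dinucleotide across the TSS, ATG at the start of exon 1, a stop
codon at the end of the last exon, splice dinucleotides, and a 5'UTR
filled with pyrimidines (avoiding runs of five T) so that the planted TSS
is the only YR candidate downstream of itself.  Declared promoter motifs
and core elements are planted at their TSS coordinates; overlapping
features are accepted only where they agree on every shared base, and a
conflicting pair is reported by name.

When a motif library is attached, the builder then "scrubs" the
background with point mutations of non-planted bases until the finished
reference scans clean: chance occurrences of library patterns, stray
TATA consensus matches in the TATA window, near-CCAAT matches in the CAAT
window, and pyrimidine tracts that would outcompete the planted Y patch
are removed iteratively (deterministic per seed).  This makes "scanning
the promoter returns exactly the planted inventory" a meaningful
end-to-end check.  Real promoters are of course not scrubbed: on real
sequence the scanner reports every degenerate-pattern occurrence, and the
curated inventories it is compared against reflect additional
context-based selection that this package does not model.

**Haplotypes.** Requested per-region SNP/indel counts are planted at
uniform random positions with carriers drawn uniformly from the non-
reference haplotypes (haplotype 0 stays unmutated); the union across
haplotypes equals the request exactly.  Indel lengths are uniform on the
configured range (the observed allele pairs motivate 1–7 and 1–18 nt
defaults; no distribution beyond the range is published).  Placement
enforces unambiguity so that truth/called comparisons are exact rather
than alignment-dependent: flanking bases block one-step gap shifts,
footprints sit at least two free bases apart with extra clearance of
(length + 8) nt around indels — two long indels planted a few bases apart
can otherwise be re-explained more cheaply by the aligner — and each
finished haplotype is verified to diff back to exactly its planted set,
with placement retried on a fresh substream otherwise.

**Reads.** Reads are emitted pre-placed (no mapper exists or is needed):
a source haplotype is drawn with probability dosage/ploidy, a start
uniformly, a strand 50/50; substitution errors are i.i.d. at the
configured rate and qualities are Gaussian (default mean 35, sd 5,
clipped to [2, 41]) independent of error status.  The unique-mapping
flag is assigned at random (default fraction 0) rather than derived from
repetitiveness — consumers only read the flag.  Coverage defaults to
12×, the middle of the 9–15× range the analysis assumes.  The source
haplotype is encoded in the read id, which is what lets validation
distinguish "the caller missed a recoverable SNP" from "sampling never
delivered three carrier reads": a planted SNP counts as recoverable when
its realized passing support from carrier reads reaches the caller's
threshold.  At 12×, a simplex SNP has an expected support of exactly
3.0, so a fraction of planted simplex SNPs is legitimately unrecoverable
in any given draw; recovery is therefore measured against realized, not
expected, support.

**Clone sampling** is a single multinomial draw with probabilities
dosage_i/Σdosage.

**Not emulated:** empirical (position- or context-dependent) error
profiles, paired-end insert sizes, repeat-driven mappability, indel
errors in reads, PCR/cloning bias in clone counts, and real promoter
background (see scrubbing above).  Passing tests therefore demonstrate
correctness of the analysis logic under clean, controlled conditions —
not robustness to artefacts of real sequencing data.

## Problem sizes

The shipped presets mirror the published feature schemes: a 2,969 nt
two-exon gene (1,960 nt promoter binned at 500 nt) and a 1,657 nt
three-exon gene (590 nt promoter, unbinned), four haplotypes each, with
the published per-region variant counts (97 SNPs + 53 indels and 36 SNPs
+ 21 indels respectively).  Read-based validation uses 20 replicate read
sets at 12× from a (3,1) tetraploid mixture over the 2,969 nt gene;
dosage consistency checks use 1,000 replicate clone draws per clone
count.  These sizes keep the full suite and the acceptance script in the
tens of seconds on a single core.

## Known limitations

* The affine aligner is exact but quadratic; it is meant for gene-scale
  sequences (a few kb), not chromosomes.
* Exact degenerate matching reproduces printed motif inventories only on
  sequence where chance occurrences are controlled (synthetic scrubbed
  promoters); on real promoters it enumerates all pattern occurrences
  and leaves biological filtering to the user.
* Dosage estimation treats clones as independent draws; with a handful
  of clones the likelihood surface is shallow (e.g. 2-of-12 minor-allele
  clones still favors a single copy, but not overwhelmingly).
* The pileup caller does not model mapping quality beyond the binary
  unique flag, and does not call indels from reads.
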