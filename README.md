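# gslkit

Conservation and regulation analysis of the potato *GSL1* and *GSL2*
(Snakin-1/Snakin-2) genes — and of gene families like them — rebuilt as a
reusable, tested Python pipeline that runs entirely on synthetic data
generated in-repo.

The GSL genes encode small cysteine-rich antimicrobial peptides that are
remarkably conserved across potato germplasm: in a highly heterozygous
autotetraploid (four haplotypes per locus), their exons show roughly one
SNP per 67 and 53 nucleotides, respectively, while introns and promoter
regions vary much more freely. `gslkit` implements the analyses that
establish such a conservation profile:

* **Haplotype variant discovery** — full-length alleles are compared to a
  reference by global affine-gap alignment (Gotoh algorithm, deterministic
  tie-breaking); every mismatch column is a SNP and every maximal gap run
  one indel event.
* **Pileup SNP calling** — placed short reads are stacked per reference
  position and filtered with strict polySNP-style rules: uniquely mapped
  reads only, base quality strictly above phred 15, and an alternate base
  must appear in at least three passing reads.  No minimum allele fraction
  is imposed: a simplex allele in a tetraploid is expected in only ~25% of
  reads.
* **Per-feature SNP density** — variants are partitioned over promoter
  bins, 5'UTR, exons, introns and 3'UTR; conservation is reported as
  *nucleotides per SNP* (region size / SNP count, one decimal, half away
  from zero; "-" when a region holds no SNP), with integer aggregates over
  region classes (e.g. all exons).
* **Gene structure inference** — exon/intron layout is recovered from a
  genomic/cDNA pair by exact spliced placement with canonical GT..AG
  introns (leftmost placement; pinned by a brute-force oracle).
* **Promoter analysis** — exact IUPAC degenerate-motif scanning on both
  strands (minus-strand hits reported along the motif's own 5'→3'
  orientation, so their start coordinate exceeds their end), TSS
  prediction by the plant YR rule (pyrimidine at −1, purine at +1) ranked
  by TATA-box support and ATG proximity, core element location (TATA box,
  pyrimidine patch, CAAT box — exact or "hypothetical" at one mismatch),
  and detection of motif occurrences disrupted by allelic variants.
* **Allele dosage estimation** — clone counts per allele are modelled as
  multinomial with category probabilities d·/ploidy; the integer dosage
  vector maximizing the likelihood is found by exhaustive enumeration.
  Counts of 15-of-16 or 10-of-12 for the major allele both yield the
  triplex/simplex (3,1) configuration.

All user-facing coordinates are TSS-anchored: the first transcribed base
is +1, the base upstream is −1, and there is no position 0.

## Worked example

Generate a synthetic GSL1-like dataset (reference with planted promoter
motifs and core elements, four haplotypes carrying the published
per-region variant counts, reads at 12×, clone draws), then summarize:

```bash
gslkit simulate --preset gsl1 --seed 1 --out demo/
gslkit summarize --variants demo/truth_variants.tsv \
                 --regions demo/regions.tsv --aggregate exon \
                 --out demo/summary.tsv
gslkit report --summaries demo/summary.tsv --out demo/summary.txt
```

This prints `aggregate nucleotides/SNP over exon: 67` and writes:

```
  Region Nucleotide position  Size  Number of indels  Number of SNPs SNP frequency (nucleotides/SNP)
promoter      -1960 to -1501   460                 6              18                            25.6
promoter      -1500 to -1001   500                 9              14                            35.7
promoter       -1000 to -501   500                 9              18                            27.8
promoter          -500 to -1   500                10              13                            38.5
   5'UTR             1 to 33    33                 0               1                            33.0
  exon 1           34 to 115    82                 0               2                            41.0
  intron          116 to 619   504                16              24                            21.0
  exon 2          620 to 804   185                 0               2                            92.5
   3'UTR         805 to 1009   205                 3               5                            41.0
```

Each row reads: region, its TSS coordinates, size in nt, indel events, SNP
count, and nucleotides per SNP (larger = more conserved).  The exon rows
(82 + 185 nt holding 2 + 2 SNPs) aggregate to one SNP every 67 nt.

Dosage from clone counts:

```bash
$ gslkit dose --counts 15,1 --ploidy 4
allele  clones  ML_copies
allele1 15      3
allele2 1       1
logLik=-5.7015  LR_vs_next=5.3888  unique=True
```

Fifteen of sixteen clones carrying one allele is best explained by three
of the four homologous copies; the log-likelihood margin over the next
configuration (2,2) is 5.39 nats.

Other subcommands: `diff` (allele-vs-reference variant tables), `call`
(pileup SNP calling from the reads TSV), `annotate` (cDNA-guided
structure + region annotation), `scan` (motif occurrences), `tss`
(YR-rule candidates), `express` (per-library FPKM comparison of two
genes).

## Layout

```
src/gslkit/
  coords.py      TSS coordinate arithmetic (no position 0), IUPAC tables
  genemodel.py   GeneModel/GeneRegion, region annotation, structure inference
  align.py       affine-gap global alignment (numba-accelerated)
  variants.py    variant model, haplotype diffing, pileup, polySNP caller
  simulate.py    synthetic genes, haplotypes, reads, clone sampling
  presets.py     GSL1/GSL2 feature schemes, motif inventories, core elements
  promoter.py    motif scanning, TSS/core-element prediction, disruptions
  dosage.py      multinomial ML dosage estimation
  regionstats.py nucleotides-per-SNP accounting, FPKM comparison
  io.py          FASTA/TSV formats, packaged motif libraries
  cli.py         the `gslkit` subcommand CLI
```
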