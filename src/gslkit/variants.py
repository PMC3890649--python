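"""Variant discovery: haplotype-vs-reference diffing and pileup SNP calling.

Two call paths mirror the two ways allelic variation is established for
these genes:

* **Allele workflow** -- full-length haplotype sequences (e.g. cloned and
  Sanger-sequenced alleles) are globally aligned against the reference and
  every mismatch column becomes a SNP, every maximal contiguous gap run one
  indel event.
* **Short-read workflow** -- simulated uniquely-mapped reads are piled up
  per reference position and SNPs are called with the polySNP filtering
  rules: only uniquely mapped reads, base quality strictly above phred 15,
  and at least three supporting reads for the alternate base.

Positions are reported in TSS coordinates of the reference (no position 0;
for indels, the first affected reference base; a pure insertion carries the
coordinate of the reference base it precedes, with ref allele '-').
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import Alignment, AlignmentScoring, align_global
from .coords import lin, offset_to_tss, tss_to_offset, revcomp
from .genemodel import GeneModel

__all__ = [
    "Variant",
    "AlignedRead",
    "PileupColumn",
    "CallerConfig",
    "SNPCall",
    "diff_haplotype",
    "variants_from_alignment",
    "apply_variants",
    "merge_variant_tables",
    "pileup_from_reads",
    "call_snps_polysnp",
]


@dataclass(frozen=True)
class Variant:
    """A SNP or indel in TSS coordinates of the reference sequence."""

    position: int
    kind: str  # "SNP" | "indel"
    ref_allele: str
    alt_allele: str
    carriers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "indel"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNP ref and alt alleles must differ")
        else:
            ins, dele = self.ref_allele == "-", self.alt_allele == "-"
            if ins == dele:
                raise ValueError("indel must have '-' on exactly one side")

    @property
    def length(self) -> int:
        """Event length in nt (1 for a SNP)."""
        if self.kind == "SNP":
            return 1
        allele = self.alt_allele if self.ref_allele == "-" else self.ref_allele
        return len(allele)

    @property
    def is_insertion(self) -> bool:
        return self.kind == "indel" and self.ref_allele == "-"

    def footprint(self) -> tuple[int, int]:
        """Inclusive linearized interval of affected reference bases.

        An insertion sits between two reference bases; its footprint is the
        empty interval just left of ``position`` (hi < lo), handled by the
        disruption-overlap logic.
        """
        lo = lin(self.position)
        if self.kind == "SNP":
            return lo, lo
        if self.is_insertion:
            return lo, lo - 1
        return lo, lo + len(self.ref_allele) - 1

    def key(self) -> tuple:
        return (lin(self.position), self.kind, self.ref_allele, self.alt_allele)

    def with_carriers(self, carriers) -> "Variant":
        return Variant(self.position, self.kind, self.ref_allele, self.alt_allele,
                       frozenset(carriers))


# ---------------------------------------------------------------------------
# Allele workflow: global alignment -> variants
# ---------------------------------------------------------------------------

def variants_from_alignment(
    aln: Alignment, *, tss_index: int, carrier: str | None = None
) -> list[Variant]:
    """Extract SNPs and indel events from a ref-vs-haplotype alignment.

    ``aln.aligned_a`` is the reference row.  One maximal contiguous gap run
    equals exactly one indel event regardless of length.
    """
    carriers = frozenset([carrier]) if carrier else frozenset()
    out: list[Variant] = []
    ref_off = 0  # offset of next reference base
    k = 0
    cols_a, cols_b = aln.aligned_a, aln.aligned_b
    ncol = len(cols_a)
    while k < ncol:
        ca, cb = cols_a[k], cols_b[k]
        if ca != "-" and cb != "-":
            if ca != cb:
                out.append(Variant(offset_to_tss(ref_off, tss_index), "SNP",
                                   ca, cb, carriers))
            ref_off += 1
            k += 1
        elif cb == "-":  # deletion in haplotype: run of gaps in b
            start_off = ref_off
            run = []
            while k < ncol and cols_b[k] == "-":
                run.append(cols_a[k])
                ref_off += 1
                k += 1
            out.append(Variant(offset_to_tss(start_off, tss_index), "indel",
                               "".join(run), "-", carriers))
        else:  # insertion in haplotype: run of gaps in a
            run = []
            while k < ncol and cols_a[k] == "-":
                run.append(cols_b[k])
                k += 1
            out.append(Variant(offset_to_tss(ref_off, tss_index), "indel",
                               "-", "".join(run), carriers))
    return out


def diff_haplotype(
    ref: str,
    hap: str,
    scoring: AlignmentScoring | None = None,
    *,
    tss_index: int = 0,
    carrier: str | None = None,
) -> list[Variant]:
    """Align ``hap`` against ``ref`` globally and extract the variant list.

    Identical sequences yield an empty list.  ``tss_index`` anchors the
    reported TSS coordinates (offset of coordinate +1 within ``ref``).
    """
    if ref == hap:
        return []
    aln = align_global(ref, hap, scoring)
    return variants_from_alignment(aln, tss_index=tss_index, carrier=carrier)


def apply_variants(ref: str, variants: list[Variant], *, tss_index: int = 0) -> str:
    """Reference sequence with ``variants`` applied (right-to-left)."""
    seq = list(ref)
    for v in sorted(variants, key=lambda v: lin(v.position), reverse=True):
        off = tss_to_offset(v.position, tss_index)
        if v.kind == "SNP":
            if seq[off] != v.ref_allele:
                raise ValueError(f"ref mismatch at {v.position}: {seq[off]} != {v.ref_allele}")
            seq[off] = v.alt_allele
        elif v.is_insertion:
            seq[off:off] = list(v.alt_allele)
        else:
            got = "".join(seq[off : off + len(v.ref_allele)])
            if got != v.ref_allele:
                raise ValueError(f"ref mismatch at {v.position}: {got} != {v.ref_allele}")
            del seq[off : off + len(v.ref_allele)]
    return "".join(seq)


def merge_variant_tables(tables) -> list[Variant]:
    """Union per-genotype variant lists into one table.

    Variants identical in (position, kind, ref, alt) are merged with their
    carrier sets unioned; output is sorted by position.  Two SNPs at one
    position must agree on the reference allele.
    """
    merged: dict[tuple, Variant] = {}
    ref_at: dict[int, str] = {}
    for table in tables:
        for v in table:
            if v.kind == "SNP":
                prev = ref_at.setdefault(v.position, v.ref_allele)
                if prev != v.ref_allele:
                    raise ValueError(
                        f"conflicting reference allele at position {v.position}: "
                        f"{prev} vs {v.ref_allele}"
                    )
            k = v.key()
            if k in merged:
                merged[k] = merged[k].with_carriers(merged[k].carriers | v.carriers)
            else:
                merged[k] = v
    return sorted(merged.values(), key=lambda v: v.key())


# ---------------------------------------------------------------------------
# Short-read workflow: pileup -> polySNP calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """One placed read in the reads-TSV dialect.

    ``start`` is the TSS coordinate of the first (leftmost) reference base
    the read covers; ``sequence`` is the read's own 5'->3' sequence, so a
    minus-strand read contributes the reverse complement to the reference
    forward strand.  Base qualities run along the read's own orientation.
    """

    read_id: str
    start: int
    strand: str
    sequence: str
    qualities: tuple[int, ...]
    unique: bool

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.qualities) != len(self.sequence):
            raise ValueError("quality string length != read length")

    def forward_bases(self) -> str:
        return self.sequence if self.strand == "+" else revcomp(self.sequence)

    def forward_quals(self) -> tuple[int, ...]:
        return self.qualities if self.strand == "+" else self.qualities[::-1]


@dataclass
class PileupColumn:
    """Per-position stack of read observations."""

    position: int
    ref_base: str
    observations: list[tuple[str, int, bool, str]]  # (base, phred, unique, read_id)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class CallerConfig:
    """polySNP filtering thresholds.

    ``min_base_quality`` is strict ("above phred 15"); ``min_alt_reads`` is
    inclusive ("present in at least three reads"); ``unique_only`` drops
    observations from multiply-mapped reads.  No minimum alternate-allele
    fraction is applied by default: in an autotetraploid a simplex allele is
    expected in only ~25% of reads.
    """

    min_base_quality: int = 15
    min_alt_reads: int = 3
    unique_only: bool = True
    min_alt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_alt_reads < 0 or self.min_alt_fraction < 0:
            raise ValueError("thresholds must be non-negative")

    def passes(self, quality: int, unique: bool) -> bool:
        if self.unique_only and not unique:
            return False
        return quality > self.min_base_quality


@dataclass(frozen=True)
class SNPCall:
    position: int
    ref_base: str
    alt_base: str
    supporting_reads: int
    total_passing_reads: int


def pileup_from_reads(reads, ref: GeneModel) -> list[PileupColumn]:
    """Stack reads into per-position columns over the reference model.

    Reads are taken at their stated placements (substitutions only; no
    gapped placement).  A read extending past the reference end is an
    error.
    """
    columns: dict[int, PileupColumn] = {}
    n = len(ref.sequence)
    for r in reads:
        off = ref.to_offset(r.start)
        bases = r.forward_bases()
        quals = r.forward_quals()
        if off + len(bases) > n:
            raise ValueError(f"read {r.read_id} extends past the reference end")
        for i, (b, q) in enumerate(zip(bases, quals)):
            o = off + i
            col = columns.get(o)
            if col is None:
                col = PileupColumn(ref.to_tss(o), ref.sequence[o], [])
                columns[o] = col
            col.observations.append((b, q, r.unique, r.read_id))
    return [columns[o] for o in sorted(columns)]


def call_snps_polysnp(columns, cfg: CallerConfig | None = None) -> list[SNPCall]:
    """Call SNPs from pileup columns under the polySNP rules.

    An observation passes iff it comes from a uniquely mapped read (when
    ``unique_only``) and its base quality is strictly above the threshold.
    An alternate base is called iff its passing support is at least
    ``min_alt_reads`` and its fraction of passing observations is at least
    ``min_alt_fraction``.  One call per (position, alternate base).
    """
    cfg = cfg or CallerConfig()
    calls: list[SNPCall] = []
    for col in columns:
        passing = [(b, q) for (b, q, u, _rid) in col.observations if cfg.passes(q, u)]
        total = len(passing)
        if not total:
            continue
        counts: dict[str, int] = {}
        for b, _q in passing:
            counts[b] = counts.get(b, 0) + 1
        for alt in sorted(counts):
            if alt == col.ref_base or alt == "N":
                continue
            n_alt = counts[alt]
            if n_alt >= cfg.min_alt_reads and n_alt / total >= cfg.min_alt_fraction:
                calls.append(SNPCall(col.position, col.ref_base, alt, n_alt, total))
    return calls
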