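"""Gene models: TSS-anchored sequences, feature regions, exon/intron structure.

A :class:`GeneModel` couples a nucleotide sequence with the array offset of
the transcription start site (TSS, coordinate +1) and an ordered feature
annotation (promoter bins, 5'UTR, exons, introns, 3'UTR).  The annotation
scheme follows the convention used for per-feature SNP-density accounting:
the 5'UTR is its own region, "exon 1" begins at the ATG, and the 3'UTR
begins immediately after the stop codon.

Exon/intron structure can be inferred from a genomic/cDNA pair by exact
spliced placement: the cDNA must be a concatenation of in-order genomic
substrings, and every skipped segment must be a canonical GT..AG intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .coords import (
    offset_to_tss,
    tss_add,
    tss_span,
    tss_to_offset,
    validate_nucleotides,
)

__all__ = [
    "GeneRegion",
    "GeneStructure",
    "GeneModel",
    "annotate_regions",
    "infer_gene_structure",
    "StructureNotFoundError",
]


@dataclass(frozen=True)
class GeneRegion:
    """One annotated feature region in inclusive TSS coordinates."""

    label: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return tss_span(self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}[{self.start}..{self.end}]"


@dataclass(frozen=True)
class GeneStructure:
    """Exon/intron layout as 0-based half-open offsets into a genomic sequence."""

    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError("exons and introns must alternate (n_introns = n_exons - 1)")
        bounds = []
        for (es, ee), (is_, ie) in zip(self.exons, self.introns + ((None, None),)):
            bounds.append((es, ee))
            if is_ is not None:
                if is_ != ee:
                    raise ValueError("intron must start where the previous exon ends")
                bounds.append((is_, ie))
        for (s, e) in bounds:
            if e is not None and e <= s:
                raise ValueError("empty structure segment")

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    def intron_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.introns)

    def splice_dinucleotides(self, genomic: str) -> tuple[tuple[str, str], ...]:
        return tuple((genomic[s : s + 2], genomic[e - 2 : e]) for s, e in self.introns)

    def spliced(self, genomic: str) -> str:
        """Concatenation of the exon substrings (the cDNA this structure implies)."""
        return "".join(genomic[s:e] for s, e in self.exons)


@dataclass
class GeneModel:
    """A gene sequence with TSS-anchored coordinates and feature regions."""

    gene_id: str
    sequence: str
    tss_index: int
    atg_pos: int  # TSS coordinate of the first base of the start codon
    regions: list[GeneRegion] = field(default_factory=list)
    structure: GeneStructure | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_nucleotides(self.sequence, name=f"{self.gene_id} sequence")
        if not (0 <= self.tss_index < len(self.sequence)):
            raise ValueError("tss_index outside sequence")
        if self.regions:
            _check_tiling(self.regions, self)

    # -- coordinate bridge -------------------------------------------------
    def to_offset(self, pos: int) -> int:
        off = tss_to_offset(pos, self.tss_index)
        if not (0 <= off < len(self.sequence)):
            raise ValueError(f"position {pos} outside {self.gene_id} ({len(self.sequence)} nt)")
        return off

    def to_tss(self, offset: int) -> int:
        if not (0 <= offset < len(self.sequence)):
            raise ValueError(f"offset {offset} outside {self.gene_id}")
        return offset_to_tss(offset, self.tss_index)

    @property
    def first_pos(self) -> int:
        return self.to_tss(0)

    @property
    def last_pos(self) -> int:
        return self.to_tss(len(self.sequence) - 1)

    def subseq(self, start: int, end: int) -> str:
        """Sequence of the inclusive TSS-coordinate range [start, end]."""
        return self.sequence[self.to_offset(start) : self.to_offset(end) + 1]

    def promoter_sequence(self) -> str:
        """Everything upstream of the TSS."""
        return self.sequence[: self.tss_index]

    def transcript(self) -> str:
        """Spliced transcript: TSS..end of sequence minus introns."""
        seq = self.sequence[self.tss_index :]
        if self.structure is None:
            return seq
        out, cursor = [], self.tss_index
        for is_, ie in self.structure.introns:
            out.append(self.sequence[cursor:is_])
            cursor = ie
        out.append(self.sequence[cursor:])
        return "".join(out)

    def region_of(self, pos: int) -> GeneRegion:
        from .coords import lin

        x = lin(pos)
        for r in self.regions:
            if lin(r.start) <= x <= lin(r.end):
                return r
        raise ValueError(f"position {pos} falls outside all annotated regions of {self.gene_id}")

    def with_regions(self, regions: list[GeneRegion]) -> "GeneModel":
        return replace(self, regions=regions)


def _check_tiling(regions: list[GeneRegion], model: GeneModel) -> None:
    from .coords import lin

    expect = lin(model.first_pos)
    for r in regions:
        if lin(r.start) != expect:
            raise ValueError(f"regions do not tile: gap/overlap before {r}")
        expect = lin(r.end) + 1
    if expect != lin(model.last_pos) + 1:
        raise ValueError("regions do not cover the full sequence")


# ---------------------------------------------------------------------------
# Region annotation (per-feature SNP density scheme)
# ---------------------------------------------------------------------------

def annotate_regions(
    model: GeneModel,
    *,
    promoter_bin_size: int | None = 500,
) -> list[GeneRegion]:
    """Annotate ``model`` into promoter bins, 5'UTR, exons, introns and 3'UTR.

    The promoter (everything upstream of the TSS) is split into bins of
    ``promoter_bin_size`` nt counted backwards from -1; the most-upstream
    bin may be short.  ``promoter_bin_size=None`` keeps the promoter as a
    single region.  Exon/intron boundaries come from ``model.structure``
    (required); exon 1 begins at the ATG, the 3'UTR after the last exon.
    """
    if model.structure is None:
        raise ValueError(f"{model.gene_id} has no exon/intron structure to annotate")

    regions: list[GeneRegion] = []
    promoter_len = model.tss_index
    if promoter_len:
        upstream_start = model.first_pos  # e.g. -1960
        if promoter_bin_size is None:
            regions.append(GeneRegion("promoter", upstream_start, -1))
        else:
            bounds: list[tuple[int, int]] = []
            hi = -1
            remaining = promoter_len
            while remaining > 0:
                take = min(promoter_bin_size, remaining)
                lo = tss_add(hi, -(take - 1))
                bounds.append((lo, hi))
                hi = tss_add(lo, -1)
                remaining -= take
            for lo, hi2 in reversed(bounds):
                regions.append(GeneRegion("promoter", lo, hi2))

    # Transcribed part. CDS exon boundaries are derived from the structure,
    # shifted so exon 1 starts at the ATG (5'UTR kept separate).
    atg_off = model.to_offset(model.atg_pos)
    if model.atg_pos > 1:
        regions.append(GeneRegion("5'UTR", 1, tss_add(model.atg_pos, -1)))

    exons = list(model.structure.exons)
    introns = list(model.structure.introns)
    # First exon of the transcript contains the 5'UTR; trim it to start at ATG.
    if not (exons[0][0] <= atg_off < exons[0][1]):
        raise ValueError("ATG must lie inside the first exon")
    exons[0] = (atg_off, exons[0][1])

    # The structure's exon list here is the CDS layout (exon 1 trimmed to
    # start at ATG above); the 3'UTR is everything after the last exon.
    last_exon_end = exons[-1][1]
    for k, (es, ee) in enumerate(exons, start=1):
        regions.append(GeneRegion(f"exon {k}", model.to_tss(es), model.to_tss(ee - 1)))
        if k <= len(introns):
            is_, ie = introns[k - 1]
            ilabel = f"intron {k}" if len(introns) > 1 else "intron"
            regions.append(GeneRegion(ilabel, model.to_tss(is_), model.to_tss(ie - 1)))
    if last_exon_end < len(model.sequence):
        regions.append(
            GeneRegion("3'UTR", model.to_tss(last_exon_end), model.last_pos)
        )
    _check_tiling(regions, model)
    return regions


# ---------------------------------------------------------------------------
# cDNA-guided exon/intron inference
# ---------------------------------------------------------------------------

class StructureNotFoundError(ValueError):
    """No consistent exon placement with GT..AG introns exists."""


def infer_gene_structure(genomic: str, cdna: str, *, min_intron: int = 50) -> GeneStructure:
    """Infer exon/intron structure by exact spliced placement of ``cdna``.

    The cDNA must equal the concatenation of >=1 in-order substrings of
    ``genomic``; every skipped segment must be at least ``min_intron`` nt,
    start with GT and end with AG.  Among valid placements the leftmost
    (earliest splice donor, greedily per intron) one is returned.
    """
    genomic = validate_nucleotides(genomic, name="genomic")
    cdna = validate_nucleotides(cdna, name="cdna")
    if not cdna:
        raise ValueError("empty cDNA")

    placement = _place(genomic, cdna, 0, 0, min_intron)
    if placement is None:
        raise StructureNotFoundError(
            "cDNA cannot be placed on the genomic sequence with GT..AG introns"
        )
    exons = tuple(placement)
    introns = tuple((e0[1], e1[0]) for e0, e1 in zip(exons, exons[1:]))
    return GeneStructure(exons=exons, introns=introns)


def _place(
    genomic: str, cdna: str, g: int, c: int, min_intron: int
) -> list[tuple[int, int]] | None:
    """Leftmost placement of cdna[c:] on genomic[g:]; first exon starts at g."""
    # Longest exon match starting here.
    n = 0
    while c + n < len(cdna) and g + n < len(genomic) and genomic[g + n] == cdna[c + n]:
        n += 1
    if c + n == len(cdna):
        # cDNA exhausted -- final exon.  (A trailing intron makes no sense.)
        if n == 0:
            return None
        return [(g, g + n)]
    # Try donor sites from the leftmost viable position.  The exon must be
    # non-empty and the donor must sit at a GT.
    for exon_len in range(1, n + 1):
        donor = g + exon_len
        if genomic[donor : donor + 2] != "GT":
            continue
        # Acceptor candidates: intron of length >= min_intron ending AG,
        # scanned left to right (leftmost placement overall).
        for acceptor_end in range(donor + min_intron, len(genomic) + 1):
            if genomic[acceptor_end - 2 : acceptor_end] != "AG":
                continue
            tail = _place(genomic, cdna, acceptor_end, c + exon_len, min_intron)
            if tail is not None:
                return [(g, donor)] + tail
    return None
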