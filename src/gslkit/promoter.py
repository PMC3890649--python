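"""Promoter analysis: degenerate motif scanning, TSS and core-element
prediction, and detection of motif-disrupting allelic variants.

Motif matching is exact per position against IUPAC degenerate patterns on
both strands (no mismatches, no scoring matrix).  Hit coordinates follow
the convention of reporting a hit along the motif's own 5'->3' orientation:
a minus-strand hit has a start coordinate numerically greater than its end.
A normalized (lo, hi) span is kept alongside for interval logic.

The TSS predictor applies the plant YR rule -- a pyrimidine at -1 directly
followed by a purine at +1 -- within a window upstream of the ATG, ranking
candidates that have a TATA box at a plausible offset above those that do
not, then by proximity to the ATG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coords import IUPAC, PURINES, PYRIMIDINES, lin, tss_add, revcomp
from .variants import Variant

__all__ = [
    "MotifDef",
    "MotifHit",
    "TSSCandidate",
    "CoreElements",
    "MotifDisruption",
    "scan_motifs",
    "predict_tss",
    "find_core_elements",
    "detect_disruptions",
]


@dataclass(frozen=True)
class MotifDef:
    """A named degenerate promoter motif."""

    motif_id: str
    pattern: str
    function_note: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.motif_id}: empty pattern")
        for ch in self.pattern:
            if ch not in IUPAC:
                raise ValueError(
                    f"motif {self.motif_id}: invalid IUPAC character {ch!r}"
                )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; start/end in motif orientation (minus-strand
    hits have start > end)."""

    motif_id: str
    start: int
    end: int
    strand: str
    matched: str

    @property
    def span(self) -> tuple[int, int]:
        """Normalized (lo, hi) TSS-coordinate span."""
        return (self.end, self.start) if self.strand == "-" else (self.start, self.end)

    def key(self) -> tuple:
        return (lin(self.span[0]), self.strand, self.motif_id)


def _matches_at(seq: str, i: int, pattern: str) -> bool:
    return all(seq[i + k] in IUPAC[pattern[k]] for k in range(len(pattern)))


def scan_motifs(seq: str, library, *, anchor: int) -> list[MotifHit]:
    """All occurrences of every library motif on both strands of ``seq``.

    ``anchor`` is the TSS coordinate of ``seq[0]``.  Overlapping
    occurrences are all reported.  A plus-strand hit at array window
    [i, i+L) is reported at coordinates (pos(i), pos(i+L-1)); the
    corresponding minus-strand convention is (pos(i+L-1), pos(i)).
    A self-reverse-complementary pattern reads identically on both
    strands, so such occurrences are reported once, on the plus strand.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif in library:
        pat = motif.pattern
        rc_pat = revcomp(pat)
        palindromic = rc_pat == pat
        L = len(pat)
        for i in range(len(seq) - L + 1):
            lo = tss_add(anchor, i)
            hi = tss_add(anchor, i + L - 1)
            window = seq[i : i + L]
            if _matches_at(seq, i, pat):
                hits.append(MotifHit(motif.motif_id, lo, hi, "+", window))
            if not palindromic and _matches_at(seq, i, rc_pat):
                hits.append(MotifHit(motif.motif_id, hi, lo, "-", revcomp(window)))
    hits.sort(key=MotifHit.key)
    return hits


# ---------------------------------------------------------------------------
# TSS prediction (YR rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TSSCandidate:
    """A candidate transcription start: the purine of a YR dinucleotide."""

    position: int  # coordinate (in the supplied frame) of the candidate +1
    distance_to_atg: int
    tata: tuple[int, int] | None  # supporting TATA-box span, if any

    @property
    def supported(self) -> bool:
        return self.tata is not None


TATA_PATTERN = "TATAWA"


def _tata_matches(seq: str, lo_off: int = 0, hi_off: int | None = None):
    """Array windows [i, i+6) matching the TATA consensus in seq[lo:hi]."""
    hi_off = len(seq) if hi_off is None else hi_off
    out = []
    for i in range(max(lo_off, 0), hi_off - len(TATA_PATTERN) + 1):
        if _matches_at(seq, i, TATA_PATTERN):
            out.append(i)
    return out


def predict_tss(
    seq: str,
    *,
    anchor: int,
    atg: int,
    window: int = 120,
    tata_offset_range: tuple[int, int] = (20, 50),
) -> list[TSSCandidate]:
    """Ranked TSS candidates upstream of the ATG under the YR rule.

    Every pyrimidine->purine dinucleotide whose purine lies within
    ``window`` nt upstream of the ATG is a candidate.  Candidates backed
    by a TATA consensus (TATAWA) ending ``tata_offset_range`` nt upstream
    of the candidate +1 rank above unsupported ones; within each class,
    candidates closer to the ATG rank first.  Empty list when the window
    holds no YR dinucleotide.
    """
    seq = seq.upper()
    atg_lin = lin(atg)
    lo_lin, hi_lin = atg_lin - window, atg_lin - 1
    tata_ends = {}  # lin(end coordinate) -> (start, end) in anchor frame
    for i in _tata_matches(seq):
        end_pos = tss_add(anchor, i + len(TATA_PATTERN) - 1)
        tata_ends[lin(end_pos)] = (tss_add(anchor, i), end_pos)

    out: list[TSSCandidate] = []
    for i in range(1, len(seq)):
        pos = tss_add(anchor, i)
        x = lin(pos)
        if not (lo_lin <= x <= hi_lin):
            continue
        if seq[i - 1] not in PYRIMIDINES or seq[i] not in PURINES:
            continue
        support = None
        for off in range(tata_offset_range[0], tata_offset_range[1] + 1):
            hit = tata_ends.get(x - off)
            if hit is not None and (support is None or hit[1] > support[1]):
                support = hit
        out.append(TSSCandidate(pos, atg_lin - x, support))
    out.sort(key=lambda c: (not c.supported, c.distance_to_atg))
    return out


# ---------------------------------------------------------------------------
# Core promoter elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreElements:
    """TATA box, pyrimidine patch and CAAT box upstream of the TSS."""

    tata: tuple[int, int] | None
    y_patch: tuple[int, int] | None
    caat: tuple[int, int] | None
    caat_kind: str | None  # "canonical" | "hypothetical"


CAAT_PATTERN = "CCAAT"


def find_core_elements(
    seq: str,
    *,
    anchor: int,
    tata_window: tuple[int, int] = (-60, -20),
    y_window: tuple[int, int] = (-60, -10),
    caat_window: tuple[int, int] = (-80, -30),
    min_y_run: int = 5,
) -> CoreElements:
    """Locate core promoter elements relative to the TSS (+1).

    TATA box: downstream-most exact TATAWA match fully inside
    ``tata_window``.  Y patch: longest maximal run of >= ``min_y_run``
    pyrimidines inside ``y_window``, excluding the TATA-box span (the two
    elements can be adjacent; without the exclusion a TATA box's leading T
    would fuse with an abutting pyrimidine tract).  CAAT box: exact CCAAT
    inside ``caat_window`` ("canonical"), else the best match with at most
    one mismatch ("hypothetical"); ties resolved downstream-most.
    Requires at least 70 nt of sequence upstream of the TSS.
    """
    seq = seq.upper()

    def off(pos: int) -> int:
        return lin(pos) - lin(anchor)

    upstream = 1 - lin(anchor)  # nt available upstream of the TSS
    if upstream < 70:
        raise ValueError(f"need >= 70 nt upstream of the TSS, have {upstream}")

    def window_offsets(win: tuple[int, int]) -> tuple[int, int]:
        return off(win[0]), off(win[1])

    def pos_of(i: int) -> int:
        return tss_add(anchor, i)

    # --- TATA -------------------------------------------------------------
    t_lo, t_hi = window_offsets(tata_window)
    tata = None
    for i in _tata_matches(seq, t_lo, min(t_hi + 1, len(seq))):
        if i >= t_lo and i + len(TATA_PATTERN) - 1 <= t_hi:
            tata = (pos_of(i), pos_of(i + len(TATA_PATTERN) - 1))
    tata_offs = (
        set(range(off(tata[0]), off(tata[1]) + 1)) if tata is not None else set()
    )

    # --- Y patch ----------------------------------------------------------
    y_lo, y_hi = window_offsets(y_window)
    best_run = None  # (length, start_off)
    run_start = None
    for i in range(y_lo, y_hi + 2):
        in_run = (
            0 <= i <= y_hi
            and i < len(seq)
            and seq[i] in PYRIMIDINES
            and i not in tata_offs
        )
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            length = i - run_start
            if length >= min_y_run and (best_run is None or length >= best_run[0]):
                best_run = (length, run_start)
            run_start = None
    y_patch = (
        (pos_of(best_run[1]), pos_of(best_run[1] + best_run[0] - 1))
        if best_run
        else None
    )

    # --- CAAT -------------------------------------------------------------
    c_lo, c_hi = window_offsets(caat_window)
    caat = caat_kind = None
    best_mm = None  # (mismatches, start_off)
    for i in range(c_lo, c_hi - len(CAAT_PATTERN) + 2):
        if i < 0 or i + len(CAAT_PATTERN) > len(seq):
            continue
        mm = sum(seq[i + k] != CAAT_PATTERN[k] for k in range(len(CAAT_PATTERN)))
        if mm <= 1 and (best_mm is None or mm < best_mm[0] or
                        (mm == best_mm[0] and i > best_mm[1])):
            best_mm = (mm, i)
    if best_mm is not None:
        i = best_mm[1]
        caat = (pos_of(i), pos_of(i + len(CAAT_PATTERN) - 1))
        caat_kind = "canonical" if best_mm[0] == 0 else "hypothetical"

    return CoreElements(tata, y_patch, caat, caat_kind)


# ---------------------------------------------------------------------------
# Motif disruption by allelic variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDisruption:
    hit: MotifHit
    genotype: str
    overlapping_variants: tuple[Variant, ...]
    disruption_kind: str  # "SNP" | "indel" | "both"


def _variant_hits_span(v: Variant, lo: int, hi: int) -> bool:
    """Does the variant's footprint intersect the linearized span [lo, hi]?

    An insertion sits between reference bases and disrupts the motif only
    when the insertion point is strictly inside the span.
    """
    if v.is_insertion:
        x = lin(v.position)
        return lo < x <= hi
    flo, fhi = v.footprint()
    return flo <= hi and fhi >= lo


def detect_disruptions(hits, genotype_variants: dict) -> list[MotifDisruption]:
    """Motif occurrences whose span is hit by >= 1 variant of a genotype.

    ``genotype_variants`` maps genotype labels to variant lists sharing the
    hits' coordinate system.  One record per (hit, genotype) with at least
    one overlapping variant; ``disruption_kind`` reflects the variant kinds
    involved.
    """
    out: list[MotifDisruption] = []
    for hit in hits:
        lo, hi = lin(hit.span[0]), lin(hit.span[1])
        for genotype in sorted(genotype_variants):
            overlapping = tuple(
                v for v in genotype_variants[genotype] if _variant_hits_span(v, lo, hi)
            )
            if not overlapping:
                continue
            kinds = {v.kind for v in overlapping}
            kind = "both" if len(kinds) == 2 else kinds.pop()
            out.append(MotifDisruption(hit, genotype, overlapping, kind))
    return out
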