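"""TSS-anchored coordinate arithmetic and nucleotide alphabet helpers.

Gene positions throughout the package follow the convention used when
annotating promoters against a transcription start site (TSS): the first
transcribed base is +1, the base immediately upstream is -1, and there is
no position 0.  Internally all computation uses 0-based half-open array
offsets; these helpers form the only bridge between the two systems.

The "linearized" scale maps TSS coordinates onto plain integers
(``lin(-1) == 0``, ``lin(+1) == 1``) so that distances and interval logic
can use ordinary arithmetic.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degenerate nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide (possibly degenerate) string."""
    return seq.translate(COMPLEMENT)[::-1]


def lin(pos: int) -> int:
    """Map a no-zero TSS coordinate onto the linear integer scale."""
    if pos == 0:
        raise ValueError("position 0 does not exist in TSS coordinates")
    return pos if pos > 0 else pos + 1


def unlin(x: int) -> int:
    """Inverse of :func:`lin`."""
    return x if x >= 1 else x - 1


def tss_add(pos: int, delta: int) -> int:
    """Shift a TSS coordinate by ``delta`` bases, skipping position 0."""
    return unlin(lin(pos) + delta)


def tss_span(start: int, end: int) -> int:
    """Number of nucleotide positions in the inclusive range [start, end]."""
    n = lin(end) - lin(start) + 1
    if n <= 0:
        raise ValueError(f"empty or inverted span {start}..{end}")
    return n


def tss_to_offset(pos: int, tss_index: int) -> int:
    """Array offset of TSS coordinate ``pos`` given the offset of +1."""
    return tss_index + lin(pos) - 1


def offset_to_tss(offset: int, tss_index: int) -> int:
    """TSS coordinate of array offset ``offset`` given the offset of +1."""
    return unlin(offset - tss_index + 1)


def validate_nucleotides(seq: str, *, name: str = "sequence") -> str:
    """Uppercase ``seq`` and reject non-ACGTN characters."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"{name} contains non-nucleotide characters: {sorted(bad)}")
    return up
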