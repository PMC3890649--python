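"""Independent brute-force oracles used to pin the implementation.

Each oracle is written as a different algorithm from the code under test:
top-down recursion instead of bottom-up tables, explicit enumeration
instead of scanning, exhaustive search instead of greedy placement.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def affine_score_recursive(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Optimal global affine-gap score by memoized top-down recursion.

    States: 0 = last column was a substitution, 1 = gap in b, 2 = gap in a.
    A gap run of length L costs gap_open + L * gap_extend.
    """
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            # only the neutral state exists at the origin; a gap state here
            # would let a run "continue" without ever paying gap_open
            return 0.0 if state == 0 else NEG
        best = NEG
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else -mismatch
            for prev in (0, 1, 2):
                v = f(i - 1, j - 1, prev)
                if state == 0 and v + s > best:
                    best = v + s
        if state == 1 and i > 0:
            cont = f(i - 1, j, 1) - gap_extend
            new = max(f(i - 1, j, 0), f(i - 1, j, 2)) - gap_open - gap_extend
            best = max(cont, new)
        if state == 2 and j > 0:
            cont = f(i, j - 1, 2) - gap_extend
            new = max(f(i, j - 1, 0), f(i, j - 1, 1)) - gap_open - gap_extend
            best = max(cont, new)
        return best

    # state encodes the LAST move; at (0,0) only state 0 is meaningful, so
    # redefine: compute max over end states at (len(a), len(b)).
    return max(f(len(a), len(b), s) for s in (0, 1, 2))


def affine_score_enumerate(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Full enumeration of alignments for very small inputs."""
    best = [float("-inf")]

    def go(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else -mismatch
            go(i + 1, j + 1, score + s, 0)
        if i < len(a):
            cost = gap_extend if last == 1 else gap_open + gap_extend
            go(i + 1, j, score - cost, 1)
        if j < len(b):
            cost = gap_extend if last == 2 else gap_open + gap_extend
            go(i, j + 1, score - cost, 2)

    go(0, 0, 0, 0)
    return best[0]


def expand_pattern(pattern: str):
    """Explicit set of concrete strings matching a degenerate pattern."""
    return {
        "".join(p) for p in itertools.product(*(IUPAC_SETS[c] for c in pattern))
    }


def scan_oracle(seq: str, pattern: str):
    """All (offset, strand) occurrences by expansion + substring search.

    Palindromic patterns are reported on the plus strand only, matching
    the scanner's single-occurrence convention.
    """
    words = expand_pattern(pattern)
    rc_words = {rc(w) for w in words}
    palindromic = words == rc_words
    L = len(pattern)
    out = []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        if w in words:
            out.append((i, "+"))
        if not palindromic and w in rc_words:
            out.append((i, "-"))
    return out


def splice_placements(genomic: str, cdna: str, min_intron: int):
    """All exon placements consistent with GT..AG introns (exhaustive)."""
    results = []

    def go(g, c, exons):
        if c == len(cdna):
            results.append(tuple(exons))
            return
        # try every exon length from here
        n = 0
        while c + n < len(cdna) and g + n < len(genomic) and genomic[g + n] == cdna[c + n]:
            n += 1
            if c + n == len(cdna) and g + n <= len(genomic):
                results.append(tuple(exons + [(g, g + n)]))
        for exon_len in range(1, n + 1):
            donor = g + exon_len
            if genomic[donor : donor + 2] != "GT":
                continue
            for acc_end in range(donor + min_intron, len(genomic) + 1):
                if genomic[acc_end - 2 : acc_end] == "AG":
                    go(acc_end, c + exon_len, exons + [(g, donor)])

    go(0, 0, [])
    # deduplicate; the final-exon case above can double-report
    return sorted(set(results))


def yr_dimers(seq: str):
    """Offsets i (of the purine) where seq[i-1] is a pyrimidine and seq[i]
    a purine."""
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "CT" and seq[i] in "AG"
    ]
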