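"""Pairwise global alignment with affine gap penalties (Gotoh algorithm).

Used to compare full-length haplotype alleles against a reference sequence
before variant extraction.  Scoring is +match for identities, -mismatch for
substitutions, and -(gap_open + L*gap_extend) for a gap run of length L.
Tie-breaking during traceback is deterministic: prefer the diagonal move,
then a gap in ``b`` (consuming a base of ``a``), then a gap in ``a``.

The dynamic program is JIT-compiled with numba when available; a pure
Python fallback keeps the package importable without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

NEG = -(10 ** 12)

__all__ = ["AlignmentScoring", "Alignment", "align_global"]


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment parameters; penalties are stored as non-negative magnitudes."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass(frozen=True)
class Alignment:
    """A global alignment of ``a`` and ``b`` as two gapped strings."""

    aligned_a: str
    aligned_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consumes b)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else -mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            # a gap run may open after a match or directly after the
            # opposite-side gap run (adjacent insertions/deletions)
            xo = M[i - 1, j] - gap_open - gap_extend
            xe = X[i - 1, j] - gap_extend
            xs = Y[i - 1, j] - gap_open - gap_extend
            X[i, j] = max(xo, xe, xs)
            yo = M[i, j - 1] - gap_open - gap_extend
            ye = Y[i, j - 1] - gap_extend
            ys = X[i, j - 1] - gap_open - gap_extend
            Y[i, j] = max(yo, ye, ys)
    return M, X, Y


_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(c, 4) for c in seq], dtype=np.int8)


def align_global(a: str, b: str, scoring: AlignmentScoring | None = None) -> Alignment:
    """Optimal global alignment of ``a`` and ``b`` under ``scoring``.

    Deterministic tie-breaking: diagonal, then gap-in-b, then gap-in-a
    (applied at each traceback step, from the final cell backwards).
    """
    if not a or not b:
        raise ValueError("align_global requires two non-empty sequences")
    sc = scoring or AlignmentScoring()
    a, b = a.upper(), b.upper()
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_fill(ea, eb, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)

    n, m = len(a), len(b)
    i, j = n, m
    # State at the end: prefer M, then X, then Y among co-optimal states.
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    if M[n, m] == score:
        state = 0
    elif X[n, m] == score:
        state = 1
    else:
        state = 2

    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal move into (i, j)
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sc.match if a[i - 1] == b[j - 1] else -sc.mismatch
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = 0
            elif X[i, j] == prev:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in b, consumes a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            # prefer ending the run via a diagonal state, then extending,
            # then switching from the opposite-side gap run
            opened = sc.gap_open + sc.gap_extend
            if M[i - 1, j] - opened == X[i, j]:
                state = 0
            elif X[i - 1, j] - sc.gap_extend == X[i, j]:
                state = 1
            else:
                state = 2
            i -= 1
        else:  # gap in a, consumes b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            opened = sc.gap_open + sc.gap_extend
            if M[i, j - 1] - opened == Y[i, j]:
                state = 0
            elif Y[i, j - 1] - sc.gap_extend == Y[i, j]:
                state = 2
            else:
                state = 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)
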