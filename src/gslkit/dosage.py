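"""Maximum-likelihood allele dosage estimation from clone counts.

In an autotetraploid, an allele present in d of the 4 homologous copies is
expected in d/4 of clones sequenced from a PCR product.  Clone counts
(n_1, ..., n_k) are modelled as multinomial with category probabilities
d_i / ploidy, and the integer dosage vector summing to the ploidy that
maximizes the likelihood is reported.  With counts like 15-of-16 or
10-of-12 for the major allele this recovers the three-plus-one
(triplex/simplex) configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


__all__ = ["CloneCounts", "DosageEstimate", "dosage_loglik", "estimate_dosage",
           "enumerate_dosages"]


@dataclass(frozen=True)
class CloneCounts:
    """Observed clone counts per allele for one gene."""

    gene_id: str
    allele_labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.allele_labels) != len(self.counts):
            raise ValueError("labels and counts differ in length")
        if len(set(self.allele_labels)) != len(self.allele_labels):
            raise ValueError("allele labels must be unique")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.n_total < 1:
            raise ValueError("need at least one clone")

    @property
    def n_total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class DosageEstimate:
    """ML integer copy numbers per allele (summing to the ploidy)."""

    gene_id: str
    allele_labels: tuple[str, ...]
    dosage: tuple[int, ...]
    log_likelihood: float
    alternatives: tuple[tuple[tuple[int, ...], float], ...] = field(repr=False)
    ml_unique: bool = True


def dosage_loglik(counts: CloneCounts, dosage, ploidy: int) -> float:
    """Multinomial log-likelihood (constant term dropped).

    ``sum_i counts_i * ln(dosage_i / ploidy)`` with 0*ln(0) := 0; returns
    -inf when an observed allele is assigned zero copies.
    """
    dosage = tuple(dosage)
    if len(dosage) != len(counts.counts):
        raise ValueError("dosage length must match the number of alleles")
    if sum(dosage) != ploidy:
        raise ValueError(f"dosage must sum to the ploidy ({ploidy})")
    ll = 0.0
    for c, d in zip(counts.counts, dosage):
        if c == 0:
            continue
        if d == 0:
            return -math.inf
        ll += c * math.log(d / ploidy)
    return ll


def enumerate_dosages(k: int, ploidy: int, min_copies: int = 1):
    """All integer vectors of length k with entries >= min_copies summing
    to the ploidy, in lexicographic order."""
    if k == 1:
        if ploidy >= min_copies:
            yield (ploidy,)
        return
    for first in range(min_copies, ploidy - min_copies * (k - 1) + 1):
        for rest in enumerate_dosages(k - 1, ploidy - first, min_copies):
            yield (first,) + rest


def estimate_dosage(
    counts: CloneCounts, ploidy: int = 4, min_copies: int = 1
) -> DosageEstimate:
    """Exhaustive-enumeration ML dosage estimate.

    Every vector with entries >= ``min_copies`` summing to ``ploidy`` is
    scored; co-maximal vectors are reported via ``ml_unique=False`` with
    the lexicographically smallest returned as the point estimate.
    """
    k = len(counts.counts)
    if min_copies * k > ploidy:
        raise ValueError(
            f"{k} observed alleles cannot each have >= {min_copies} copies "
            f"at ploidy {ploidy}"
        )
    scored = [
        (d, dosage_loglik(counts, d, ploidy))
        for d in enumerate_dosages(k, ploidy, min_copies)
    ]
    if not scored:
        raise ValueError("no feasible dosage vector")
    best_ll = max(ll for _d, ll in scored)
    # ties detected with a tolerance: permuted dosage vectors accumulate
    # identical log terms in different orders
    winners = [
        d for d, ll in scored
        if ll == best_ll or math.isclose(ll, best_ll, rel_tol=1e-12, abs_tol=1e-12)
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return DosageEstimate(
        gene_id=counts.gene_id,
        allele_labels=counts.allele_labels,
        dosage=winners[0],
        log_likelihood=best_ll,
        alternatives=tuple(scored),
        ml_unique=len(winners) == 1,
    )
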