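"""Per-region variant accounting and expression comparison.

Reproduces the feature-by-feature conservation statistic used for these
genes: for each annotated region, the number of indel events, the number
of SNPs, and the SNP frequency expressed as nucleotides per SNP
(region size / SNP count, one decimal, half away from zero; rendered "-"
when the region holds no SNP).  Aggregates over a set of regions (e.g.
all exons) report an integer nucleotides-per-SNP the same way.

Expression comparison consumes per-library FPKM tables and counts, per
library, which of two genes is expressed higher (strict comparison, zero
FPKM participating as the value 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .coords import lin
from .genemodel import GeneRegion
from .variants import Variant

__all__ = [
    "RegionVariantSummary",
    "ExpressionRecord",
    "ComparisonSummary",
    "summarize_regions",
    "aggregate_frequency",
    "compare_expression",
]


@dataclass(frozen=True)
class RegionVariantSummary:
    """One row of the per-region accounting."""

    region: GeneRegion
    n_indels: int
    n_snps: int

    @property
    def nts_per_snp(self) -> Decimal | None:
        """Region size / SNP count, one decimal, half away from zero."""
        if self.n_snps == 0:
            return None
        return (Decimal(self.region.size) / Decimal(self.n_snps)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )

    @property
    def nts_per_snp_str(self) -> str:
        v = self.nts_per_snp
        return "-" if v is None else str(v)


def summarize_regions(variants, regions) -> list[RegionVariantSummary]:
    """Partition a variant table over annotated regions.

    Each variant is assigned to the region holding its first affected
    reference base (indels included); a variant outside every region is an
    error naming the position.
    """
    spans = [(lin(r.start), lin(r.end)) for r in regions]
    n_snps = [0] * len(regions)
    n_indels = [0] * len(regions)
    for v in variants:
        x = lin(v.position)
        for i, (lo, hi) in enumerate(spans):
            if lo <= x <= hi:
                if v.kind == "SNP":
                    n_snps[i] += 1
                else:
                    n_indels[i] += 1
                break
        else:
            raise ValueError(f"variant at position {v.position} falls outside all regions")
    return [
        RegionVariantSummary(r, n_indels[i], n_snps[i]) for i, r in enumerate(regions)
    ]


def aggregate_frequency(summaries, labels) -> int | None:
    """Integer nucleotides/SNP aggregated over regions selected by label.

    A label selects regions whose label equals it or whose first word
    equals it (so ``{"exon"}`` selects "exon 1", "exon 2", ...).  Rounding
    is half away from zero; None when the selected regions hold no SNP.
    """
    labels = set(labels)
    chosen = [
        s for s in summaries
        if s.region.label in labels or s.region.label.split()[0] in labels
    ]
    if not chosen:
        raise ValueError(f"labels {sorted(labels)} select no region")
    total_size = sum(s.region.size for s in chosen)
    total_snps = sum(s.n_snps for s in chosen)
    if total_snps == 0:
        return None
    return int(
        (Decimal(total_size) / Decimal(total_snps)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# FPKM comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    library_id: str
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"negative FPKM for {self.gene_id} in {self.library_id}")


@dataclass(frozen=True)
class ComparisonSummary:
    gene_a: str
    gene_b: str
    n_a_higher: int
    n_b_higher: int
    n_tied: int
    libraries: tuple[tuple[str, float, float], ...]  # (library, fpkm_a, fpkm_b)

    @property
    def n_libraries(self) -> int:
        return self.n_a_higher + self.n_b_higher + self.n_tied


def compare_expression(records, gene_a: str, gene_b: str) -> ComparisonSummary:
    """Per-library strict FPKM comparison of two genes.

    Both genes must be present in every library mentioned; a library
    missing either gene is an error naming the library.
    """
    table: dict[str, dict[str, float]] = {}
    for r in records:
        table.setdefault(r.library_id, {})[r.gene_id] = r.fpkm
    rows = []
    n_a = n_b = n_t = 0
    for lib in sorted(table):
        vals = table[lib]
        for g in (gene_a, gene_b):
            if g not in vals:
                raise ValueError(f"library {lib!r} has no FPKM for gene {g!r}")
        fa, fb = vals[gene_a], vals[gene_b]
        if fa > fb:
            n_a += 1
        elif fb > fa:
            n_b += 1
        else:
            n_t += 1
        rows.append((lib, fa, fb))
    return ComparisonSummary(gene_a, gene_b, n_a, n_b, n_t, tuple(rows))
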