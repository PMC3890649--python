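"""Built-in gene presets: GSL1- and GSL2-like synthetic gene definitions.

The two presets emulate the published feature layout of the potato GSL1
(Snakin-1) and GSL2 (Snakin-2) genes on the DM reference genotype:

* region sizes and per-region SNP/indel counts of the published
  feature-by-feature polymorphism accounting,
* the full printed inventories of key promoter motif occurrences
  (42 occurrences of 8 motifs for GSL1; 15 occurrences of 11 motifs for
  GSL2), planted at their printed TSS coordinates and strands,
* core promoter elements (TATA box, pyrimidine patch, CAAT box) at their
  annotated positions, and a YR dinucleotide at the TSS.

Everything here is synthetic sequence built around those published
coordinates -- no accession data is shipped or required.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MotifOccurrence",
    "GSL1_MOTIF_OCCURRENCES",
    "GSL2_MOTIF_OCCURRENCES",
    "GSL1_REGION_SCHEME",
    "GSL2_REGION_SCHEME",
    "GSL1_CORE_ELEMENTS",
    "GSL2_CORE_ELEMENTS",
    "gene_model_spec",
    "region_variant_counts",
    "PRESETS",
]


@dataclass(frozen=True)
class MotifOccurrence:
    """One printed motif occurrence: coordinates follow the motif's own
    5'->3' orientation, so minus-strand rows have start > end."""

    motif_id: str
    matched: str  # concrete sequence, motif orientation
    start: int
    end: int
    strand: str


def _occ(rows):
    return tuple(MotifOccurrence(*r) for r in rows)


# Printed motif inventory of the GSL1 promoter (8 motifs, 42 occurrences).
GSL1_MOTIF_OCCURRENCES = _occ([
    ("BIHD1OS", "TGTCA", -1024, -1028, "-"),
    ("BIHD1OS", "TGTCA", -878, -874, "+"),
    ("BIHD1OS", "TGTCA", -873, -869, "+"),
    ("BIHD1OS", "TGTCA", -385, -389, "-"),
    ("BIHD1OS", "TGTCA", -110, -106, "+"),
    ("GT1GMSCAM4", "GAAAAA", -1678, -1673, "+"),
    ("GT1GMSCAM4", "GAAAAA", -1069, -1064, "+"),
    ("GT1GMSCAM4", "GAAAAA", -918, -923, "-"),
    ("GT1GMSCAM4", "GAAAAA", -826, -821, "+"),
    ("GT1GMSCAM4", "GAAAAA", -706, -701, "+"),
    ("GT1GMSCAM4", "GAAAAA", -505, -500, "+"),
    ("IBOXCORE", "GATAA", -1834, -1838, "-"),
    ("IBOXCORE", "GATAA", -1545, -1541, "+"),
    ("IBOXCORE", "GATAA", -1483, -1487, "-"),
    ("IBOXCORE", "GATAA", -1463, -1459, "+"),
    ("IBOXCORE", "GATAA", -1242, -1238, "+"),
    ("IBOXCORE", "GATAA", -1121, -1117, "+"),
    ("IBOXCORE", "GATAA", -1109, -1105, "+"),
    ("IBOXCORE", "GATAA", -834, -830, "+"),
    ("IBOXCORE", "GATAA", -537, -541, "-"),
    ("IBOXCORE", "GATAA", -235, -239, "-"),
    ("IBOXCORE", "GATAA", -117, -121, "-"),
    ("MYB1AT", "AAACCA", -1927, -1922, "+"),
    ("MYB1AT", "AAACCA", -703, -698, "+"),
    ("MYB1AT", "TAACCA", -173, -168, "+"),
    ("MYB1AT", "AAACCA", -15, -10, "+"),
    ("MYBST1", "GGATA", -1556, -1552, "+"),
    ("MYBST1", "GGATA", -1299, -1303, "-"),
    ("MYBST1", "GGATA", -1122, -1118, "+"),
    ("MYBST1", "GGATA", -835, -831, "+"),
    ("MYBST1", "GGATA", -116, -120, "-"),
    ("RAV1AAT", "CAACA", -1834, -1830, "+"),
    ("RAV1AAT", "CAACA", -1320, -1316, "+"),
    ("RAV1AAT", "CAACA", -1242, -1246, "-"),
    ("RAV1AAT", "CAACA", -981, -977, "+"),
    ("RAV1AAT", "CAACA", -339, -335, "+"),
    ("RAV1AAT", "CAACA", -281, -285, "-"),
    ("RAV1AAT", "CAACA", -169, -165, "+"),
    ("SREATMSD", "TTATCC", -1117, -1122, "-"),
    ("SREATMSD", "TTATCC", -830, -835, "-"),
    ("SREATMSD", "TTATCC", -121, -116, "+"),
    ("WUSATAg", "TTAATGG", -15, -21, "-"),
])

# Printed motif inventory of the GSL2 promoter (11 motifs, 15 occurrences).
GSL2_MOTIF_OCCURRENCES = _occ([
    ("MYBPLANT", "CACCTACC", -353, -346, "+"),
    ("RYREPEATVFLEB4", "CATGCATG", -182, -175, "+"),
    ("SURE1STPAT21", "AATAGAAAA", -101, -109, "-"),
    ("CPBCSPOR", "TATTAG", -310, -315, "-"),
    ("GT1GMSCAM4", "GAAAAA", -273, -278, "-"),
    ("GT1GMSCAM4", "GAAAAA", -193, -188, "+"),
    ("GT1GMSCAM4", "GAAAAA", -143, -148, "-"),
    ("GT1GMSCAM4", "GAAAAA", -105, -110, "-"),
    ("GT1GMSCAM4", "GAAAAA", -21, -26, "-"),
    ("MYBGAHV", "TAACAAA", -467, -473, "-"),
    ("MYBST1", "GGATA", -437, -433, "+"),
    ("NTBBF1ARROLB", "ACTTTA", -374, -369, "+"),
    ("SREATMSD", "TTATCC", -432, -437, "-"),
    ("WBOXHVISO1", "TGACT", -13, -17, "-"),
    ("WUSATAg", "TTAATGG", -224, -230, "-"),
])

# Feature scheme rows: (label, start, end, n_indels, n_snps) following the
# published per-region accounting (promoter binned at 500 nt for GSL1).
GSL1_REGION_SCHEME = (
    ("promoter", -1960, -1501, 6, 18),
    ("promoter", -1500, -1001, 9, 14),
    ("promoter", -1000, -501, 9, 18),
    ("promoter", -500, -1, 10, 13),
    ("5'UTR", 1, 33, 0, 1),
    ("exon 1", 34, 115, 0, 2),
    ("intron", 116, 619, 16, 24),
    ("exon 2", 620, 804, 0, 2),
    ("3'UTR", 805, 1009, 3, 5),
)

GSL2_REGION_SCHEME = (
    ("promoter", -590, -1, 6, 12),
    ("5'UTR", 1, 38, 1, 0),
    ("exon 1", 39, 125, 0, 1),
    ("intron 1", 126, 374, 2, 7),
    ("exon 2", 375, 420, 0, 1),
    ("intron 2", 421, 583, 5, 5),
    ("exon 3", 584, 765, 0, 4),
    ("3'UTR", 766, 1067, 7, 6),
)

# Core promoter elements: (name, start, end, concrete planted sequence).
GSL1_CORE_ELEMENTS = (
    ("tata", -32, -27, "TATAAA"),
    ("y_patch", -26, -20, "TTCTTCC"),
    ("caat", -48, -44, "CCAAT"),
)
GSL2_CORE_ELEMENTS = (
    ("tata", -50, -45, "TATAAA"),
    ("y_patch", -59, -51, "CTTCTCTTC"),
    ("caat", -65, -61, "CCATT"),  # 'hypothetical': one mismatch from CCAAT
)


def region_variant_counts(gene: str):
    """Per-region (n_snps, n_indels) for a preset, keyed by (start, end)."""
    scheme = {"gsl1": GSL1_REGION_SCHEME, "gsl2": GSL2_REGION_SCHEME}[gene.lower()]
    return {(s, e): (n_snps, n_indels) for (_lbl, s, e, n_indels, n_snps) in scheme}


def gene_model_spec(gene: str, seed: int = 0):
    """GeneModelSpec for a preset (import cycle avoided by late import)."""
    from .simulate import GeneModelSpec

    g = gene.lower()
    if g == "gsl1":
        return GeneModelSpec(
            gene_id="GSL1",
            region_lengths=(
                ("promoter", 1960), ("5'UTR", 33), ("exon 1", 82),
                ("intron", 504), ("exon 2", 185), ("3'UTR", 205),
            ),
            planted_motifs=GSL1_MOTIF_OCCURRENCES,
            planted_core_elements=GSL1_CORE_ELEMENTS,
            motif_library="gsl1",
            seed=seed,
        )
    if g == "gsl2":
        return GeneModelSpec(
            gene_id="GSL2",
            region_lengths=(
                ("promoter", 590), ("5'UTR", 38), ("exon 1", 87),
                ("intron 1", 249), ("exon 2", 46), ("intron 2", 163),
                ("exon 3", 182), ("3'UTR", 302),
            ),
            planted_motifs=GSL2_MOTIF_OCCURRENCES,
            planted_core_elements=GSL2_CORE_ELEMENTS,
            motif_library="gsl2",
            seed=seed,
        )
    raise KeyError(f"unknown preset {gene!r} (expected 'gsl1' or 'gsl2')")


#: indel length ranges observed between the cloned allele pairs.
PRESETS = {
    "gsl1": {"indel_length_range": (1, 7), "promoter_bin_size": 500, "dosage": (3, 1)},
    "gsl2": {"indel_length_range": (1, 18), "promoter_bin_size": None, "dosage": (3, 1)},
}
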