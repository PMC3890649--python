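"""File formats: FASTA, the reads-TSV dialect, variant/region/motif/FPKM
tables, and packaged motif libraries.

All user-facing coordinates are TSS-style (1-based inclusive, no position
0, negative promoter); conversion to internal 0-based offsets happens in
the library, never in files.  Every emitted TSV begins with comment lines
carrying the tool version, a configuration hash and the seed, so reruns
with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import validate_nucleotides
from .genemodel import GeneRegion
from .promoter import MotifDef
from .regionstats import ExpressionRecord
from .variants import AlignedRead, Variant

log = logging.getLogger("gslkit")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_variants_tsv",
    "write_variants_tsv",
    "write_regions_tsv",
    "read_regions_tsv",
    "read_motif_library",
    "load_packaged_motif_library",
    "read_fpkm_tsv",
    "write_fpkm_tsv",
    "write_summaries_tsv",
    "read_summaries_tsv",
    "summaries_frame",
    "write_hits_tsv",
    "diff_allele_fasta",
    "file_header",
]

_PHRED_OFFSET = 33


def file_header(*, seed=None, config: dict | None = None) -> list[str]:
    """Comment header lines: tool version, config hash, seed."""
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return [
        f"# gslkit {__version__}",
        f"# config_hash={digest} seed={seed}",
    ]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a nucleotide FASTA into an ordered id -> sequence mapping.

    Duplicate ids and non-nucleotide characters are errors; mixed-case
    input is uppercased (logged).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        raw = str(rec.seq)
        if raw != raw.upper():
            log.info("uppercasing mixed-case sequence %s", rec.id)
        out[rec.id] = validate_nucleotides(raw, name=f"record {rec.id}")
    return out


def write_fasta(records: dict[str, str], path) -> None:
    """Write id -> sequence records as 60-column-wrapped FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path, *, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        for line in file_header(seed=seed, config=config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    # skip only the leading comment header: '#' is a legal character inside
    # data fields (e.g. phred-33 quality strings)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    return pd.read_csv(path, sep="\t", skiprows=n_header, **kwargs)


# ---------------------------------------------------------------------------
# Reads dialect: read_id, start, strand, sequence, phred33, unique_flag
# ---------------------------------------------------------------------------

def write_reads_tsv(reads, path, *, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "start": [r.start for r in reads],
            "strand": [r.strand for r in reads],
            "sequence": [r.sequence for r in reads],
            "phred33": [
                "".join(chr(q + _PHRED_OFFSET) for q in r.qualities) for r in reads
            ],
            "unique_flag": [int(r.unique) for r in reads],
        }
    )
    _write_tsv(df, path, seed=seed, config=config)


def read_reads_tsv(path) -> list[AlignedRead]:
    df = _read_tsv(path, dtype={"read_id": str, "sequence": str, "phred33": str})
    return [
        AlignedRead(
            row.read_id,
            int(row.start),
            row.strand,
            row.sequence,
            tuple(ord(c) - _PHRED_OFFSET for c in row.phred33),
            bool(int(row.unique_flag)),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Variant tables (VCF-lite TSV)
# ---------------------------------------------------------------------------

def write_variants_tsv(variants, path, *, gene_id: str, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {
            "CHROM": gene_id,
            "POS": [v.position for v in variants],
            "REF": [v.ref_allele for v in variants],
            "ALT": [v.alt_allele for v in variants],
            "KIND": [v.kind for v in variants],
            "LEN": [v.length for v in variants],
            "CARRIERS": [",".join(sorted(v.carriers)) for v in variants],
        }
    )
    _write_tsv(df, path, seed=seed, config=config)


def read_variants_tsv(path) -> list[Variant]:
    df = _read_tsv(path, dtype={"REF": str, "ALT": str, "CARRIERS": str})
    out = []
    for row in df.itertuples():
        carriers = frozenset(
            c for c in str(row.CARRIERS).split(",") if c and c != "nan"
        )
        out.append(Variant(int(row.POS), row.KIND, row.REF, row.ALT, carriers))
    return out


# ---------------------------------------------------------------------------
# Regions / structure (GFF3-like TSV)
# ---------------------------------------------------------------------------

def write_regions_tsv(regions, path, *, gene_id: str, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {
            "seqid": gene_id,
            "feature": [r.label for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "size": [r.size for r in regions],
            "strand": "+",
        }
    )
    _write_tsv(df, path, seed=seed, config=config)


def read_regions_tsv(path) -> list[GeneRegion]:
    df = _read_tsv(path)
    return [GeneRegion(row.feature, int(row.start), int(row.end)) for row in df.itertuples()]


# ---------------------------------------------------------------------------
# Motif libraries
# ---------------------------------------------------------------------------

def read_motif_library(path) -> list[MotifDef]:
    df = _read_tsv(path, dtype=str)
    return [
        MotifDef(row.motif_id, row.pattern, getattr(row, "function_note", "") or "")
        for row in df.itertuples()
    ]


def load_packaged_motif_library(name: str) -> list[MotifDef]:
    """Load one of the shipped libraries ('gsl1' or 'gsl2')."""
    fname = f"{name.lower()}_motifs.tsv"
    ref = resources.files("gslkit.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return read_motif_library(p)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_summaries_tsv(summaries, path, *, seed=None, config=None) -> None:
    """Per-region summary TSV mirroring the published column order."""
    df = summaries_frame(summaries)
    _write_tsv(df, path, seed=seed, config=config)


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Region": [s.region.label for s in summaries],
            "Nucleotide position": [
                f"{s.region.start} to {s.region.end}" for s in summaries
            ],
            "Size": [s.region.size for s in summaries],
            "Number of indels": [s.n_indels for s in summaries],
            "Number of SNPs": [s.n_snps for s in summaries],
            "SNP frequency (nucleotides/SNP)": [s.nts_per_snp_str for s in summaries],
        }
    )


def read_summaries_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, dtype={"SNP frequency (nucleotides/SNP)": str})


def write_hits_tsv(hits, path, *, seed=None, config=None) -> None:
    """Motif hits in both the motif-orientation and normalized coordinates."""
    df = pd.DataFrame(
        {
            "motif_id": [h.motif_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "matched": [h.matched for h in hits],
            "span_lo": [h.span[0] for h in hits],
            "span_hi": [h.span[1] for h in hits],
        }
    )
    _write_tsv(df, path, seed=seed, config=config)


def diff_allele_fasta(path_a, path_b, scoring=None) -> tuple[int, int, list[int]]:
    """SNP/indel tally between two locally supplied single-record FASTAs.

    Intended for allele pairs such as the deposited a1/a2 or b1/b2 clones;
    no download is attempted -- a missing file raises FileNotFoundError.
    Returns (n_snps, n_indels, indel lengths).
    """
    for p in (path_a, path_b):
        if not Path(p).exists():
            raise FileNotFoundError(
                f"allele FASTA {p} not supplied; this comparison needs local files"
            )
    a = next(iter(read_fasta(path_a).values()))
    b = next(iter(read_fasta(path_b).values()))
    from .variants import diff_haplotype

    variants = diff_haplotype(a, b)
    n_snps = sum(v.kind == "SNP" for v in variants)
    indels = [v.length for v in variants if v.kind == "indel"]
    return n_snps, len(indels), sorted(indels)


def read_fpkm_tsv(path) -> list[ExpressionRecord]:
    df = _read_tsv(path, dtype={"library_id": str, "gene_id": str})
    return [
        ExpressionRecord(row.library_id, row.gene_id, float(row.fpkm))
        for row in df.itertuples()
    ]


def write_fpkm_tsv(records, path, *, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {
            "library_id": [r.library_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "fpkm": [r.fpkm for r in records],
        }
    )
    _write_tsv(df, path, seed=seed, config=config)
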