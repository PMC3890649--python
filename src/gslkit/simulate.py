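"""Synthetic data generation: gene models, haplotypes, reads, clone counts.

The generator builds a synthetic gene with the layout the analysis assumes
(promoter, 5'UTR, GT..AG introns, exons, 3'UTR, TSS-anchored coordinates),
plants promoter motifs and core elements at declared coordinates, derives
up to four haplotypes per (auto)tetraploid genotype with per-region SNP and
indel counts, simulates placed short reads with phred qualities at a target
coverage, and draws clone counts from allele-dosage proportions.  Ground
truth for every planted feature is returned alongside.

Design choices that make truth/called comparisons exact rather than
alignment-dependent: variant footprints are planted at least two free bases
apart, and indels are placed so that their gap placement is unambiguous
(the flanking context blocks left or right shifts).  The reference
haplotype (index 0) is always unmutated.

When a motif library is attached to the spec, the builder additionally
"scrubs" the background so that scanning the finished reference yields
exactly the planted occurrences: chance occurrences of library patterns,
stray TATA consensus matches near the TSS, near-CCAAT matches in the CAAT
search window, and competing pyrimidine tracts are removed by point
mutations of non-planted bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import IUPAC, PYRIMIDINES, lin, tss_add, revcomp
from .genemodel import GeneModel, GeneRegion, GeneStructure
from .promoter import CAAT_PATTERN, TATA_PATTERN, MotifDef, scan_motifs, _matches_at
from .variants import AlignedRead, Variant, apply_variants

__all__ = [
    "GeneModelSpec",
    "TruthRecord",
    "ReadSimConfig",
    "build_reference",
    "spawn_haplotypes",
    "simulate_reads",
    "sample_clones",
    "read_source_haplotype",
    "planted_snp_support",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneModelSpec:
    """Recipe for a synthetic gene model.

    ``region_lengths`` orders the features 5'->3': a promoter, a 5'UTR,
    alternating exons/introns, and a 3'UTR.  Planted motifs and core
    elements are given in TSS coordinates; overlapping planted features
    are accepted only where they agree on every shared base.
    """

    gene_id: str
    region_lengths: tuple[tuple[str, int], ...]
    planted_motifs: tuple = ()
    planted_core_elements: tuple = ()
    gc_fraction: float = 0.38
    seed: int = 0
    motif_library: object = None  # preset name, list[MotifDef], or None
    scrub: bool = True

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _n in self.region_lengths]
        if any(n <= 0 for _lbl, n in self.region_lengths):
            raise ValueError("region lengths must be positive")
        if labels[0] != "promoter" or labels[1] != "5'UTR":
            raise ValueError("layout must start with promoter, 5'UTR")
        if labels[-1] != "3'UTR":
            raise ValueError("layout must end with 3'UTR")
        inner = labels[2:-1]
        if not inner or not inner[0].startswith("exon") or not inner[-1].startswith("exon"):
            raise ValueError("transcribed core must start and end with an exon")
        for a, b in zip(inner, inner[1:]):
            if a.split()[0] == b.split()[0]:
                raise ValueError("exons and introns must alternate")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")

    @property
    def utr5_length(self) -> int:
        return dict(self.region_lengths)["5'UTR"]

    @property
    def atg_pos(self) -> int:
        return self.utr5_length + 1


@dataclass
class TruthRecord:
    """Ground truth emitted next to every synthetic dataset."""

    variants: list[Variant] = field(default_factory=list)
    dosage: tuple[int, ...] | None = None
    motifs: tuple = ()
    core_elements: tuple = ()

    def __post_init__(self) -> None:
        if self.dosage is not None and any(d < 0 for d in self.dosage):
            raise ValueError("dosage entries must be >= 0")

    def snps(self) -> list[Variant]:
        return [v for v in self.variants if v.kind == "SNP"]

    def indels(self) -> list[Variant]:
        return [v for v in self.variants if v.kind == "indel"]


def _resolve_library(spec: GeneModelSpec):
    lib = spec.motif_library
    if lib is None:
        return None
    if isinstance(lib, str):
        from .io import load_packaged_motif_library

        return load_packaged_motif_library(lib)
    return list(lib)


class _Canvas:
    """Mutable sequence with per-base ownership and zone alphabets."""

    def __init__(self, seq: list[str], rng: np.random.Generator):
        self.seq = seq
        self.owner: list[str | None] = [None] * len(seq)
        self.zone: list[str] = ["ACGT"] * len(seq)
        self.rng = rng

    def plant(self, name: str, offset: int, bases: str) -> None:
        if offset < 0 or offset + len(bases) > len(self.seq):
            raise ValueError(f"planted feature {name} falls outside the sequence")
        for k, b in enumerate(bases):
            o = offset + k
            prev = self.owner[o]
            if prev is not None and self.seq[o] != b:
                raise ValueError(
                    f"planted features overlap inconsistently: {prev} vs {name} "
                    f"at offset {o} ({self.seq[o]} vs {b})"
                )
            self.seq[o] = b
            if prev is None:
                self.owner[o] = name

    def mutable(self, offset: int) -> bool:
        return self.owner[offset] is None

    def mutate_window(self, lo: int, length: int, forbidden_per_slot) -> bool:
        """Break a pattern occurrence at window [lo, lo+length).

        ``forbidden_per_slot(k)`` gives the base set slot ``k`` must avoid
        to break the match.  Returns True when a mutation was applied.
        """
        order = list(self.rng.permutation(length))
        for k in order:
            o = lo + k
            if not self.mutable(o):
                continue
            choices = [b for b in self.zone[o] if b not in forbidden_per_slot(k) and b != self.seq[o]]
            if choices:
                self.seq[o] = choices[int(self.rng.integers(len(choices)))]
                return True
        return False


def _fill_pyrimidines(canvas: _Canvas, lo: int, hi: int, *, max_t_run: int = 4) -> None:
    """Soft pyrimidine fill for [lo, hi); avoids runs of > max_t_run T's."""
    t_run = 0
    for o in range(lo, hi):
        if not canvas.mutable(o):
            t_run = t_run + 1 if canvas.seq[o] == "T" else 0
            continue
        if t_run >= max_t_run:
            base = "C"
        else:
            base = "T" if canvas.rng.random() < 0.5 else "C"
        canvas.seq[o] = base
        canvas.zone[o] = "CT"
        t_run = t_run + 1 if base == "T" else 0


def build_reference(spec: GeneModelSpec) -> GeneModel:
    """Construct the reference GeneModel for ``spec``.

    The returned model contains every planted motif and core element at
    its declared TSS coordinate, GT..AG introns, an ATG at the start of
    exon 1, a stop codon at the end of the last exon, and a TG (YR)
    dinucleotide across the TSS.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.region_lengths)
    promoter_len = lengths["promoter"]
    total = sum(n for _lbl, n in spec.region_lengths)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = [_BASES[i] for i in rng.choice(4, size=total, p=probs)]
    canvas = _Canvas(seq, rng)
    tss_index = promoter_len

    def off(pos: int) -> int:
        return tss_index + lin(pos) - 1

    # Fixed anatomy ---------------------------------------------------------
    canvas.plant("TSS YR dinucleotide", tss_index - 1, "TG")
    atg_off = tss_index + spec.utr5_length
    canvas.plant("start codon", atg_off, "ATG")
    _fill_pyrimidines(canvas, tss_index + 1, atg_off)

    # Region boundaries and structure.
    regions: list[GeneRegion] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    cursor = 0
    for lbl, n in spec.region_lengths:
        start_off, end_off = cursor, cursor + n
        if lbl.startswith("exon"):
            exons.append((start_off, end_off))
        elif lbl.startswith("intron"):
            introns.append((start_off, end_off))
            canvas.plant(f"{lbl} donor GT", start_off, "GT")
            canvas.plant(f"{lbl} acceptor AG", end_off - 2, "AG")
        cursor = end_off
    canvas.plant("stop codon", exons[-1][1] - 3, "TAA")

    # Planted promoter features --------------------------------------------
    for occ in spec.planted_motifs:
        s, e = (occ.end, occ.start) if occ.strand == "-" else (occ.start, occ.end)
        image = occ.matched if occ.strand == "+" else revcomp(occ.matched)
        if len(image) != lin(e) - lin(s) + 1:
            raise ValueError(f"motif {occ.motif_id} at {occ.start}: span/sequence length mismatch")
        name = f"motif {occ.motif_id}@{occ.start}{occ.strand}"
        canvas.plant(name, off(s), image)
    for name, s, e, image in spec.planted_core_elements:
        if len(image) != lin(e) - lin(s) + 1:
            raise ValueError(f"core element {name}: span/sequence length mismatch")
        canvas.plant(f"core {name}", off(s), image)

    library = _resolve_library(spec)
    if spec.scrub and library is not None:
        _scrub(canvas, spec, library, tss_index)

    regions = []
    cursor = 0
    for lbl, n in spec.region_lengths:
        start_pos = lin_pos(cursor - tss_index)
        end_pos = lin_pos(cursor + n - 1 - tss_index)
        regions.append(GeneRegion(lbl, start_pos, end_pos))
        cursor += n

    model = GeneModel(
        gene_id=spec.gene_id,
        sequence="".join(canvas.seq),
        tss_index=tss_index,
        atg_pos=spec.atg_pos,
        regions=regions,
        structure=GeneStructure(exons=tuple(exons), introns=tuple(introns)),
    )
    _verify_planted(model, spec)
    return model


def lin_pos(delta: int) -> int:
    """TSS coordinate of the base ``delta`` linear steps from +1."""
    from .coords import unlin

    return unlin(1 + delta)


def _verify_planted(model: GeneModel, spec: GeneModelSpec) -> None:
    for occ in spec.planted_motifs:
        s, e = (occ.end, occ.start) if occ.strand == "-" else (occ.start, occ.end)
        got = model.subseq(s, e)
        want = occ.matched if occ.strand == "+" else revcomp(occ.matched)
        if got != want:
            raise AssertionError(f"planted motif {occ.motif_id}@{occ.start} lost: {got}")


def _scrub(canvas: _Canvas, spec: GeneModelSpec, library, tss_index: int) -> None:
    """Point-mutate non-planted bases until the reference scans clean."""
    anchor = lin_pos(-tss_index)
    allowed_hits = {
        (occ.motif_id, occ.start, occ.end, occ.strand) for occ in spec.planted_motifs
    }
    core = {name: (s, e, image) for name, s, e, image in spec.planted_core_elements}

    def off(pos: int) -> int:
        return tss_index + lin(pos) - 1

    for _round in range(100):
        dirty = False
        seq = "".join(canvas.seq)

        # 1. chance occurrences of library motifs anywhere in the sequence
        for hit in scan_motifs(seq, library, anchor=anchor):
            if (hit.motif_id, hit.start, hit.end, hit.strand) in allowed_hits:
                continue
            pat = next(m.pattern for m in library if m.motif_id == hit.motif_id)
            if hit.strand == "-":
                pat = revcomp(pat)
            lo = off(hit.span[0])
            if not canvas.mutate_window(lo, len(pat), lambda k: IUPAC[pat[k]]):
                raise ValueError(
                    f"cannot scrub chance {hit.motif_id} occurrence at {hit.span}"
                )
            dirty = True
            break  # re-scan after each fix
        if dirty:
            continue

        # 2. stray TATA consensus in the core-element search window
        dirty |= _scrub_pattern_window(
            canvas, seq, tss_index, TATA_PATTERN,
            window=(-60, -20), keep=core.get("tata"),
        )
        if dirty:
            continue

        # 3. near-CCAAT matches in the CAAT search window
        dirty |= _scrub_caat(canvas, seq, tss_index, keep=core.get("caat"))
        if dirty:
            continue

        # 4. pyrimidine tracts that would outcompete the planted Y patch
        dirty |= _scrub_y_runs(canvas, seq, tss_index, core)
        if not dirty:
            return
    raise ValueError("background scrub did not converge")


def _window_offsets(tss_index: int, window: tuple[int, int]) -> tuple[int, int]:
    return tss_index + lin(window[0]) - 1, tss_index + lin(window[1]) - 1


def _scrub_pattern_window(canvas, seq, tss_index, pattern, *, window, keep) -> bool:
    lo_off, hi_off = _window_offsets(tss_index, window)
    keep_off = None if keep is None else tss_index + lin(keep[0]) - 1
    L = len(pattern)
    for i in range(max(lo_off, 0), min(hi_off - L + 2, len(seq) - L + 1)):
        if i == keep_off or not _matches_at(seq, i, pattern):
            continue
        if not canvas.mutate_window(i, L, lambda k: IUPAC[pattern[k]]):
            raise ValueError(f"cannot scrub stray {pattern} at offset {i}")
        return True
    return False


def _scrub_caat(canvas, seq, tss_index, *, keep) -> bool:
    lo_off, hi_off = _window_offsets(tss_index, (-80, -30))
    keep_off = None if keep is None else tss_index + lin(keep[0]) - 1
    L = len(CAAT_PATTERN)
    for i in range(max(lo_off, 0), min(hi_off - L + 2, len(seq) - L + 1)):
        if i == keep_off:
            continue
        mism = [k for k in range(L) if seq[i + k] != CAAT_PATTERN[k]]
        if len(mism) > 1:
            continue
        # Mutate a currently-matching slot so the window has >= 2 mismatches.
        if not canvas.mutate_window(i, L, lambda k: (
            {CAAT_PATTERN[k]} if k not in mism else set("ACGT")
        )):
            raise ValueError(f"cannot scrub near-CCAAT at offset {i}")
        return True
    return False


def _scrub_y_runs(canvas, seq, tss_index, core) -> bool:
    """Break pyrimidine runs that would beat the planted Y patch."""
    y_keep = core.get("y_patch")
    lo_off, hi_off = _window_offsets(tss_index, (-60, -10))
    tata = core.get("tata")
    tata_offs = (
        set(range(tss_index + lin(tata[0]) - 1, tss_index + lin(tata[1])))
        if tata
        else set()
    )
    keep_span = None
    keep_len = 0
    if y_keep is not None:
        keep_span = (tss_index + lin(y_keep[0]) - 1, tss_index + lin(y_keep[1]))
        keep_len = keep_span[1] - keep_span[0]
    runs = []
    start = None
    for i in range(max(lo_off, 0), min(hi_off + 2, len(seq) + 1)):
        py = i <= hi_off and i < len(seq) and seq[i] in PYRIMIDINES and i not in tata_offs
        if py and start is None:
            start = i
        elif not py and start is not None:
            runs.append((start, i))
            start = None
    threshold = max(keep_len, 5)
    for s, e in runs:
        if keep_span is not None and (s, e) == keep_span:
            continue
        length = e - s
        beats = length > threshold or (
            keep_span is not None and length == keep_len and s > keep_span[0]
        )
        if keep_span is None:
            beats = length >= 5
        if not beats:
            continue
        if not canvas.mutate_window(s, e - s, lambda k: PYRIMIDINES):
            raise ValueError(f"cannot scrub pyrimidine run at offsets {s}..{e}")
        return True
    return False


# ---------------------------------------------------------------------------
# Haplotype spawning
# ---------------------------------------------------------------------------

def spawn_haplotypes(
    model: GeneModel,
    counts: dict,
    *,
    indel_length_range: tuple[int, int] = (1, 7),
    n_haplotypes: int = 4,
    seed: int = 0,
    min_separation: int = 2,
) -> tuple[list[str], TruthRecord]:
    """Derive haplotypes carrying the requested per-region variant counts.

    ``counts`` maps regions -- :class:`GeneRegion` objects or (start, end)
    coordinate pairs -- to (n_snps, n_indels).  The union of variants
    across haplotypes matches the requested counts exactly per region;
    each variant is carried by >= 1 of haplotypes 1..n-1 (haplotype 0 is
    the unmutated reference).  Indels are placed with unambiguous flanking
    context, all variant footprints at least ``min_separation`` free bases
    apart (indels get extra clearance proportional to their length, since
    two long indel events planted close together can be re-explained more
    cheaply by a global aligner), and the finished haplotypes are verified
    to diff back to exactly the planted variants; placement is retried
    with a fresh substream when the verification fails.
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes (haplotype 0 is the reference)")
    for attempt in range(20):
        try:
            return _spawn_once(
                model, counts,
                indel_length_range=indel_length_range,
                n_haplotypes=n_haplotypes,
                seed=seed + 7919 * attempt,
                min_separation=min_separation,
            )
        except _AmbiguousPlacement:
            continue
    raise ValueError("could not find an unambiguous variant placement")


class _AmbiguousPlacement(Exception):
    pass


def _spawn_once(model, counts, *, indel_length_range, n_haplotypes, seed, min_separation):
    rng = np.random.default_rng(seed)
    ref = model.sequence
    blocked: set[int] = set()
    variants: list[Variant] = []

    def reserve(footprint: set[int], pad: int) -> None:
        for o in footprint:
            for d in range(-pad, pad + 1):
                blocked.add(o + d)

    def clear(footprint: set[int], pad: int) -> bool:
        return not any((o + d) in blocked for o in footprint
                       for d in range(-pad, pad + 1))

    def carriers() -> frozenset[str]:
        while True:
            picks = [k for k in range(1, n_haplotypes) if rng.random() < 0.5]
            if picks:
                return frozenset(f"h{k}" for k in picks)

    def other_base(*avoid: str) -> str:
        choices = [b for b in _BASES if b not in avoid]
        return choices[int(rng.integers(len(choices)))]

    for key in counts:
        region = key if isinstance(key, GeneRegion) else GeneRegion("region", *key)
        n_snps, n_indels = counts[key]
        lo = model.to_offset(region.start)
        hi = model.to_offset(region.end)
        size = hi - lo + 1
        if n_snps + n_indels and size < (n_snps + n_indels):
            raise ValueError(f"region {region.label} {region.start}..{region.end} "
                             f"too small for {n_snps} SNPs + {n_indels} indels")

        for _ in range(n_indels):
            placed = False
            for _try in range(2000):
                length = int(rng.integers(indel_length_range[0], indel_length_range[1] + 1))
                is_del = bool(rng.random() < 0.5)
                pad = max(min_separation, length + 8)
                if is_del:
                    if size < length + 2:
                        continue
                    o = int(rng.integers(lo, hi - length + 2))
                    if o < 1 or o + length >= len(ref):
                        continue
                    footprint = set(range(o, o + length))
                    if not clear(footprint, pad):
                        continue
                    # flanking context must pin the gap placement
                    if ref[o - 1] == ref[o + length - 1] or ref[o] == ref[o + length]:
                        continue
                    v = Variant(model.to_tss(o), "indel", ref[o : o + length], "-",
                                carriers())
                else:
                    o = int(rng.integers(max(lo, 1), hi + 1))
                    footprint = {o - 1, o}
                    if not clear(footprint, pad):
                        continue
                    ins = [_BASES[i] for i in rng.integers(0, 4, size=length)]
                    if length == 1:
                        ins[0] = other_base(ref[o], ref[o - 1])
                    else:
                        if ins[0] == ref[o]:
                            ins[0] = other_base(ref[o])
                        if ins[-1] == ref[o - 1]:
                            ins[-1] = other_base(ref[o - 1])
                    v = Variant(model.to_tss(o), "indel", "-", "".join(ins),
                                carriers())
                variants.append(v)
                reserve(footprint, min_separation)
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place indel in region {region.label} "
                                 f"{region.start}..{region.end}")

        for _ in range(n_snps):
            placed = False
            for _try in range(2000):
                o = int(rng.integers(lo, hi + 1))
                if not clear({o}, min_separation):
                    continue
                v = Variant(model.to_tss(o), "SNP", ref[o], other_base(ref[o]),
                            carriers())
                variants.append(v)
                reserve({o}, min_separation)
                placed = True
                break
            if not placed:
                raise ValueError(f"could not place SNP in region {region.label} "
                                 f"{region.start}..{region.end}")

    variants.sort(key=lambda v: v.key())
    haplotypes = [ref]
    for k in range(1, n_haplotypes):
        mine = [v for v in variants if f"h{k}" in v.carriers]
        hap = apply_variants(ref, mine, tss_index=model.tss_index)
        # The planted representation must be what a global aligner recovers.
        from .variants import diff_haplotype

        called = diff_haplotype(ref, hap, tss_index=model.tss_index)
        if {v.key() for v in called} != {v.key() for v in mine}:
            raise _AmbiguousPlacement
        haplotypes.append(hap)
    truth = TruthRecord(variants=variants, motifs=tuple(), core_elements=tuple())
    return haplotypes, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Short-read simulation parameters (substitution errors only)."""

    read_length: int = 100
    mean_coverage: float = 12.0
    base_error_rate: float = 0.0
    quality_mean: float = 35.0
    quality_sd: float = 5.0
    nonunique_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.nonunique_fraction <= 1.0:
            raise ValueError("nonunique_fraction must be a proportion")


def simulate_reads(
    model: GeneModel,
    haplotypes: list[str],
    dosage: tuple[int, ...],
    cfg: ReadSimConfig,
) -> list[AlignedRead]:
    """Simulate placed reads from a dosage-weighted haplotype mixture.

    Haplotypes must be reference-length (substitution variants only; the
    short-read path calls SNPs, not indels).  Reads carry their true
    placement, per-base phred qualities, a unique-mapping flag, and their
    source haplotype encoded in the read id (``r000123/h2``).
    """
    if len(dosage) != len(haplotypes):
        raise ValueError("dosage length must equal the number of haplotypes")
    ploidy = sum(dosage)
    if ploidy <= 0:
        raise ValueError("ploidy (sum of dosage) must be >= 1")
    if any(d < 0 for d in dosage):
        raise ValueError("dosage entries must be >= 0")
    L = len(model.sequence)
    for h in haplotypes:
        if len(h) != L:
            raise ValueError("read simulation requires reference-length (SNP-only) haplotypes")
    if cfg.read_length > L:
        raise ValueError("read length exceeds the reference length")

    rng = np.random.default_rng(cfg.seed)
    n_reads = int(round(cfg.mean_coverage * L / cfg.read_length))
    probs = np.asarray(dosage, dtype=float) / ploidy
    reads: list[AlignedRead] = []
    for i in range(n_reads):
        hap_idx = int(rng.choice(len(haplotypes), p=probs))
        o = int(rng.integers(0, L - cfg.read_length + 1))
        frag = list(haplotypes[hap_idx][o : o + cfg.read_length])
        if cfg.base_error_rate > 0:
            err = rng.random(cfg.read_length) < cfg.base_error_rate
            for j in np.nonzero(err)[0]:
                frag[j] = _BASES[(("ACGT".index(frag[j])) + int(rng.integers(1, 4))) % 4]
        quals = np.clip(np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd,
                                           size=cfg.read_length)), 2, 41).astype(int)
        strand = "-" if rng.random() < 0.5 else "+"
        seq = "".join(frag)
        q = tuple(int(x) for x in quals)
        if strand == "-":
            seq = revcomp(seq)
            q = q[::-1]
        unique = bool(rng.random() >= cfg.nonunique_fraction)
        reads.append(
            AlignedRead(f"r{i:06d}/h{hap_idx}", model.to_tss(o), strand, seq, q, unique)
        )
    return reads


def read_source_haplotype(read_id: str) -> int:
    """Recover the true source haplotype index from a simulated read id."""
    return int(read_id.rsplit("/h", 1)[1])


def planted_snp_support(columns, snp: Variant, cfg) -> int:
    """Realized passing support for a planted SNP: passing observations of
    the alternate base contributed by reads from carrier haplotypes."""
    carrier_idx = {int(c[1:]) for c in snp.carriers}
    for col in columns:
        if col.position != snp.position:
            continue
        return sum(
            1
            for (b, q, u, rid) in col.observations
            if b == snp.alt_allele
            and cfg.passes(q, u)
            and read_source_haplotype(rid) in carrier_idx
        )
    return 0


# ---------------------------------------------------------------------------
# Clone sampling
# ---------------------------------------------------------------------------

def sample_clones(dosage, n_clones: int, seed: int = 0) -> np.ndarray:
    """Multinomial clone counts with probabilities dosage_i / sum(dosage)."""
    dosage = np.asarray(dosage, dtype=int)
    if (dosage < 0).any():
        raise ValueError("dosage entries must be >= 0")
    total = int(dosage.sum())
    if total < 1:
        raise ValueError("sum of dosage must be >= 1")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_clones, dosage / total)
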