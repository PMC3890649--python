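"""Motif scanning, TSS prediction, core elements, disruption detection."""

import numpy as np
import pytest

from conftest import random_seq
from oracle_utils import scan_oracle, yr_dimers

import gslkit
from gslkit.coords import lin, tss_add
from gslkit.presets import (
    GSL1_MOTIF_OCCURRENCES,
    GSL2_MOTIF_OCCURRENCES,
)
from gslkit.io import load_packaged_motif_library
from gslkit.promoter import (
    MotifDef,
    detect_disruptions,
    find_core_elements,
    predict_tss,
    scan_motifs,
)
from gslkit.variants import Variant


class TestScanMotifs:
    def test_minus_strand_convention_start_greater_than_end(self):
        # TTAATGG on the minus strand <=> CCATTAA on the plus strand
        seq = "GGGG" + "CCATTAA" + "GGGG"
        (hit,) = scan_motifs(seq, [MotifDef("WUSATAg", "TTAATGG")], anchor=-15)
        assert (hit.start, hit.end, hit.strand) == (-5, -11, "-")
        assert hit.matched == "TTAATGG"
        assert hit.start > hit.end

    def test_degenerate_pattern_finds_both_expansions(self):
        seq = "AAACCATAACCA"
        hits = scan_motifs(seq, [MotifDef("MYB1AT", "WAACCA")], anchor=1)
        plus = [(h.matched, h.start) for h in hits if h.strand == "+"]
        assert ("AAACCA", 1) in plus and ("TAACCA", 7) in plus

    def test_empty_library_yields_no_hits(self, rng):
        assert scan_motifs(random_seq(rng, 500), [], anchor=1) == []

    def test_invalid_iupac_character_is_named(self):
        with pytest.raises(ValueError, match="'E'"):
            MotifDef("BAD", "GAEA")

    @pytest.mark.parametrize("pattern", [
        "TGTCA", "GAAAAA", "WAACCA", "MACCWAMC", "CATGCATG", "NYRS", "TTAATGG",
    ])
    def test_matches_expansion_oracle_on_random_sequence(self, pattern):
        rng = np.random.default_rng(hash(pattern) % 2**31)
        seq = random_seq(rng, 800)
        anchor = -400
        hits = scan_motifs(seq, [MotifDef("X", pattern)], anchor=anchor)
        got = {(lin(h.span[0]) - lin(anchor), h.strand) for h in hits}
        assert got == set(scan_oracle(seq, pattern))

    def test_strand_symmetry(self, rng):
        """Minus-strand hits equal coordinate-mapped plus-strand hits on the
        reverse complement."""
        from gslkit.coords import revcomp

        seq = random_seq(rng, 400)
        pattern = MotifDef("X", "GATAA")
        minus = {
            lin(h.span[0]) - lin(-200)
            for h in scan_motifs(seq, [pattern], anchor=-200)
            if h.strand == "-"
        }
        plus_on_rc = {
            len(seq) - (i + len(pattern.pattern))
            for i, s in scan_oracle(revcomp(seq), pattern.pattern)
            if s == "+"
        }
        assert minus == plus_on_rc

    @pytest.mark.parametrize(
        "gene,occurrences",
        [("gsl1", GSL1_MOTIF_OCCURRENCES), ("gsl2", GSL2_MOTIF_OCCURRENCES)],
    )
    def test_preset_promoters_scan_to_exactly_the_planted_inventory(
        self, gene, occurrences, gsl1_model, gsl2_model
    ):
        model = {"gsl1": gsl1_model, "gsl2": gsl2_model}[gene]
        library = load_packaged_motif_library(gene)
        hits = scan_motifs(model.promoter_sequence(), library, anchor=model.first_pos)
        got = {(h.motif_id, h.start, h.end, h.strand) for h in hits}
        want = {(o.motif_id, o.start, o.end, o.strand) for o in occurrences}
        assert got == want
        for h in hits:  # every hit satisfies its own pattern
            pat = next(m.pattern for m in library if m.motif_id == h.motif_id)
            from gslkit.coords import IUPAC

            assert len(h.matched) == len(pat)
            assert all(c in IUPAC[p] for c, p in zip(h.matched, pat))


class TestPredictTSS:
    def test_gsl1_top_candidate_puts_atg_at_plus_34(self, gsl1_model):
        m = gsl1_model
        seq = m.sequence[: m.to_offset(m.atg_pos)]
        cands = predict_tss(seq, anchor=m.first_pos, atg=m.atg_pos)
        assert cands[0].position == 1
        assert cands[0].distance_to_atg == 33
        assert cands[0].tata == (-32, -27)

    def test_gsl2_top_candidate_puts_atg_at_plus_39(self, gsl2_model):
        m = gsl2_model
        seq = m.sequence[: m.to_offset(m.atg_pos)]
        cands = predict_tss(seq, anchor=m.first_pos, atg=m.atg_pos)
        assert cands[0].position == 1
        assert cands[0].distance_to_atg == 38

    def test_all_g_window_has_no_candidates(self):
        assert predict_tss("G" * 80, anchor=-80, atg=1, window=60) == []

    def test_candidate_set_equals_dimer_oracle(self, rng):
        seq = random_seq(rng, 300)
        atg, window = 1, 150
        cands = predict_tss(seq, anchor=-300, atg=atg, window=window)
        got = {lin(c.position) for c in cands}
        lo, hi = lin(atg) - window, lin(atg) - 1
        want = {
            tss_add(-300, i) for i in yr_dimers(seq)
        }
        want = {lin(p) for p in want if lo <= lin(p) <= hi}
        assert got == want


class TestCoreElements:
    def test_gsl1_elements_at_annotated_coordinates(self, gsl1_model):
        core = find_core_elements(
            gsl1_model.promoter_sequence(), anchor=gsl1_model.first_pos
        )
        assert core.tata == (-32, -27)
        assert core.y_patch == (-26, -20)
        assert core.caat == (-48, -44)
        assert core.caat_kind == "canonical"

    def test_gsl2_hypothetical_caat(self, gsl2_model):
        core = find_core_elements(
            gsl2_model.promoter_sequence(), anchor=gsl2_model.first_pos
        )
        assert core.tata == (-50, -45)
        assert core.y_patch == (-59, -51)
        assert core.caat == (-65, -61)
        assert core.caat_kind == "hypothetical"

    def test_absent_y_patch_when_no_pyrimidine_run(self):
        seq = ("AG" * 50)  # no pyrimidine run at all
        core = find_core_elements(seq, anchor=-100)
        assert core.y_patch is None

    def test_insufficient_upstream_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="70"):
            find_core_elements("ACGT" * 10, anchor=-40)


class TestDetectDisruptions:
    def _hit(self, start=-826, end=-821, strand="+"):
        from gslkit.promoter import MotifHit

        return MotifHit("GT1GMSCAM4", start, end, strand, "GAAAAA")

    def test_snp_inside_hit_span_is_a_disruption(self):
        hit = self._hit()
        variants = {"C": [Variant(-824, "SNP", "A", "G")]}
        (d,) = detect_disruptions([hit], variants)
        assert d.genotype == "C"
        assert d.disruption_kind == "SNP"

    def test_adjacent_variant_is_not_a_disruption(self):
        hit = self._hit()
        variants = {"C": [Variant(-827, "SNP", "A", "G"), Variant(-820, "SNP", "T", "C")]}
        assert detect_disruptions([hit], variants) == []

    def test_insertion_at_the_boundary_is_outside(self):
        hit = self._hit()
        # insertion before -826 (the hit's first base) leaves the motif intact
        outside = {"S": [Variant(-826, "indel", "-", "TTT")]}
        inside = {"S": [Variant(-823, "indel", "-", "TTT")]}
        assert detect_disruptions([hit], outside) == []
        (d,) = detect_disruptions([hit], inside)
        assert d.disruption_kind == "indel"

    def test_mixed_kinds_are_reported_as_both(self):
        hit = self._hit()
        variants = {
            "V": [Variant(-824, "SNP", "A", "G"), Variant(-822, "indel", "AA", "-")]
        }
        (d,) = detect_disruptions([hit], variants)
        assert d.disruption_kind == "both"

    def test_matches_interval_intersection_oracle(self, rng):
        from gslkit.promoter import MotifHit

        hits = []
        for i in range(30):
            lo = -int(rng.integers(20, 900))
            length = int(rng.integers(4, 9))
            hi = tss_add(lo, length - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            s, e = (lo, hi) if strand == "+" else (hi, lo)
            hits.append(MotifHit(f"m{i}", s, e, strand, "N" * length))
        variants = {}
        for g in ("C", "K", "S", "V"):
            vs = []
            for _ in range(25):
                pos = -int(rng.integers(2, 900))
                if rng.random() < 0.5:
                    vs.append(Variant(pos, "SNP", "A", "G"))
                else:
                    L = int(rng.integers(1, 7))
                    vs.append(Variant(pos, "indel", "N" * L, "-"))
            variants[g] = vs
        got = {
            (d.hit.motif_id, d.genotype, frozenset(v.key() for v in d.overlapping_variants))
            for d in detect_disruptions(hits, variants)
        }
        expect = set()
        for h in hits:
            lo, hi = lin(h.span[0]), lin(h.span[1])
            for g, vs in variants.items():
                over = [
                    v for v in vs
                    if (lin(v.position) <= hi and lin(v.position) + v.length - 1 >= lo)
                ]
                if over:
                    expect.add((h.motif_id, g, frozenset(v.key() for v in over)))
        assert got == expect
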