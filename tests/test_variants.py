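"""Haplotype diffing, variant merging, pileup and the polySNP caller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gslkit
from conftest import random_seq
from gslkit.genemodel import GeneModel
from gslkit.variants import (
    AlignedRead,
    CallerConfig,
    PileupColumn,
    Variant,
    apply_variants,
    call_snps_polysnp,
    diff_haplotype,
    merge_variant_tables,
    pileup_from_reads,
)


class TestDiffHaplotype:
    def test_identical_sequences_yield_no_variants(self, rng):
        seq = random_seq(rng, 200)
        assert diff_haplotype(seq, seq) == []

    def test_planted_snps_and_indels_are_recovered_exactly(self, rng):
        ref = random_seq(rng, 600)
        planted = [
            Variant(40, "SNP", ref[39], "A" if ref[39] != "A" else "C"),
            Variant(120, "SNP", ref[119], "G" if ref[119] != "G" else "T"),
            Variant(200, "indel", ref[199:201], "-"),  # 2 nt deletion
            Variant(320, "SNP", ref[319], "C" if ref[319] != "C" else "G"),
            Variant(400, "indel", ref[399:406], "-"),  # 7 nt deletion
            Variant(500, "SNP", ref[499], "T" if ref[499] != "T" else "A"),
            Variant(560, "SNP", ref[559], "A" if ref[559] != "A" else "G"),
        ]
        # keep the fixture honest: skip flanks that make a gap slideable
        safe = []
        for v in planted:
            if v.kind == "indel":
                o = v.position - 1
                L = len(v.ref_allele)
                if ref[o - 1] == ref[o + L - 1] or ref[o] == ref[o + L]:
                    continue
            safe.append(v)
        hap = apply_variants(ref, safe)
        got = diff_haplotype(ref, hap)
        assert {v.key() for v in got} == {v.key() for v in safe}
        lengths = sorted(v.length for v in got if v.kind == "indel")
        assert lengths == sorted(v.length for v in safe if v.kind == "indel")

    def test_apply_then_diff_is_identity_on_truth(self, table1_pipeline):
        for gene in ("gsl1", "gsl2"):
            data = table1_pipeline[gene]
            model, truth = data["model"], data["truth"]
            for k, hap in enumerate(data["haplotypes"]):
                if k == 0:
                    assert hap == model.sequence
                    continue
                mine = [v for v in truth.variants if f"h{k}" in v.carriers]
                rebuilt = apply_variants(
                    model.sequence, mine, tss_index=model.tss_index
                )
                assert rebuilt == hap
                called = diff_haplotype(
                    model.sequence, hap, tss_index=model.tss_index
                )
                assert {v.key() for v in called} == {v.key() for v in mine}

    def test_one_gap_run_counts_as_one_indel_event(self, rng):
        ref = random_seq(rng, 300)
        # delete 5 bases with shift-blocking flanks
        for start in range(100, 140):
            if ref[start - 1] != ref[start + 4] and ref[start] != ref[start + 5]:
                break
        hap = ref[:start] + ref[start + 5 :]
        got = diff_haplotype(ref, hap)
        indels = [v for v in got if v.kind == "indel"]
        assert len(indels) == 1
        assert indels[0].length == 5


class TestMergeVariantTables:
    def test_shared_snp_unions_carriers(self):
        a = [Variant(10, "SNP", "A", "G", frozenset({"geno1"}))]
        b = [Variant(10, "SNP", "A", "G", frozenset({"geno2"}))]
        merged = merge_variant_tables([a, b])
        assert len(merged) == 1
        assert merged[0].carriers == {"geno1", "geno2"}

    def test_disjoint_tables_conserve_counts(self, rng):
        tables = [
            [Variant(10 * (i + 1) + j, "SNP", "A", "G", frozenset({f"g{i}"}))
             for j in range(3)]
            for i in range(5)
        ]
        merged = merge_variant_tables(tables)
        assert len(merged) == sum(len(t) for t in tables)

    def test_matches_brute_force_set_union(self, rng):
        keys = [(int(p), "SNP", "A", "G") for p in rng.choice(
            np.arange(1, 200), size=40, replace=False)]
        tables = []
        for g in range(4):
            chosen = [k for k in keys if rng.random() < 0.4]
            tables.append(
                [Variant(k[0], k[1], k[2], k[3], frozenset({f"g{g}"})) for k in chosen]
            )
        merged = merge_variant_tables(tables)
        expect = {}
        for t in tables:
            for v in t:
                expect.setdefault(v.key(), set()).update(v.carriers)
        assert {v.key(): set(v.carriers) for v in merged} == expect
        positions = [v.position for v in merged]
        assert positions == sorted(positions, key=lambda p: p if p > 0 else p + 1)

    def test_conflicting_reference_allele_is_an_error(self):
        a = [Variant(10, "SNP", "A", "G")]
        b = [Variant(10, "SNP", "C", "G")]
        with pytest.raises(ValueError, match="10"):
            merge_variant_tables([a, b])


def _flat_model(seq: str) -> GeneModel:
    return GeneModel("ref", seq, 0, 1)


class TestPileup:
    def test_single_read_covers_its_span_once(self, rng):
        seq = random_seq(rng, 300)
        model = _flat_model(seq)
        read = AlignedRead("r0/h0", 51, "+", seq[50:150], (30,) * 100, True)
        cols = pileup_from_reads([read], model)
        assert len(cols) == 100
        assert all(c.depth == 1 for c in cols)
        assert all(c.observations[0][0] == c.ref_base for c in cols)

    def test_overlap_columns_have_two_observations(self, rng):
        seq = random_seq(rng, 200)
        model = _flat_model(seq)
        reads = [
            AlignedRead("r0/h0", 1, "+", seq[0:100], (30,) * 100, True),
            AlignedRead("r1/h0", 51, "+", seq[50:150], (30,) * 100, True),
        ]
        cols = pileup_from_reads(reads, model)
        depth = {c.position: c.depth for c in cols}
        assert depth[60] == 2 and depth[10] == 1 and depth[120] == 1

    def test_minus_strand_reads_are_complemented_back(self, rng):
        seq = random_seq(rng, 120)
        model = _flat_model(seq)
        from gslkit.coords import revcomp

        read = AlignedRead("r0/h0", 11, "-", revcomp(seq[10:60]), tuple(range(50)), True)
        cols = pileup_from_reads([read], model)
        assert all(c.observations[0][0] == c.ref_base for c in cols)
        # qualities follow the read orientation; reference-forward order reverses them
        assert [c.observations[0][1] for c in cols] == list(range(49, -1, -1))

    def test_read_past_reference_end_is_an_error(self, rng):
        seq = random_seq(rng, 50)
        model = _flat_model(seq)
        read = AlignedRead("r0/h0", 30, "+", "A" * 40, (30,) * 40, True)
        with pytest.raises(ValueError, match="past"):
            pileup_from_reads([read], model)

    def test_mean_depth_tracks_coverage(self, gsl1_model):
        from gslkit.simulate import ReadSimConfig, simulate_reads

        haps = [gsl1_model.sequence] * 4
        reads = simulate_reads(gsl1_model, haps, (1, 1, 1, 1),
                               ReadSimConfig(mean_coverage=12, seed=8))
        cols = pileup_from_reads(reads, gsl1_model)
        mean_depth = sum(c.depth for c in cols) / len(gsl1_model.sequence)
        assert mean_depth == pytest.approx(12, rel=0.08)


def _column(ref="A", obs=()):
    return PileupColumn(100, ref, list(obs))


class TestPolySNPCaller:
    def test_three_passing_alt_reads_call_two_do_not(self):
        base = [("G", 30, True, f"r{i}") for i in range(3)]
        col3 = _column(obs=base + [("A", 30, True, "r9")])
        col2 = _column(obs=base[:2] + [("A", 30, True, "r9")])
        assert len(call_snps_polysnp([col3])) == 1
        assert call_snps_polysnp([col2]) == []

    def test_quality_exactly_at_threshold_is_excluded(self):
        col = _column(obs=[("G", 15, True, f"r{i}") for i in range(5)])
        assert call_snps_polysnp([col]) == []
        col_pass = _column(obs=[("G", 16, True, f"r{i}") for i in range(5)])
        assert len(call_snps_polysnp([col_pass])) == 1

    def test_non_unique_reads_are_excluded_by_default(self):
        col = _column(obs=[("G", 30, False, f"r{i}") for i in range(5)])
        assert call_snps_polysnp([col]) == []
        relaxed = CallerConfig(unique_only=False)
        assert len(call_snps_polysnp([col], relaxed)) == 1

    def test_all_reference_column_yields_no_call(self):
        col = _column(obs=[("A", 30, True, f"r{i}") for i in range(10)])
        assert call_snps_polysnp([col]) == []

    def test_call_records_support_and_depth(self):
        obs = [("G", 30, True, f"r{i}") for i in range(4)]
        obs += [("A", 30, True, f"s{i}") for i in range(6)]
        obs += [("G", 10, True, "low")]  # fails quality
        (call,) = call_snps_polysnp([_column(obs=obs)])
        assert (call.alt_base, call.supporting_reads, call.total_passing_reads) == ("G", 4, 10)

    @given(
        n_alt=st.integers(0, 8),
        n_ref=st.integers(0, 8),
        extra_quality=st.integers(16, 41),
        threshold=st.integers(1, 6),
    )
    @settings(max_examples=60, derandomize=True)
    def test_monotonicity_in_support_and_threshold(self, n_alt, n_ref, extra_quality, threshold):
        """Adding a passing alt observation never removes a call; raising
        min_alt_reads never adds one."""
        obs = [("A", 30, True, f"ref{i}") for i in range(n_ref)]
        obs += [("G", 30, True, f"alt{i}") for i in range(n_alt)]
        cfg = CallerConfig(min_alt_reads=threshold)
        before = call_snps_polysnp([_column(obs=obs)], cfg)
        more = call_snps_polysnp(
            [_column(obs=obs + [("G", extra_quality, True, "extra")])], cfg
        )
        assert {c.alt_base for c in before} <= {c.alt_base for c in more}
        stricter = call_snps_polysnp(
            [_column(obs=obs)], CallerConfig(min_alt_reads=threshold + 1)
        )
        assert {c.alt_base for c in stricter} <= {c.alt_base for c in before}
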