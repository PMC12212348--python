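import random

import pytest

from panmem.alignment import Alignment, cigar_to_string
from panmem.pangenome import (LiftMap, LiftSegment, PangenomeError,
                              ReferenceGenome, VariantRecord, apply_variants,
                              build_pangenome_text, dedup_same_position,
                              lift_alignment, SEPARATOR, TERMINATOR)
from panmem.simulate import SimConfig, simulate_pangenome

from conftest import random_dna


def _ref(seq: str, name: str = "c1") -> ReferenceGenome:
    return ReferenceGenome([(name, seq)])


def _var(pos, ref, alt, gt=(1, 1), contig="c1"):
    return VariantRecord(contig=contig, pos=pos, ref=ref, alts=[alt],
                         genotypes=[gt], phased=[True])


class TestApplyVariants:
    def test_all_reference_genotypes_identity(self):
        ref = _ref("ACGTACGTAC")
        hap, lift = apply_variants(ref, [_var(3, "G", "T", gt=(0, 0))], 0, 1)
        assert hap.sequence == "ACGTACGTAC"
        assert len(lift.segments) == 1
        assert lift.segments[0].kind == "M"
        assert lift.segments[0].length == 10

    def test_deletion_shifts_coordinates(self):
        # 50 bp reference; deletion removes 1-based ref positions 11-12,
        # so the haplotype has 48 bp and hap position 20 (1-based) lifts
        # to reference position 22 (1-based).
        rng = random.Random(0)
        seq = random_dna(rng, 50).decode()
        var = _var(10, seq[9:12], seq[9])
        hap, lift = apply_variants(_ref(seq), [var], 0, 1)
        assert len(hap.sequence) == 48
        assert hap.sequence == seq[:10] + seq[12:]
        assert lift.hap_to_ref(19) == 21

    def test_snp_keeps_single_match_segment(self):
        ref = _ref("ACGTACGTAC")
        hap, lift = apply_variants(ref, [_var(4, "T", "G")], 0, 1)
        assert len(hap.sequence) == 10
        assert hap.sequence == "ACGGACGTAC"
        assert [s.kind for s in lift.segments] == ["M"]
        assert lift.substitutions == [(3, "G")]

    def test_insertion(self):
        ref = _ref("AAAACCCC")
        hap, lift = apply_variants(ref, [_var(4, "A", "ATTT")], 0, 1)
        assert hap.sequence == "AAAATTTCCCC"
        assert lift.hap_to_ref(3) == 3
        assert lift.hap_to_ref(4) is None      # inside the insertion
        assert lift.hap_to_ref(7) == 4
        assert lift.apply_to("AAAACCCC") == hap.sequence

    def test_ref_mismatch_rejected(self):
        with pytest.raises(PangenomeError, match="mismatch"):
            apply_variants(_ref("AAAA"), [_var(2, "C", "G")], 0, 1)

    def test_overlapping_variants_keep_first(self, caplog):
        ref = _ref("AAAAAAAAAA")
        vs = [_var(2, "AAA", "A"), _var(3, "A", "C")]
        with caplog.at_level("WARNING"):
            hap, _ = apply_variants(ref, vs, 0, 1)
        assert hap.sequence == "AAAAAAAA"      # only the deletion applied
        assert "overlapping" in caplog.text

    def test_unphased_rejected(self):
        v = VariantRecord("c1", 2, "A", ["C"], [(0, 1)], phased=[False])
        with pytest.raises(PangenomeError, match="unphased"):
            apply_variants(_ref("AAAA"), [v], 0, 2)

    def test_symbolic_allele_rejected(self):
        with pytest.raises(PangenomeError, match="symbolic"):
            apply_variants(_ref("AAAA"), [_var(2, "A", "<DEL>")], 0, 1)

    def test_multiallelic_decomposed_by_gt_index(self):
        v = VariantRecord("c1", 2, "A", ["C", "G"], [(1, 2)], phased=[True])
        hap1, _ = apply_variants(_ref("AAAA"), [v], 0, 1)
        hap2, _ = apply_variants(_ref("AAAA"), [v], 0, 2)
        assert hap1.sequence == "ACAA"
        assert hap2.sequence == "AGAA"


class TestLiftMapInvariants:
    def test_round_trip_and_monotonic(self):
        rng = random.Random(1)
        seq = random_dna(rng, 300).decode()
        vs = [_var(50, seq[49:52], seq[49]),          # deletion
              _var(150, seq[149], seq[149] + "GGG"),  # insertion
              _var(250, seq[249], "ACGT"[("ACGT".index(seq[249]) + 1) % 4])]
        hap, lift = apply_variants(_ref(seq), vs, 0, 1)
        prev = -1
        for hp in range(len(hap.sequence)):
            rp = lift.hap_to_ref(hp)
            if rp is None:
                continue
            assert lift.ref_to_hap(rp) == hp          # round trip
            assert rp > prev                          # monotone
            prev = rp

    def test_reconstruction_on_random_haplotypes(self):
        # generator-independent check over 100 random synthetic haplotypes
        cfg = SimConfig(ref_length=2000, n_haplotypes=100, snp_rate=0.005,
                        indel_rate=0.001, seed=3)
        sim = simulate_pangenome(cfg)
        ref_seq = sim.reference.contigs[0][1]
        assert len(sim.haplotypes) == 100
        for hap, lift in zip(sim.haplotypes, sim.lift_maps):
            assert lift.apply_to(ref_seq) == hap.sequence

    def test_identity_map_on_variant_free_haplotype(self):
        lift = LiftMap.identity("c1", 100)
        for p in (0, 42, 99):
            assert lift.hap_to_ref(p) == p
            assert lift.ref_to_hap(p) == p


class TestPangenomeText:
    def test_single_haplotype_layout(self):
        from panmem.pangenome import Haplotype

        text = build_pangenome_text([Haplotype("s#1", "ACGT", "c1")])
        assert text.text == b"ACGT" + bytes([TERMINATOR])
        assert text.doc_bounds == [0]

    def test_two_haplotype_bounds(self):
        from panmem.pangenome import Haplotype

        h1 = Haplotype("a#1", "A" * 10, "c1")
        h2 = Haplotype("a#2", "C" * 20, "c1")
        text = build_pangenome_text([h1, h2])
        assert text.doc_bounds == [0, 11]
        assert text.text[10] == SEPARATOR
        assert text.text[-1] == TERMINATOR

    def test_separator_not_a_sequence_position(self):
        from panmem.pangenome import Haplotype

        text = build_pangenome_text([Haplotype("a#1", "AAAA", "c1"),
                                     Haplotype("a#2", "CCCC", "c1")])
        with pytest.raises(ValueError, match="not a sequence position"):
            text.global_to_local(4)

    def test_coordinate_bijection(self):
        from panmem.pangenome import Haplotype

        text = build_pangenome_text([Haplotype("a#1", "ACGTT", "c1"),
                                     Haplotype("b#1", "GGG", "c1")])
        for g in range(len(text.text)):
            try:
                doc, local = text.global_to_local(g)
            except ValueError:
                continue
            assert text.local_to_global(doc, local) == g

    def test_empty_rejected(self):
        with pytest.raises(PangenomeError):
            build_pangenome_text([])


class TestLiftAlignment:
    def test_variant_free_window_unchanged(self):
        lift = LiftMap.identity("c1", 100)
        aln = Alignment(doc="h", strand="+", hap_start=10,
                        cigar=[("M", 20)], score=40.0)
        out = lift_alignment(aln, lift)
        assert out.ref_start == 10
        assert out.cigar == [("M", 20)]
        assert out.score == 40.0

    def test_deletion_appears_in_lifted_cigar(self):
        # haplotype lacks 2 reference bases at hap position 15
        segs = [LiftSegment(0, 0, 15, "M"), LiftSegment(15, 15, 2, "D"),
                LiftSegment(15, 17, 33, "M")]
        lift = LiftMap("c1", segs)
        aln = Alignment(doc="h", strand="+", hap_start=5,
                        cigar=[("M", 20)], score=40.0)
        out = lift_alignment(aln, lift)
        assert out.ref_start == 5
        assert out.cigar == [("M", 10), ("D", 2), ("M", 10)]
        assert out.score == 40.0               # score preserved

    def test_insertion_becomes_read_insertion(self):
        segs = [LiftSegment(0, 0, 10, "M"), LiftSegment(10, 10, 3, "I", "GGG"),
                LiftSegment(13, 10, 10, "M")]
        lift = LiftMap("c1", segs)
        aln = Alignment(doc="h", strand="+", hap_start=5,
                        cigar=[("M", 12)], score=24.0)
        out = lift_alignment(aln, lift)
        assert out.cigar == [("M", 5), ("I", 3), ("M", 4)]
        assert out.ref_start == 5

    def test_alignment_inside_insertion_unliftable(self):
        segs = [LiftSegment(0, 0, 5, "M"), LiftSegment(5, 5, 20, "I", "A" * 20),
                LiftSegment(25, 5, 5, "M")]
        lift = LiftMap("c1", segs)
        aln = Alignment(doc="h", strand="+", hap_start=8,
                        cigar=[("M", 10)], score=20.0)
        out = lift_alignment(aln, lift)
        assert out.unliftable

    def test_same_position_dedup_keeps_higher_score(self):
        a = Alignment(doc="h1", strand="+", hap_start=0, cigar=[("M", 10)],
                      score=20.0, contig="c1", ref_start=7)
        b = Alignment(doc="h2", strand="+", hap_start=3, cigar=[("M", 10)],
                      score=18.0, contig="c1", ref_start=7)
        kept = dedup_same_position([b, a])
        assert kept == [a]
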