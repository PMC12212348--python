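import math

import numpy as np
import pytest

from panmem.pangenome import apply_variants
from panmem.samio import SamRecord, sam_header, write_sam
from panmem.simulate import (SimConfig, TruthRecord, read_truth,
                             score_alignments, simulate_pangenome,
                             simulate_reads, write_fasta, write_fastq,
                             write_truth, write_vcf)


class TestSimulatePangenome:
    def test_zero_rates_haplotypes_equal_reference(self):
        cfg = SimConfig(ref_length=1000, n_haplotypes=4, snp_rate=0,
                        indel_rate=0, seed=1)
        sim = simulate_pangenome(cfg)
        ref = sim.reference.contigs[0][1]
        assert all(h.sequence == ref for h in sim.haplotypes)
        assert sim.variants == []

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(ref_length=2000, n_haplotypes=4, seed=9)
        a = simulate_pangenome(cfg)
        b = simulate_pangenome(cfg)
        assert [h.sequence for h in a.haplotypes] == \
            [h.sequence for h in b.haplotypes]
        assert [(v.pos, v.ref, v.alts) for v in a.variants] == \
            [(v.pos, v.ref, v.alts) for v in b.variants]

    def test_vcf_round_trip_through_pangenome_module(self):
        cfg = SimConfig(ref_length=3000, n_haplotypes=6, snp_rate=0.005,
                        indel_rate=0.001, seed=2)
        sim = simulate_pangenome(cfg)
        for h in range(cfg.n_haplotypes):
            hap, lift = apply_variants(
                sim.reference, sim.variants, h // 2, h % 2 + 1,
                sample_name=sim.sample_names[h // 2])
            assert hap.sequence == sim.haplotypes[h].sequence
            # and the generator's own lift map agrees positionally
            gen_lift = sim.lift_maps[h]
            for p in range(0, len(hap.sequence), 37):
                assert lift.hap_to_ref(p) == gen_lift.hap_to_ref(p)

    def test_duplication_knob(self):
        cfg = SimConfig(ref_length=5000, n_haplotypes=2, snp_rate=0,
                        indel_rate=0, dup_len=500, seed=3)
        sim = simulate_pangenome(cfg)
        assert len(sim.reference.contigs[0][1]) == 5000


class TestSimulateReads:
    def _sim(self, **kw):
        cfg = SimConfig(ref_length=5000, n_haplotypes=2, snp_rate=0.001,
                        indel_rate=0, n_pairs=50, seed=4, **kw)
        sim = simulate_pangenome(cfg)
        return cfg, sim

    def test_zero_error_reads_are_exact_substrings(self):
        cfg, sim = self._sim(subst_error_rate=0.0)
        r1, r2, truth = simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
        hap_by_id = {h.id: h.sequence for h in sim.haplotypes}
        for reads in (r1, r2):
            for rid, seq, _ in reads:
                assert any(seq in hs or _rc(seq) in hs
                           for hs in hap_by_id.values())

    def test_zero_sd_constant_insert(self):
        cfg, sim = self._sim(subst_error_rate=0.0, insert_sd=0.0)
        _, _, truth = simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
        by_read = {}
        for t in truth:
            by_read.setdefault(t.read_id, []).append(t)
        for ts in by_read.values():
            left = min(t.hap_pos for t in ts)
            right = max(t.hap_pos for t in ts) + cfg.read_length
            assert right - left == cfg.insert_mean

    def test_empirical_error_rate(self):
        cfg = SimConfig(ref_length=20000, n_haplotypes=2, snp_rate=0,
                        indel_rate=0, n_pairs=500, read_length=100,
                        subst_error_rate=0.01, seed=5)
        sim = simulate_pangenome(cfg)
        r1, r2, truth = simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
        ref = sim.haplotypes[0].sequence
        truth_by = {(t.read_id, t.mate): t for t in truth}
        errors = bases = 0
        for mate, reads in ((1, r1), (2, r2)):
            for rid, seq, _ in reads:
                t = truth_by[(rid, mate)]
                true_seq = ref[t.hap_pos:t.hap_pos + cfg.read_length]
                hap = sim.haplotypes[[h.id for h in sim.haplotypes]
                                     .index(t.haplotype)].sequence
                true_seq = hap[t.hap_pos:t.hap_pos + cfg.read_length]
                if t.strand == "-":
                    true_seq = _rc(true_seq)
                errors += sum(a != b for a, b in zip(seq, true_seq))
                bases += len(seq)
        rate = errors / bases
        sd = math.sqrt(cfg.subst_error_rate * (1 - cfg.subst_error_rate)
                       / bases)
        assert abs(rate - cfg.subst_error_rate) <= 3 * sd

    def test_truth_positions_consistent_with_lift(self):
        cfg, sim = self._sim(subst_error_rate=0.0)
        _, _, truth = simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
        lift_by = {h.id: lm for h, lm in zip(sim.haplotypes, sim.lift_maps)}
        for t in truth:
            r = lift_by[t.haplotype].hap_to_ref(t.hap_pos)
            if r is not None:
                assert r == t.ref_pos


def _rc(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestScoreAlignments:
    def _write_sam(self, tmp_path, rows):
        path = tmp_path / "x.sam"
        recs = []
        for rid, mate, flag, pos in rows:
            recs.append(SamRecord(
                qname=rid, flag=flag | (0x40 if mate == 1 else 0x80) | 0x1,
                rname="chr1" if not flag & 0x4 else "*",
                pos=pos, mapq=60,
                cigar="10M" if not flag & 0x4 else "*",
                seq="A" * 10, qual="I" * 10))
        write_sam(str(path), recs, [("chr1", 10000)])
        return str(path)

    def _truth(self, n):
        out = []
        for i in range(n):
            out.append(TruthRecord(f"r{i}", 1, "S0#1", 100 * i, 100 * i, "+"))
        return out

    def test_perfect_sam(self, tmp_path):
        truth = self._truth(4)
        path = self._write_sam(tmp_path, [
            (f"r{i}", 1, 0x1, 100 * i + 1) for i in range(4)])
        rep = score_alignments(path, truth)
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_everything_unmapped(self, tmp_path):
        truth = self._truth(3)
        path = self._write_sam(tmp_path, [
            (f"r{i}", 1, 0x5, 0) for i in range(3)])
        rep = score_alignments(path, truth)
        assert rep.recall == 0.0
        assert rep.precision == 1.0 and rep.zero_denominator

    def test_hand_built_counts(self, tmp_path):
        # 4 reads: 2 correct, 1 wrong position, 1 unmapped
        truth = self._truth(4)
        path = self._write_sam(tmp_path, [
            ("r0", 1, 0x1, 1),
            ("r1", 1, 0x1, 101),
            ("r2", 1, 0x1, 5000),       # > 10 bp away
            ("r3", 1, 0x5, 0)])
        rep = score_alignments(path, truth)
        assert rep.tp == 2 and rep.fp == 1 and rep.fn == 1
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 4)

    def test_tolerance_window(self, tmp_path):
        truth = [TruthRecord("r0", 1, "S0#1", 100, 100, "+")]
        path = self._write_sam(tmp_path, [("r0", 1, 0x1, 111)])
        assert score_alignments(path, truth).tp == 1       # exactly 10 off
        path = self._write_sam(tmp_path, [("r0", 1, 0x1, 112)])
        assert score_alignments(path, truth).tp == 0

    def test_unknown_read_rejected(self, tmp_path):
        path = self._write_sam(tmp_path, [("zz", 1, 0x1, 1)])
        with pytest.raises(KeyError):
            score_alignments(path, self._truth(1))


class TestEmission:
    def test_text_formats_round_trip(self, tmp_path):
        cfg = SimConfig(ref_length=2000, n_haplotypes=4, seed=6, n_pairs=10)
        sim = simulate_pangenome(cfg)
        r1, r2, truth = simulate_reads(sim.haplotypes, sim.lift_maps, cfg)
        write_fasta(str(tmp_path / "ref.fa"), sim.reference.contigs)
        write_vcf(str(tmp_path / "v.vcf"), sim.reference, sim.variants,
                  sim.sample_names)
        write_fastq(str(tmp_path / "r1.fq"), r1, mate=1)
        write_truth(str(tmp_path / "t.tsv"), truth)
        assert read_truth(str(tmp_path / "t.tsv")) == truth

        from panmem.pangenome import load_reference, load_vcf

        ref = load_reference(str(tmp_path / "ref.fa"))
        assert ref.contigs == sim.reference.contigs
        variants, samples = load_vcf(str(tmp_path / "v.vcf"), ref)
        assert samples == sim.sample_names
        assert [(v.pos, v.ref, v.alts, v.genotypes) for v in variants] == \
            [(v.pos, v.ref, v.alts, v.genotypes) for v in sim.variants]
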