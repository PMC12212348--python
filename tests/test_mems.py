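import csv
import random

import pytest

from panmem.mems import (MatchingStatistics, Seed, SeedingConfig,
                         extract_mems, frequency_filter, locate_seeds,
                         matching_statistics, mem_stats_rows,
                         orientation_filter, revcomp, split_long_mems,
                         write_mem_stats, MEM_STATS_HEADER)
from panmem.pangenome import Haplotype, build_pangenome_text
from panmem.rindex import build_rindex, text_from_bytes

from conftest import random_dna
from oracles import naive_matching_statistics, naive_occurrences

GATTA = b"GATTACAT#GATTAGAT#GATTACCAT"


@pytest.fixture(scope="module")
def gatta_index():
    return build_rindex(text_from_bytes(GATTA))


class TestMatchingStatistics:
    def test_full_match_prefix(self, gatta_index):
        ms = matching_statistics(b"GATTAC", gatta_index)
        assert ms.lengths[0] == 6

    def test_taccg_example(self, gatta_index):
        ms = matching_statistics(b"TACCG", gatta_index)
        assert ms.lengths[0] == 4          # TACC occurs, TACCG does not

    def test_absent_characters_all_zero(self, gatta_index):
        ms = matching_statistics(b"NNNN", gatta_index)
        assert ms.lengths == [0, 0, 0, 0]

    def test_empty_read_rejected(self, gatta_index):
        with pytest.raises(ValueError):
            matching_statistics(b"", gatta_index)

    def test_oracle_random_pairs(self):
        rng = random.Random(20)
        for _ in range(40):
            n = rng.randint(20, 600)
            raw = random_dna(rng, n)
            idx = build_rindex(text_from_bytes(raw))
            m = rng.randint(1, 80)
            if rng.random() < 0.5 and n > m:
                start = rng.randrange(n - m)
                read = bytearray(raw[start:start + m])
                for _ in range(rng.randint(0, 4)):
                    read[rng.randrange(m)] = rng.choice(b"ACGTN")
                read = bytes(read)
            else:
                read = random_dna(rng, m, b"ACGTN")
            ms = matching_statistics(read, idx)
            assert ms.lengths == naive_matching_statistics(idx.text.text, read)
            for i, (l, p) in enumerate(zip(ms.lengths, ms.positions)):
                if l > 0:
                    assert idx.text.text[p:p + l] == read[i:i + l]

    def test_read_n_never_matches_text_n(self):
        idx = build_rindex(text_from_bytes(b"ACGTNNNACGT"))
        ms = matching_statistics(b"GTNNA", idx)
        assert ms.lengths[0] == 2          # stops before N despite text NN


class TestExtractMems:
    def test_decreasing_profile_single_mem(self):
        ms = MatchingStatistics(lengths=[4, 3, 2, 1], positions=[0, 1, 2, 3])
        assert extract_mems(ms, SeedingConfig(min_mem_len=2)) == [(0, 4)]

    def test_all_below_minimum(self):
        ms = MatchingStatistics(lengths=[4, 3, 2, 1], positions=[0, 1, 2, 3])
        assert extract_mems(ms, SeedingConfig(min_mem_len=5)) == []

    def test_default_minimum_is_25(self):
        assert SeedingConfig().min_mem_len == 25

    def test_nondecreasing_opens_new_mem(self):
        ms = MatchingStatistics(lengths=[5, 4, 6, 5, 4],
                                positions=[0] * 5)
        assert extract_mems(ms, SeedingConfig(min_mem_len=4)) == \
            [(0, 5), (2, 6)]

    def test_maximality_on_random_inputs(self):
        rng = random.Random(21)
        for _ in range(20):
            raw = random_dna(rng, 300)
            idx = build_rindex(text_from_bytes(raw))
            start = rng.randrange(200)
            read = bytearray(raw[start:start + 60])
            read[rng.randrange(60)] = rng.choice(b"ACGT")
            read = bytes(read)
            ms = matching_statistics(read, idx)
            for i, l in extract_mems(ms, SeedingConfig(min_mem_len=2)):
                sub = read[i:i + l]
                assert naive_occurrences(raw, sub)
                if i + l < len(read):     # right-maximal
                    assert not naive_occurrences(raw, read[i:i + l + 1])
                if i > 0:                 # left-maximal
                    assert not naive_occurrences(raw, read[i - 1:i + l])


class TestSplitLongMems:
    def test_length_100_two_halves(self):
        assert split_long_mems([(0, 100)]) == [(0, 50), (50, 50)]

    def test_length_50_boundary_unsplit(self):
        assert split_long_mems([(3, 50)]) == [(3, 50)]

    def test_length_51(self):
        assert split_long_mems([(0, 51)]) == [(0, 26), (26, 25)]


class TestLocateSeeds:
    def test_occurrence_enumeration(self, gatta_index):
        seeds = locate_seeds([(0, 5)], b"GATTA", "+", gatta_index,
                             SeedingConfig(min_mem_len=2))
        assert len(seeds) == 1
        occs = sorted(seeds[0].occurrences)
        assert [gatta_index.text.local_to_global(d, l) for d, l in occs] == \
            naive_occurrences(GATTA, b"GATTA")
        assert seeds[0].occ_total_uncapped == 3

    def test_per_genome_cap(self):
        haps = [Haplotype("S0#1", "ACGT" * 50, "c"),
                Haplotype("S0#2", "ACGT" * 50, "c"),
                Haplotype("S1#1", "ACGT" * 50, "c")]
        idx = build_rindex(build_pangenome_text(haps))
        cfg = SeedingConfig(min_mem_len=2, max_occ_per_genome=10)
        seeds = locate_seeds([(0, 4)], b"ACGT", "+", idx, cfg)
        per_genome = {}
        for d, _ in seeds[0].occurrences:
            g = idx.text.genome_of_doc[d]
            per_genome[g] = per_genome.get(g, 0) + 1
        assert all(v <= 10 for v in per_genome.values())
        assert set(per_genome) == {"S0", "S1"}
        assert seeds[0].occ_total_uncapped > sum(per_genome.values())


def _seed(count, length=30, strand="+"):
    return Seed(read_start=0, length=length, strand=strand,
                occurrences=[(0, i) for i in range(count)],
                occ_total_uncapped=count)


class TestFrequencyFilter:
    CFG = SeedingConfig(freq_filter_enabled=True)

    def test_dominant_seed_removed(self):
        seeds = [_seed(600), _seed(300), _seed(100)]
        kept = frequency_filter(seeds, self.CFG)
        assert [len(s.occurrences) for s in kept] == [300, 100]

    def test_balanced_seeds_kept(self):
        seeds = [_seed(400), _seed(400), _seed(200)]
        assert len(frequency_filter(seeds, self.CFG)) == 3

    def test_single_seed_guard(self):
        seeds = [_seed(600)]
        assert frequency_filter(seeds, self.CFG) == seeds

    def test_disabled_passthrough(self):
        seeds = [_seed(600), _seed(1)]
        assert frequency_filter(seeds, SeedingConfig()) == seeds

    def test_filters_never_mutate_survivors(self):
        seeds = [_seed(600), _seed(300), _seed(100)]
        before = [(s.read_start, s.length, list(s.occurrences))
                  for s in seeds[1:]]
        kept = frequency_filter(seeds, self.CFG)
        after = [(s.read_start, s.length, list(s.occurrences)) for s in kept]
        assert before == after


class TestOrientationFilter:
    CFG = SeedingConfig(orientation_filter_enabled=True)

    def test_short_strand_dropped(self):
        fwd = [_seed(1, length=80)]
        rc = [_seed(1, length=20, strand="-")]
        f, r = orientation_filter(fwd, rc, self.CFG)
        assert f and not r

    def test_below_gap_both_kept(self):
        fwd = [_seed(1, length=60)]
        rc = [_seed(1, length=20, strand="-")]
        f, r = orientation_filter(fwd, rc, self.CFG)
        assert f and r

    def test_empty_strand_never_triggers(self):
        fwd = [_seed(1, length=80)]
        f, r = orientation_filter(fwd, [], self.CFG)
        assert f == fwd and r == []


class TestMemStatsCsv:
    def test_header_only_for_empty_input(self, tmp_path):
        path = tmp_path / "stats.csv"
        write_mem_stats(str(path), [])
        rows = list(csv.reader(path.open()))
        assert rows == [MEM_STATS_HEADER]

    def test_row_totals(self, tmp_path):
        fwd = [_seed(3, length=40), _seed(2, length=30)]
        rc = [_seed(1, length=25, strand="-")]
        row = mem_stats_rows("r1", fwd, rc, fwd + rc, fwd)
        assert row[0] == "r1"
        assert row[1] == 2 and row[2] == 1
        assert row[5] == 6 and row[6] == 6
        assert row[7] == 6 and row[8] == 5
        path = tmp_path / "stats.csv"
        write_mem_stats(str(path), [row])
        rows = list(csv.reader(path.open()))
        assert len(rows) == 2


def test_revcomp():
    assert revcomp(b"ACGTN") == b"NACGT"
    assert revcomp(revcomp(b"GATTACA")) == b"GATTACA"
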