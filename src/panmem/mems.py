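"""MEM seeding: two-pass matching statistics, extraction, splitting, filters.

The backward pass walks the read right-to-left through the index keeping one
BWT row and its SA value; when the extension fails the thresholds decide
which neighboring run to jump to.  The forward pass turns the recorded
positions into lengths: a plain LF step extends the previous match by one,
while a threshold jump forces a direct text comparison (amortized cheap).
A MEM starts wherever the length profile is non-decreasing.

``N`` in a read matches nothing (treated as an exhausted character), and a
read base never matches an ``N`` in the text.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .rindex import CharacterExhausted, RIndex

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


@dataclass
class MatchingStatistics:
    lengths: List[int]        # longest match length starting at each position
    positions: List[int]      # a global text position of that match (-1 if 0)


@dataclass
class Seed:
    """A (possibly split) MEM on one strand with its located occurrences."""

    read_start: int           # offset in the oriented read
    length: int
    strand: str               # "+" or "-"
    occurrences: List[Tuple[int, int]] = field(default_factory=list)
    occ_total_uncapped: int = 0


@dataclass
class SeedingConfig:
    min_mem_len: int = 25
    split_threshold: int = 50
    max_occ_per_genome: int = 1000
    freq_filter_enabled: bool = False
    freq_fraction: float = 0.5
    orientation_filter_enabled: bool = False
    orientation_gap: int = 50

    def __post_init__(self):
        if min(self.min_mem_len, self.split_threshold,
               self.max_occ_per_genome, self.orientation_gap) <= 0:
            raise ValueError("seeding parameters must be positive")
        if not 0 < self.freq_fraction <= 1:
            raise ValueError("freq_fraction must be in (0, 1]")


_N = ord("N")


def matching_statistics(read: bytes, idx: RIndex) -> MatchingStatistics:
    """Matching statistics of ``read`` against the indexed text.

    ``lengths[i]`` is the length of the longest prefix of ``read[i:]`` that
    occurs in the text and ``positions[i]`` one global position where it does.
    """
    m = len(read)
    if m == 0:
        raise ValueError("empty read")
    text = idx.text.text
    n = idx.n
    positions = [-1] * m
    jumped = [True] * m
    ok = [False] * m

    row = 0
    sa = n - 1                      # SA[0]
    ms_step = idx.ms_step
    for i in range(m - 1, -1, -1):
        c = read[i]
        if c == _N:
            # N in reads never matches; restart from the terminator row
            row, sa = 0, n - 1
            continue
        try:
            row, sa, j = ms_step(row, sa, c)
        except CharacterExhausted:
            row, sa = 0, n - 1
            continue
        positions[i] = sa
        jumped[i] = j
        ok[i] = True

    lengths = [0] * m
    prev_len = 0
    for i in range(m - 1, -1, -1):
        if not ok[i]:
            prev_len = 0
            continue
        if not jumped[i]:
            prev_len = prev_len + 1
        else:
            # direct comparison from the recorded position
            p = positions[i]
            limit = min(m - i, n - p)
            k = 0
            # a read N never matches, not even a text N
            while (k < limit and read[i + k] != _N
                   and text[p + k] == read[i + k]):
                k += 1
            prev_len = k
        lengths[i] = prev_len
    return MatchingStatistics(lengths=lengths, positions=positions)


def extract_mems(ms: MatchingStatistics,
                 cfg: Optional[SeedingConfig] = None) -> List[Tuple[int, int]]:
    """(read_start, length) of every MEM with length >= min_mem_len.

    Position ``i`` opens a MEM iff its length clears the minimum and the
    length profile does not decrease coming into it (``len[i-1] <= len[i]``).
    """
    if cfg is None:
        cfg = SeedingConfig()
    out = []
    lens = ms.lengths
    for i, li in enumerate(lens):
        if li >= cfg.min_mem_len and (i == 0 or lens[i - 1] <= li):
            out.append((i, li))
    return out


def split_long_mems(mems: Sequence[Tuple[int, int]],
                    cfg: Optional[SeedingConfig] = None,
                    ) -> List[Tuple[int, int]]:
    """Split MEMs longer than the threshold into two adjacent half-MEMs."""
    if cfg is None:
        cfg = SeedingConfig()
    out = []
    for start, length in mems:
        if length > cfg.split_threshold:
            first = (length + 1) // 2
            out.append((start, first))
            out.append((start + first, length - first))
        else:
            out.append((start, length))
    return out


def locate_seeds(seeds: Sequence[Tuple[int, int]], read: bytes, strand: str,
                 idx: RIndex, cfg: Optional[SeedingConfig] = None,
                 ) -> List[Seed]:
    """Locate every seed's occurrences, capped per input genome.

    Occurrences are (doc, local offset) pairs in enumeration order; for each
    genome (a sample's haplotypes count as one genome, per ``genome_of_doc``)
    at most ``max_occ_per_genome`` occurrences are kept.
    """
    if cfg is None:
        cfg = SeedingConfig()
    text = idx.text
    out = []
    for start, length in seeds:
        rng = idx.find(read[start:start + length])
        if rng.empty:
            raise RuntimeError("seed string absent from index (internal error)")
        positions = idx.locate(rng)
        per_genome: Dict[str, int] = {}
        occs: List[Tuple[int, int]] = []
        for g in positions:
            doc, local = text.global_to_local(g)
            genome = text.genome_of_doc[doc]
            cnt = per_genome.get(genome, 0)
            if cnt < cfg.max_occ_per_genome:
                per_genome[genome] = cnt + 1
                occs.append((doc, local))
        out.append(Seed(read_start=start, length=length, strand=strand,
                        occurrences=occs, occ_total_uncapped=len(positions)))
    return out


def frequency_filter(seeds: Sequence[Seed],
                     cfg: Optional[SeedingConfig] = None) -> List[Seed]:
    """Drop seeds whose occurrence count is >= fraction of the read's total.

    Skipped entirely when the read has a single seed (pooled over strands).
    """
    if cfg is None:
        cfg = SeedingConfig()
    if not cfg.freq_filter_enabled or len(seeds) <= 1:
        return list(seeds)
    total = sum(len(s.occurrences) for s in seeds)
    if total == 0:
        return list(seeds)
    return [s for s in seeds
            if len(s.occurrences) < cfg.freq_fraction * total]


def orientation_filter(fwd: Sequence[Seed], rc: Sequence[Seed],
                       cfg: Optional[SeedingConfig] = None,
                       ) -> Tuple[List[Seed], List[Seed]]:
    """Drop the strand with the smaller mean MEM length when means differ
    by at least ``orientation_gap``.  A strand without seeds never causes
    the other to be dropped."""
    if cfg is None:
        cfg = SeedingConfig()
    fwd, rc = list(fwd), list(rc)
    if not cfg.orientation_filter_enabled or not fwd or not rc:
        return fwd, rc
    mean_f = sum(s.length for s in fwd) / len(fwd)
    mean_r = sum(s.length for s in rc) / len(rc)
    if abs(mean_f - mean_r) >= cfg.orientation_gap:
        if mean_f < mean_r:
            return [], rc
        return fwd, []
    return fwd, rc


MEM_STATS_HEADER = [
    "read_id", "fwd_mems", "rc_mems", "mean_mem_len", "max_mem_len",
    "occ_before_cap", "occ_after_cap", "occ_after_freq", "occ_after_orient",
]


def mem_stats_rows(read_id: str, fwd: Sequence[Seed], rc: Sequence[Seed],
                   after_freq: Sequence[Seed],
                   after_orient: Sequence[Seed]) -> List:
    """One CSV row of per-read MEM statistics."""
    both = list(fwd) + list(rc)
    lens = [s.length for s in both]
    return [
        read_id,
        len(fwd),
        len(rc),
        round(sum(lens) / len(lens), 3) if lens else 0,
        max(lens) if lens else 0,
        sum(s.occ_total_uncapped for s in both),
        sum(len(s.occurrences) for s in both),
        sum(len(s.occurrences) for s in after_freq),
        sum(len(s.occurrences) for s in after_orient),
    ]


def write_mem_stats(path: str, rows: Iterable[List]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEM_STATS_HEADER)
        for row in rows:
            writer.writerow(row)
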