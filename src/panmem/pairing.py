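"""Insert-size model, paired-end selection, orphan recovery, mapping quality.

The single-end mapping quality is

    Q = min(60, 6.02 * (s1 - s2) * i / (4*m1) - 4.343 * ln(n + 1))

with confidence ``i = 1 - (m1*l - s1) / ((m1 + m2)*l)`` (4.343 = 10/ln 10,
so the second term is 10*log10(n+1)); ``n`` counts distinct secondary scores
within a fixed fraction of the best.  The paired value for mate i is

    Qi = min(max(Q, min(Q', Q + 40)), 6.02 * (s1p - s2p) / m1)

where Q' reuses the first formula on paired score sums.  Values are
truncated to integers and clamped to [0, 60].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .alignment import Alignment
from .extension import ScoringScheme, fit_align

MAPQ_MAX = 60


@dataclass
class InsertSizeModel:
    """Welford online mean/variance of observed insert sizes."""

    count: int = 0
    mean: float = 0.0
    m2: float = 0.0

    def update(self, x: float) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)

    @property
    def variance(self) -> float:
        return self.m2 / (self.count - 1) if self.count >= 2 else 0.0

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    @property
    def usable(self) -> bool:
        return self.count >= 2

    def window(self, n_sd: float = 4.0) -> Tuple[float, float]:
        return self.mean - n_sd * self.sd, self.mean + n_sd * self.sd


@dataclass
class PairingConfig:
    max_model_pairs: int = 1000
    insert_sd_window: float = 4.0
    orphan_recovery_enabled: bool = True
    orphan_floor_fraction: float = 0.5   # of the perfect score m1*l
    mapq_window_fraction: float = 0.8


def insert_size(a1: Alignment, a2: Alignment) -> int:
    """Outer distance: leftmost start to rightmost end (TLEN convention)."""
    left = min(a1.position, a2.position)
    right = max(a1.end, a2.end)
    return right - left


def estimate_insert_size(unique_pairs: Sequence[Tuple[Alignment, Alignment]],
                         max_pairs: int = 1000) -> InsertSizeModel:
    """Welford model over the first ``max_pairs`` uniquely aligned pairs."""
    model = InsertSizeModel()
    for a1, a2 in unique_pairs[:max_pairs]:
        model.update(insert_size(a1, a2))
    return model


def _same_contig(a1: Alignment, a2: Alignment) -> bool:
    c1 = a1.contig if a1.contig is not None else a1.doc
    c2 = a2.contig if a2.contig is not None else a2.doc
    return c1 == c2


def pair_select(cands1: Sequence[Alignment], cands2: Sequence[Alignment],
                model: Optional[InsertSizeModel],
                cfg: Optional[PairingConfig] = None,
                ) -> Tuple[Optional[Alignment], Optional[Alignment], List[float]]:
    """Best concordant pair, or an anchor/orphan split.

    A valid pair is on one contig, opposite strands, with insert inside the
    mean +- 4 sd window (hard constraint); among those the score sum wins.
    Returns (a1, a2, valid_pair_sums); a2 (or a1) is None in orphan state.
    """
    if cfg is None:
        cfg = PairingConfig()
    pair_sums: List[float] = []
    best: Optional[Tuple[Alignment, Alignment]] = None
    best_sum = -math.inf
    if model is not None and model.usable and cands1 and cands2:
        lo, hi = model.window(cfg.insert_sd_window)
        for a1 in cands1:
            for a2 in cands2:
                if not _same_contig(a1, a2) or a1.strand == a2.strand:
                    continue
                ins = insert_size(a1, a2)
                if not (lo <= ins <= hi):
                    continue
                s = a1.score + a2.score
                pair_sums.append(s)
                if s > best_sum:
                    best_sum = s
                    best = (a1, a2)
    if best is not None:
        return best[0], best[1], sorted(pair_sums, reverse=True)
    # orphan state: the higher-scoring mate anchors
    b1 = cands1[0] if cands1 else None
    b2 = cands2[0] if cands2 else None
    if b1 is not None and b2 is not None:
        # no concordant combination: keep both as independent single-end hits
        return b1, b2, []
    return b1, b2, []


def orphan_recover(anchor: Alignment, orphan_seq: bytes, hap_seq: bytes,
                   model: InsertSizeModel, scheme: ScoringScheme,
                   cfg: Optional[PairingConfig] = None,
                   ) -> Optional[Alignment]:
    """Align the unaligned mate inside the insert window around its anchor.

    ``orphan_seq`` must already be oriented to the strand opposite the
    anchor's.  ``hap_seq`` is the anchor's haplotype document (or reference
    contig) sequence; coordinates follow the anchor's space.  Accepted iff
    the fit score clears ``orphan_floor_fraction * m1 * l`` (inclusive
    window bounds).
    """
    if cfg is None:
        cfg = PairingConfig()
    if not model.usable:
        return None
    lo, hi = model.window(cfg.insert_sd_window)
    l = len(orphan_seq)
    # candidate windows on both sides of the anchor
    win_lo = max(0, int(anchor.position + lo) - l - 1)
    win_hi = min(len(hap_seq), int(anchor.position + hi) + 1)
    windows = []
    if win_hi > win_lo:
        windows.append((win_lo, win_hi))
    wlo2 = max(0, int(anchor.end - hi) - 1)
    whi2 = min(len(hap_seq), int(anchor.end - lo) + l + 1)
    if whi2 > wlo2 and (wlo2, whi2) != windows[0:1]:
        windows.append((wlo2, whi2))

    floor = cfg.orphan_floor_fraction * scheme.match * l
    best: Optional[Alignment] = None
    for wlo, whi in windows:
        window = hap_seq[wlo:whi]
        if len(window) < 1:
            continue
        score, off, cigar = fit_align(orphan_seq, window, scheme)
        if score < floor:
            continue
        cand = Alignment(
            doc=anchor.doc, strand="-" if anchor.strand == "+" else "+",
            hap_start=wlo + off, cigar=cigar, score=score,
            contig=anchor.contig,
            ref_start=(wlo + off) if anchor.ref_start is not None else None)
        ins = insert_size(anchor, cand)
        if not (lo <= ins <= hi):
            continue
        if best is None or cand.score > best.score:
            best = cand
    return best


# ---------------------------------------------------------------------------
# mapping quality
# ---------------------------------------------------------------------------

def count_secondary_scores(scores: Sequence[float], s1: float,
                           window_fraction: float = 0.8) -> int:
    """Distinct scores strictly below s1 but within the fixed range of it."""
    return len({s for s in scores if s < s1 and s >= window_fraction * s1})


def confidence(s1: float, read_len: int, scheme: ScoringScheme) -> float:
    m1, m2 = scheme.match, scheme.mismatch
    return 1.0 - (m1 * read_len - s1) / ((m1 + m2) * read_len)


def mapq_single(s1: float, s2: float, n: int, read_len: int,
                scheme: ScoringScheme) -> int:
    """Single-end MAPQ; truncated and clamped to [0, 60]."""
    i = confidence(s1, read_len, scheme)
    q = 6.02 * (s1 - s2) * i / (4.0 * scheme.match) - 4.343 * math.log(n + 1)
    q = min(MAPQ_MAX, q)
    return max(0, min(MAPQ_MAX, int(q)))


def mapq_paired(q_single: int, q_prime: int, s1p: float, s2p: float,
                scheme: ScoringScheme) -> int:
    """Mate MAPQ: pair evidence may elevate a low mate by at most 40."""
    inner = max(q_single, min(q_prime, q_single + 40))
    cap = 6.02 * (s1p - s2p) / scheme.match
    q = min(inner, cap)
    return max(0, min(MAPQ_MAX, int(q)))
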