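"""Colinear chaining of seed occurrences, minimap2-style.

Anchors from one (haplotype, strand) are chained by dynamic programming:

    f(j) = max( l_j,  max_i f(i) + gain(i,j) - cost(i,j) )

over predecessors with strictly smaller read and haplotype coordinates and
both gaps bounded by ``max_gap``, where ``gain = min(dy, dx, l_j)`` and the
gap cost for diagonal difference ``d`` is ``0`` if ``d == 0`` else
``c1*d + c2*log2(d)``.  Backtracking greedily peels disjoint chains in
descending score order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple


@dataclass(frozen=True)
class Anchor:
    x: int          # read start (oriented read)
    y: int          # haplotype start
    l: int          # length
    doc: int        # haplotype (document) index
    strand: str     # "+" or "-"


@dataclass
class Chain:
    anchors: List[Anchor]
    score: float
    doc: int
    strand: str
    leftmost_lifted_pos: Optional[Tuple[str, int]] = None

    def __post_init__(self):
        for a, b in zip(self.anchors, self.anchors[1:]):
            assert b.x > a.x and b.y > a.y, "chain anchors must be colinear"


@dataclass
class ChainConfig:
    min_chain_score: float = 40.0
    max_chains: int = 5
    max_gap: int = 500
    uniqueness_filter_enabled: bool = True
    gap_c1: float = 0.12
    gap_c2: float = 0.5

    def __post_init__(self):
        if self.min_chain_score <= 0 or self.max_chains <= 0 or self.max_gap <= 0:
            raise ValueError("chain parameters must be positive")


def gap_cost(d: int, cfg: ChainConfig) -> float:
    if d == 0:
        return 0.0
    return cfg.gap_c1 * d + cfg.gap_c2 * math.log2(d)


def pair_score(a: Anchor, b: Anchor, cfg: ChainConfig) -> Optional[float]:
    """Transition gain minus gap cost from anchor ``a`` to ``b`` (or None
    when ``b`` is not an admissible successor of ``a``)."""
    dx = b.x - a.x
    dy = b.y - a.y
    if dx <= 0 or dy <= 0 or dx > cfg.max_gap or dy > cfg.max_gap:
        return None
    gain = min(dy, dx, b.l)
    return gain - gap_cost(abs(dy - dx), cfg)


def chain_anchors(anchors: Sequence[Anchor],
                  cfg: Optional[ChainConfig] = None) -> List[Chain]:
    """DP chaining of anchors from a single (haplotype, strand)."""
    if cfg is None:
        cfg = ChainConfig()
    if not anchors:
        return []
    doc, strand = anchors[0].doc, anchors[0].strand
    assert all(a.doc == doc and a.strand == strand for a in anchors)
    aa = sorted(anchors, key=lambda a: (a.y, a.x))
    k = len(aa)
    f = [float(a.l) for a in aa]
    parent = [-1] * k
    for j in range(1, k):
        bj = aa[j]
        best, arg = f[j], -1
        for i in range(j):
            step = pair_score(aa[i], bj, cfg)
            if step is None:
                continue
            cand = f[i] + step
            if cand > best:
                best, arg = cand, i
        f[j] = best
        parent[j] = arg

    order = sorted(range(k), key=lambda j: (-f[j], aa[j].y, aa[j].x))
    used = [False] * k
    chains: List[Chain] = []
    for j in order:
        if used[j]:
            continue
        path = []
        i = j
        while i != -1 and not used[i]:
            path.append(i)
            used[i] = True
            i = parent[i]
        path.reverse()
        chains.append(Chain(anchors=[aa[i] for i in path], score=f[j],
                            doc=doc, strand=strand))
    return chains


def select_chains(chains: Sequence[Chain],
                  cfg: Optional[ChainConfig] = None) -> List[Chain]:
    """Score cutoff then deterministic top-k selection across all groups."""
    if cfg is None:
        cfg = ChainConfig()
    kept = [c for c in chains if c.score >= cfg.min_chain_score]
    kept.sort(key=lambda c: (-c.score, c.doc, c.anchors[0].y, c.strand))
    return kept[:cfg.max_chains]


def uniqueness_filter(chains: Sequence[Chain],
                      cfg: Optional[ChainConfig] = None) -> List[Chain]:
    """Discard a chain whose (score, lifted leftmost position) repeats an
    earlier chain's pair.  Chains must carry ``leftmost_lifted_pos``."""
    if cfg is None:
        cfg = ChainConfig()
    if not cfg.uniqueness_filter_enabled:
        return list(chains)
    seen = set()
    out = []
    for c in chains:
        key = (round(c.score, 6), c.leftmost_lifted_pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out
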