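"""Base-level alignment: affine-gap DP between chain anchors and at flanks.

Anchors contribute exact-match segments; the read/haplotype gaps between
consecutive anchors are filled by global affine-gap alignment (Gotoh), and
the flanks are aligned by extension alignment that soft-clips wherever the
score would go negative.  A gap of length ``k`` costs ``gap_open +
k*gap_extend``; matches score ``+m1``, mismatches ``-m2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .alignment import (Alignment, Cigar, collapse_matches, merge_cigar,
                        normalize_cigar)
from .chaining import Chain

NEG = float("-inf")
_N = ord("N")


@dataclass
class ScoringScheme:
    match: int = 2          # m1
    mismatch: int = 4       # m2 (penalty, applied negatively)
    gap_open: int = 4
    gap_extend: int = 2

    def __post_init__(self):
        if self.match <= 0 or min(self.mismatch, self.gap_open,
                                  self.gap_extend) < 0:
            raise ValueError("invalid scoring scheme")

    def sub(self, a: int, b: int) -> int:
        if a == b and a != _N:
            return self.match
        return -self.mismatch


def _gotoh(q: bytes, t: bytes, scheme: ScoringScheme, free_t_start: bool):
    """Affine DP matrices + tracebacks.  Returns (H, E, F, tbH, tbE, tbF).

    ``tbH[i][j]``: 0 diagonal, 1 from E (deletion, consumes target), 2 from F
    (insertion, consumes query).  ``tbE``/``tbF``: True when the gap extends.
    """
    m, n = len(q), len(t)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    tbH = [[0] * (n + 1) for _ in range(m + 1)]
    tbE = [[False] * (n + 1) for _ in range(m + 1)]
    tbF = [[False] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0
    for j in range(1, n + 1):
        if free_t_start:
            H[0][j] = 0
        else:
            E[0][j] = -(go + j * ge)
            H[0][j] = E[0][j]
            tbE[0][j] = j > 1
            tbH[0][j] = 1
    for i in range(1, m + 1):
        F[i][0] = -(go + i * ge)
        H[i][0] = F[i][0]
        tbF[i][0] = i > 1
        tbH[i][0] = 2
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e_ext = Ei[j - 1] - ge
            e_open = Hi[j - 1] - go - ge
            if e_ext >= e_open:
                Ei[j] = e_ext
                tbE[i][j] = True
            else:
                Ei[j] = e_open
            f_ext = Fi1[j] - ge
            f_open = Hi1[j] - go - ge
            if f_ext >= f_open:
                Fi[j] = f_ext
                tbF[i][j] = True
            else:
                Fi[j] = f_open
            diag = Hi1[j - 1] + scheme.sub(qi, t[j - 1])
            best, tb = diag, 0
            if Ei[j] > best:
                best, tb = Ei[j], 1
            if Fi[j] > best:
                best, tb = Fi[j], 2
            Hi[j] = best
            tbH[i][j] = tb
    return H, E, F, tbH, tbF, tbE


def _traceback(q: bytes, t: bytes, tbH, tbF, tbE, i: int, j: int,
               stop_row0_any_col: bool) -> Tuple[Cigar, int]:
    """Walk back from (i, j); returns (cigar, start column)."""
    ops: Cigar = []
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or (j > 0 and not stop_row0_any_col):
        if state == 0:
            state = tbH[i][j]
            if state == 0:
                if i == 0 or j == 0:
                    break
                ops.append(("=" if q[i - 1] == t[j - 1] and q[i - 1] != _N
                            else "X", 1))
                i -= 1
                j -= 1
        elif state == 1:   # E: gap consuming target
            ops.append(("D", 1))
            ext = tbE[i][j]
            j -= 1
            state = 1 if ext else 0
        else:              # F: gap consuming query
            ops.append(("I", 1))
            ext = tbF[i][j]
            i -= 1
            state = 2 if ext else 0
    ops.reverse()
    return merge_cigar(ops), j


def affine_global(q: bytes, t: bytes,
                  scheme: Optional[ScoringScheme] = None,
                  ) -> Tuple[float, Cigar]:
    """Global affine-gap alignment of the full query vs the full target."""
    if scheme is None:
        scheme = ScoringScheme()
    if not q and not t:
        return 0.0, []
    if not q:
        return -(scheme.gap_open + len(t) * scheme.gap_extend), [("D", len(t))]
    if not t:
        return -(scheme.gap_open + len(q) * scheme.gap_extend), [("I", len(q))]
    H, E, F, tbH, tbF, tbE = _gotoh(q, t, scheme, free_t_start=False)
    cigar, _ = _traceback(q, t, tbH, tbF, tbE, len(q), len(t),
                          stop_row0_any_col=False)
    return float(H[len(q)][len(t)]), cigar


def affine_extend(q: bytes, t: bytes,
                  scheme: Optional[ScoringScheme] = None,
                  ) -> Tuple[float, int, int, Cigar]:
    """Extension alignment from the origin; stops where the score peaks.

    Returns (score, query consumed, target consumed, cigar).  The empty
    extension scores 0, so a negative-score prefix is clipped entirely.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not q or not t:
        return 0.0, 0, 0, []
    H, E, F, tbH, tbF, tbE = _gotoh(q, t, scheme, free_t_start=False)
    best, bi, bj = 0.0, 0, 0
    for i in range(len(q) + 1):
        Hi = H[i]
        for j in range(len(t) + 1):
            # prefer longer query consumption on ties for fuller alignments
            if Hi[j] > best or (Hi[j] == best and i > bi):
                best, bi, bj = Hi[j], i, j
    if bi == 0 and bj == 0:
        return 0.0, 0, 0, []
    cigar, _ = _traceback(q, t, tbH, tbF, tbE, bi, bj, stop_row0_any_col=False)
    return float(best), bi, bj, cigar


def fit_align(q: bytes, t: bytes,
              scheme: Optional[ScoringScheme] = None,
              ) -> Tuple[float, int, Cigar]:
    """Glocal alignment: full query against a free-floating target window.

    Returns (score, target start offset, cigar).  Used by orphan recovery.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not q:
        raise ValueError("empty query")
    if not t:
        return -(scheme.gap_open + len(q) * scheme.gap_extend), 0, [("I", len(q))]
    H, E, F, tbH, tbF, tbE = _gotoh(q, t, scheme, free_t_start=True)
    m = len(q)
    best, bj = NEG, 0
    for j in range(len(t) + 1):
        if H[m][j] > best:
            best, bj = H[m][j], j
    cigar, j0 = _traceback(q, t, tbH, tbF, tbE, m, bj, stop_row0_any_col=True)
    return float(best), j0, cigar


def score_cigar(cigar: Cigar, read: bytes, window: bytes,
                scheme: Optional[ScoringScheme] = None) -> float:
    """Recompute the affine score of a CIGAR from scratch (consistency check).

    ``window`` must start exactly at the alignment's target start.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not cigar:
        raise ValueError("empty CIGAR")
    from .alignment import cigar_query_len

    if cigar_query_len(cigar) != len(read):
        raise ValueError("CIGAR does not consume the read")
    score = 0.0
    qi = ti = 0
    for op, n in cigar:
        if op in ("M", "=", "X"):
            for k in range(n):
                score += scheme.sub(read[qi + k], window[ti + k])
            qi += n
            ti += n
        elif op == "I":
            score -= scheme.gap_open + n * scheme.gap_extend
            qi += n
        elif op == "D":
            score -= scheme.gap_open + n * scheme.gap_extend
            ti += n
        elif op == "S":
            qi += n
        else:
            raise ValueError(f"unknown op {op!r}")
    if qi != len(read):
        raise ValueError("CIGAR does not consume the read")
    return score


def _cigar_nm(cigar: Cigar, read: bytes, window: bytes) -> int:
    nm = 0
    qi = ti = 0
    for op, n in cigar:
        if op in ("M", "=", "X"):
            for k in range(n):
                if read[qi + k] != window[ti + k] or read[qi + k] == _N:
                    nm += 1
            qi += n
            ti += n
        elif op == "I":
            nm += n
            qi += n
        elif op == "D":
            nm += n
            ti += n
        elif op == "S":
            qi += n
    return nm


def fill_between_anchors(read: bytes, hap_seq: bytes, chain: Chain,
                         scheme: Optional[ScoringScheme] = None,
                         doc_name: str = "", read_id: str = "",
                         cigar_mode: str = "M") -> Alignment:
    """Full alignment of a chained read against its haplotype.

    ``hap_seq`` is the complete haplotype document sequence; anchors carry
    haplotype-local coordinates.  Returns an on-haplotype Alignment.
    """
    if scheme is None:
        scheme = ScoringScheme()
    # trim anchor overlaps so segments are disjoint in both coordinates
    anchors: List[Tuple[int, int, int]] = []
    px = py = -1
    for a in chain.anchors:
        x, y, l = a.x, a.y, a.l
        delta = max(px - x, py - y, 0) if anchors else 0
        if delta >= l:
            continue
        x, y, l = x + delta, y + delta, l - delta
        anchors.append((x, y, l))
        px, py = x + l, y + l
    if not anchors:
        raise ValueError("chain has no usable anchors")
    for x, y, l in anchors:
        assert read[x:x + l] == hap_seq[y:y + l], "anchor does not match"

    cigar: Cigar = []
    score = 0.0
    x0, y0, _ = anchors[0]

    # left flank (extension leftward, reversed)
    lq = read[:x0][::-1]
    lt_avail = min(y0, len(lq) + 40)
    lt = hap_seq[y0 - lt_avail:y0][::-1]
    lscore, lqi, lti, lcig = affine_extend(lq, lt, scheme)
    start = y0 - lti
    left_cigar = [(op, n) for op, n in lcig][::-1]
    clip = len(lq) - lqi
    if clip:
        left_cigar = [("S", clip)] + left_cigar
    cigar.extend(left_cigar)
    score += lscore

    # anchors and inter-anchor fills
    for idx, (x, y, l) in enumerate(anchors):
        if idx > 0:
            pxe = anchors[idx - 1][0] + anchors[idx - 1][2]
            pye = anchors[idx - 1][1] + anchors[idx - 1][2]
            qgap = x - pxe
            tgap = y - pye
            if qgap == 0 and tgap == 0:
                pass
            elif qgap == 0:
                cigar.append(("D", tgap))
                score -= scheme.gap_open + tgap * scheme.gap_extend
            elif tgap == 0:
                cigar.append(("I", qgap))
                score -= scheme.gap_open + qgap * scheme.gap_extend
            else:
                gscore, gcig = affine_global(read[pxe:x], hap_seq[pye:y],
                                             scheme)
                cigar.extend(gcig)
                score += gscore
        cigar.append(("=", l))
        score += l * scheme.match

    # right flank
    xe = anchors[-1][0] + anchors[-1][2]
    ye = anchors[-1][1] + anchors[-1][2]
    rq = read[xe:]
    rt = hap_seq[ye:ye + len(rq) + 40]
    rscore, rqi, rti, rcig = affine_extend(rq, rt, scheme)
    cigar.extend(rcig)
    clip = len(rq) - rqi
    if clip:
        cigar.append(("S", clip))
    score += rscore

    cigar = normalize_cigar(cigar)
    if cigar_mode == "M":
        cigar = collapse_matches(cigar)
    nm = _cigar_nm(cigar, read, hap_seq[start:])
    return Alignment(doc=doc_name or str(chain.doc), strand=chain.strand,
                     hap_start=start, cigar=cigar, score=score, nm=nm,
                     read_id=read_id)
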