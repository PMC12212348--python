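"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own data structures: plain scans,
suffix sorts, exhaustive enumeration, and textbook DP.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple


def naive_suffix_array(text: bytes) -> List[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_occurrences(text: bytes, pattern: bytes) -> List[int]:
    if not pattern:
        return []
    out = []
    start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def naive_matching_statistics(text: bytes, read: bytes) -> List[int]:
    """Longest-prefix lengths by full scan; read N matches nothing."""
    n, m = len(text), len(read)
    N = ord("N")
    lens = []
    for i in range(m):
        best = 0
        for p in range(n):
            k = 0
            while (i + k < m and p + k < n and read[i + k] != N
                   and text[p + k] == read[i + k]):
                k += 1
            if k > best:
                best = k
        lens.append(best)
    return lens


def brute_best_chain_score(anchors, cfg) -> float:
    """Exhaustive search over all increasing anchor subsequences."""
    from panmem.chaining import pair_score

    k = len(anchors)
    best = 0.0
    for mask in range(1, 1 << k):
        subset = [anchors[i] for i in range(k) if mask >> i & 1]
        subset.sort(key=lambda a: (a.x, a.y))
        ok = True
        score = float(subset[0].l)
        for a, b in zip(subset, subset[1:]):
            step = pair_score(a, b, cfg)
            if step is None:
                ok = False
                break
            score += step
        if ok and score > best:
            best = score
    return best


def brute_affine_global(q: bytes, t: bytes, match: int, mismatch: int,
                        gap_open: int, gap_extend: int) -> float:
    """Textbook three-state affine global alignment score (recursive memo)."""
    import functools

    NEG = float("-inf")

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        best = NEG
        if state == 0 and i > 0 and j > 0:
            s = match if q[i - 1] == t[j - 1] else -mismatch
            best = max(rec(i - 1, j - 1, st) for st in (0, 1, 2)) + s
        elif state == 1 and j > 0:
            best = max(rec(i, j - 1, 1) - gap_extend,
                       max(rec(i, j - 1, st) for st in (0, 2))
                       - gap_open - gap_extend)
        elif state == 2 and i > 0:
            best = max(rec(i - 1, j, 2) - gap_extend,
                       max(rec(i - 1, j, st) for st in (0, 1))
                       - gap_open - gap_extend)
        return best

    result = max(rec(len(q), len(t), st) for st in (0, 1, 2))
    rec.cache_clear()
    return result


def two_pass_mean_sd(xs: Sequence[float]) -> Tuple[float, float]:
    n = len(xs)
    mean = sum(xs) / n
    if n < 2:
        return mean, 0.0
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    return mean, var ** 0.5
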