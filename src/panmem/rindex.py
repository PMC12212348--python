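"""Run-length BWT index with run-boundary SA samples, thresholds, and phi.

Construction is desk-scale: the full suffix array is built by numpy prefix
doubling, the LCP array by Kasai's recurrence, and everything is then
compressed down to per-run structures:

* per character ``c``: row starts/lengths of the ``c``-runs, cumulative
  ``c``-counts, SA samples at each run's first and last row, and the
  thresholds (row of the first LCP minimum between consecutive ``c``-runs);
* a phi structure (successor over run-boundary-derived SA samples) that
  enumerates occurrence positions from a single toehold;
* the text itself, kept verbatim behind the random-access contract.

Alphabet order is byte order: terminator(0) < separator(1) < '#' < 'A' < 'C'
< 'G' < 'N' < 'T'.  BWT content depends on this ordering.
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .pangenome import PangenomeText, TERMINATOR


# ---------------------------------------------------------------------------
# suffix array / LCP construction
# ---------------------------------------------------------------------------

def suffix_array(text: bytes) -> np.ndarray:
    """Full suffix array by prefix doubling (O(n log^2 n), vectorized)."""
    n = len(text)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    codes = np.frombuffer(text, dtype=np.uint8).astype(np.int64)
    rank = codes
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        prev = order[:-1]
        cur = order[1:]
        changed = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def lcp_array(text: bytes, sa: np.ndarray) -> np.ndarray:
    """LCP[i] = lcp(suffix at SA[i-1], suffix at SA[i]); LCP[0] = 0 (Kasai)."""
    n = len(text)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    isa = np.empty(n, dtype=np.int64)
    isa[sa] = np.arange(n)
    sa_l = sa.tolist()
    isa_l = isa.tolist()
    out = [0] * n
    h = 0
    for i in range(n):
        r = isa_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            out[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return np.asarray(out, dtype=np.int64)


def bwt_from_sa(text: bytes, sa: np.ndarray) -> np.ndarray:
    codes = np.frombuffer(text, dtype=np.uint8)
    return codes[(sa - 1) % len(text)]


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------

@dataclass
class BWTRange:
    """Half-open BWT row interval with the SA value of its last row."""

    lo: int
    hi: int
    toehold: int = -1   # SA[hi-1]; -1 when empty

    @property
    def width(self) -> int:
        return max(0, self.hi - self.lo)

    @property
    def empty(self) -> bool:
        return self.hi <= self.lo


@dataclass
class RLBWT:
    chars: List[int]        # run characters (byte values)
    lengths: List[int]      # run lengths
    C: List[int]            # C[c] = number of text characters < c (len 257)

    @property
    def r(self) -> int:
        return len(self.chars)

    def expand(self) -> bytes:
        return bytes(b"".join(bytes([c]) * l
                              for c, l in zip(self.chars, self.lengths)))


class CharacterExhausted(Exception):
    """Raised when a matching-statistics step finds no run of the character."""


class RIndex:
    """r-index over a PangenomeText (or raw bytes ending in the terminator)."""

    FORMAT_VERSION = 1

    def __init__(self, text: PangenomeText, rlbwt: RLBWT,
                 run_starts: List[int], per_char: Dict[int, dict],
                 phi_keys: List[int], phi_vals: List[int],
                 last_row_sa: int):
        self.text = text
        self.rlbwt = rlbwt
        self.run_starts = run_starts          # row of each run's first entry
        self.per_char = per_char
        self.phi_keys = phi_keys
        self.phi_vals = phi_vals
        self.n = len(text.text)
        self.last_row_sa = last_row_sa        # SA[n-1], full-range toehold
        self.C = rlbwt.C

    # -- basic accessors ----------------------------------------------------

    @property
    def r(self) -> int:
        return self.rlbwt.r

    def access(self, pos: int) -> int:
        """Character (byte value) at a global text position."""
        if not 0 <= pos < self.n:
            raise IndexError(pos)
        return self.text.text[pos]

    def char_at_row(self, row: int) -> int:
        i = bisect_right(self.run_starts, row) - 1
        return self.rlbwt.chars[i]

    def rank(self, c: int, row: int) -> int:
        """Occurrences of c in BWT[0:row)."""
        st = self.per_char.get(c)
        if st is None:
            return 0
        starts, lens, cum = st["starts"], st["lens"], st["cum"]
        i = bisect_right(starts, row - 1) - 1
        if i < 0:
            return 0
        return cum[i] + min(row - starts[i], lens[i])

    def lf(self, row: int) -> int:
        c = self.char_at_row(row)
        return self.C[c] + self.rank(c, row)

    # -- backward search ----------------------------------------------------

    def full_range(self) -> BWTRange:
        return BWTRange(0, self.n, self.last_row_sa)

    def backward_step(self, rng: BWTRange, c: int) -> BWTRange:
        """Extend the matched pattern by prepending character ``c``."""
        st = self.per_char.get(c)
        if st is None or rng.empty:
            return BWTRange(0, 0, -1)
        lo = self.C[c] + self.rank(c, rng.lo)
        hi = self.C[c] + self.rank(c, rng.hi)
        if lo >= hi:
            return BWTRange(lo, lo, -1)
        if self.char_at_row(rng.hi - 1) == c:
            toe = (rng.toehold - 1) % self.n
        else:
            starts = st["starts"]
            j = bisect_right(starts, rng.hi - 1) - 1
            toe = (st["sa_last"][j] - 1) % self.n
        return BWTRange(lo, hi, toe)

    def phi(self, p: int) -> int:
        """SA value of the row preceding the row whose SA value is ``p``."""
        j = bisect_left(self.phi_keys, p)
        return self.phi_vals[j] - (self.phi_keys[j] - p)

    def locate(self, rng: BWTRange) -> List[int]:
        """All occurrence positions in the range, from the toehold via phi."""
        if rng.empty:
            return []
        out = [rng.toehold]
        p = rng.toehold
        for _ in range(rng.width - 1):
            p = self.phi(p)
            out.append(p)
        return out

    def count(self, pattern: bytes) -> int:
        rng = self.find(pattern)
        return rng.width

    def find(self, pattern: bytes) -> BWTRange:
        rng = self.full_range()
        for c in reversed(pattern):
            rng = self.backward_step(rng, c)
            if rng.empty:
                return rng
        return rng

    # -- thresholds / matching-statistics support ---------------------------

    def threshold_jump(self, c: int, row: int) -> Tuple[int, int]:
        """Row and SA sample to jump to when the range for ``c`` empties.

        Returns the last row of the preceding ``c``-run when ``row`` is below
        the threshold between the two neighboring ``c``-runs, else the first
        row of the following run (ties jump down).  Raises
        :class:`CharacterExhausted` when ``c`` has no run at all.
        """
        st = self.per_char.get(c)
        if st is None:
            raise CharacterExhausted(c)
        starts, lens = st["starts"], st["lens"]
        i = bisect_right(starts, row) - 1
        if i >= 0 and row < starts[i] + lens[i]:
            # row is inside a c-run; no jump needed
            return row, self._sa_in_run(st, i, row)
        has_prev = i >= 0
        has_next = i + 1 < len(starts)
        if not has_prev and not has_next:
            raise CharacterExhausted(c)
        if not has_next:
            return starts[i] + lens[i] - 1, st["sa_last"][i]
        if not has_prev:
            return starts[i + 1], st["sa_first"][i + 1]
        t = st["thr"][i]
        if row < t:
            return starts[i] + lens[i] - 1, st["sa_last"][i]
        return starts[i + 1], st["sa_first"][i + 1]

    @staticmethod
    def _sa_in_run(st: dict, i: int, row: int) -> int:
        # only run-boundary samples are stored; interior rows are not needed
        if row == st["starts"][i]:
            return st["sa_first"][i]
        if row == st["starts"][i] + st["lens"][i] - 1:
            return st["sa_last"][i]
        raise AssertionError("SA sample requested for run-interior row")

    def ms_step(self, row: int, sa: int, c: int) -> Tuple[int, int, bool]:
        """One backward matching-statistics step.

        Given the current row (whose suffix realizes the longest match with
        the already-processed read suffix) and its SA value, prepend ``c``.
        Returns ``(new_row, new_sa, jumped)``; ``jumped`` means the position
        changed via a threshold jump and the match length must be recomputed.
        Raises :class:`CharacterExhausted` when ``c`` does not occur.
        """
        st = self.per_char.get(c)
        if st is None:
            raise CharacterExhausted(c)
        starts, lens = st["starts"], st["lens"]
        i = bisect_right(starts, row) - 1
        if i >= 0 and row < starts[i] + lens[i]:
            # BWT[row] == c: plain LF step
            new_row = self.C[c] + st["cum"][i] + (row - starts[i])
            return new_row, (sa - 1) % self.n, False
        has_prev = i >= 0
        has_next = i + 1 < len(starts)
        if not has_prev and not has_next:
            raise CharacterExhausted(c)
        if has_prev and (not has_next or row < st["thr"][i]):
            jrow = starts[i] + lens[i] - 1
            jsa = st["sa_last"][i]
            new_row = self.C[c] + st["cum"][i] + lens[i] - 1
        else:
            jrow = starts[i + 1]
            jsa = st["sa_first"][i + 1]
            new_row = self.C[c] + st["cum"][i + 1]
        _ = jrow
        return new_row, (jsa - 1) % self.n, True

    # -- serialization ------------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "format_version": self.FORMAT_VERSION,
            "n": self.n,
            "last_row_sa": self.last_row_sa,
            "doc_bounds": self.text.doc_bounds,
            "doc_names": self.text.doc_names,
            "genome_of_doc": self.text.genome_of_doc,
        }
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump(meta, fh)
        arrays = {
            "text": np.frombuffer(self.text.text, dtype=np.uint8),
            "run_chars": np.asarray(self.rlbwt.chars, dtype=np.uint8),
            "run_lens": np.asarray(self.rlbwt.lengths, dtype=np.int64),
            "C": np.asarray(self.rlbwt.C, dtype=np.int64),
            "run_starts": np.asarray(self.run_starts, dtype=np.int64),
            "phi_keys": np.asarray(self.phi_keys, dtype=np.int64),
            "phi_vals": np.asarray(self.phi_vals, dtype=np.int64),
        }
        for c, st in self.per_char.items():
            for k in ("starts", "lens", "cum", "sa_first", "sa_last", "thr"):
                arrays[f"c{c}_{k}"] = np.asarray(st[k], dtype=np.int64)
        np.savez(os.path.join(directory, "rindex.npz"), **arrays)

    @classmethod
    def load(cls, directory: str) -> "RIndex":
        with open(os.path.join(directory, "meta.json")) as fh:
            meta = json.load(fh)
        if meta["format_version"] != cls.FORMAT_VERSION:
            raise ValueError("unsupported index format version")
        data = np.load(os.path.join(directory, "rindex.npz"))
        text = PangenomeText(
            text=data["text"].tobytes(),
            doc_bounds=list(meta["doc_bounds"]),
            doc_names=list(meta["doc_names"]),
            genome_of_doc=list(meta["genome_of_doc"]),
        )
        rlbwt = RLBWT(chars=data["run_chars"].tolist(),
                      lengths=data["run_lens"].tolist(),
                      C=data["C"].tolist())
        per_char: Dict[int, dict] = {}
        for key in data.files:
            if key.startswith("c") and "_" in key:
                c_str, field_name = key[1:].split("_", 1)
                if not c_str.isdigit():
                    continue
                per_char.setdefault(int(c_str), {})[field_name] = \
                    data[key].tolist()
        return cls(text=text, rlbwt=rlbwt,
                   run_starts=data["run_starts"].tolist(),
                   per_char=per_char,
                   phi_keys=data["phi_keys"].tolist(),
                   phi_vals=data["phi_vals"].tolist(),
                   last_row_sa=int(meta["last_row_sa"]))


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def build_rindex(text: PangenomeText) -> RIndex:
    """Build the full index (runs, samples, thresholds, phi) from the text."""
    raw = text.text
    n = len(raw)
    if n == 0:
        raise ValueError("empty text")
    term = raw[-1]
    if raw.count(bytes([term])) != 1:
        raise ValueError("terminator must be unique")
    if n > 1 and term >= min(raw[:-1]):
        raise ValueError("terminator must be smaller than all other symbols")

    sa = suffix_array(raw)
    lcp = lcp_array(raw, sa)
    bwt = bwt_from_sa(raw, sa)

    # runs
    boundaries = np.flatnonzero(np.diff(bwt.astype(np.int16)) != 0) + 1
    run_starts = np.concatenate(([0], boundaries))
    run_ends = np.concatenate((boundaries, [n])) - 1     # inclusive
    run_chars = bwt[run_starts]
    run_lens = run_ends - run_starts + 1

    counts = np.bincount(np.frombuffer(raw, dtype=np.uint8), minlength=256)
    C = np.concatenate(([0], np.cumsum(counts))).tolist()  # len 257

    sa_list = sa  # numpy fancy indexing below
    per_char: Dict[int, dict] = {}
    for c in sorted(set(run_chars.tolist())):
        mask = run_chars == c
        starts_c = run_starts[mask]
        lens_c = run_lens[mask]
        ends_c = run_ends[mask]
        cum_c = np.concatenate(([0], np.cumsum(lens_c)))[:-1]
        sa_first = sa_list[starts_c]
        sa_last = sa_list[ends_c]
        # thresholds: first LCP-minimum row in (end of run j, start of run j+1]
        thr = []
        for j in range(len(starts_c) - 1):
            a = int(ends_c[j]) + 1
            b = int(starts_c[j + 1])          # inclusive
            window = lcp[a:b + 1]
            thr.append(a + int(np.argmin(window)))
        per_char[int(c)] = {
            "starts": starts_c.tolist(),
            "lens": lens_c.tolist(),
            "cum": cum_c.tolist(),
            "sa_first": sa_first.tolist(),
            "sa_last": sa_last.tolist(),
            "thr": thr,
        }

    # phi anchors: {SA[i]-1 : i run start, SA[i] >= 1} with values from the
    # full SA, plus the circular anchor n-1 -> SA[n-1]
    isa = np.empty(n, dtype=np.int64)
    isa[sa] = np.arange(n)
    keys: List[int] = []
    vals: List[int] = []
    for row in run_starts.tolist():
        s = int(sa_list[row])
        if s >= 1:
            key = s - 1
            prev_row = int(isa[key]) - 1
            keys.append(key)
            vals.append(int(sa_list[prev_row]) if prev_row >= 0
                        else int(sa_list[n - 1]))
    keys.append(n - 1)
    vals.append(int(sa_list[n - 1]))
    order = np.argsort(np.asarray(keys))
    phi_keys = [keys[i] for i in order]
    phi_vals = [vals[i] for i in order]
    # drop duplicate keys (n-1 may coincide with a derived anchor)
    dedup_k: List[int] = []
    dedup_v: List[int] = []
    for k, v in zip(phi_keys, phi_vals):
        if dedup_k and dedup_k[-1] == k:
            continue
        dedup_k.append(k)
        dedup_v.append(v)

    rlbwt = RLBWT(chars=run_chars.tolist(), lengths=run_lens.tolist(), C=C)
    return RIndex(text=text, rlbwt=rlbwt, run_starts=run_starts.tolist(),
                  per_char=per_char, phi_keys=dedup_k, phi_vals=dedup_v,
                  last_row_sa=int(sa_list[n - 1]))


def text_from_bytes(raw: bytes, name: str = "doc0",
                    add_terminator: bool = True) -> PangenomeText:
    """Wrap raw bytes as a single document (terminator appended by default).

    With ``add_terminator=False`` the final byte of ``raw`` is taken as the
    terminator (it must be unique and strictly smallest, e.g. ``$`` below
    lowercase test alphabets).
    """
    if add_terminator and not raw.endswith(bytes([TERMINATOR])):
        raw = raw + bytes([TERMINATOR])
    return PangenomeText(text=raw, doc_bounds=[0], doc_names=[name],
                         genome_of_doc=[name])
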