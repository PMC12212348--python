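"""Shared alignment record and CIGAR helpers.

CIGAR is represented as a list of ``(op, length)`` tuples with ``op`` one of
``M = X I D S``.  ``M``/``=``/``X`` consume both query and target, ``I``/``S``
consume query only, ``D`` consumes target only.  Coordinates are 0-based
half-open internally; SAM emission converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

Cigar = List[Tuple[str, int]]

_QUERY_OPS = {"M", "=", "X", "I", "S"}
_TARGET_OPS = {"M", "=", "X", "D"}


@dataclass
class Alignment:
    """A base-level alignment of an oriented read against one haplotype.

    ``hap_start`` is the 0-based start on the haplotype (or on the reference
    after lifting).  ``strand`` is ``"+"`` or ``"-"``; the query is always the
    oriented read (reverse-complemented for ``"-"``).
    """

    doc: str
    strand: str
    hap_start: int
    cigar: Cigar
    score: float
    nm: int = 0
    read_id: str = ""
    contig: Optional[str] = None       # set after liftover
    ref_start: Optional[int] = None    # set after liftover
    unliftable: bool = False
    tags: dict = field(default_factory=dict)

    def copy(self, **kw) -> "Alignment":
        kw.setdefault("cigar", list(self.cigar))
        kw.setdefault("tags", dict(self.tags))
        return replace(self, **kw)

    @property
    def query_len(self) -> int:
        return cigar_query_len(self.cigar)

    @property
    def target_len(self) -> int:
        return cigar_target_len(self.cigar)

    @property
    def position(self) -> int:
        """Leftmost coordinate in the space the alignment currently lives in."""
        return self.ref_start if self.ref_start is not None else self.hap_start

    @property
    def end(self) -> int:
        return self.position + self.target_len


def cigar_query_len(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in _QUERY_OPS)


def cigar_target_len(cigar: Cigar) -> int:
    return sum(n for op, n in cigar if op in _TARGET_OPS)


def merge_cigar(cigar: Cigar) -> Cigar:
    """Drop zero-length ops and merge adjacent runs of the same op."""
    out: Cigar = []
    for op, n in cigar:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def collapse_matches(cigar: Cigar) -> Cigar:
    """Replace ``=``/``X`` by plain ``M`` (the default SAM emission mode)."""
    return merge_cigar([("M" if op in "=X" else op, n) for op, n in cigar])


def cigar_to_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) if cigar else "*"


def cigar_from_string(s: str) -> Cigar:
    if s == "*":
        return []
    out: Cigar = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def leading_clip(cigar: Cigar) -> int:
    return cigar[0][1] if cigar and cigar[0][0] == "S" else 0


def normalize_cigar(cigar: Cigar) -> Cigar:
    """Merge ops and convert boundary insertions into soft clips."""
    cig = merge_cigar(cigar)
    # leading: S then I blocks fold into one S
    while len(cig) >= 2 and cig[0][0] == "S" and cig[1][0] == "I":
        cig = [("S", cig[0][1] + cig[1][1])] + cig[2:]
    if cig and cig[0][0] == "I":
        cig[0] = ("S", cig[0][1])
        cig = merge_cigar(cig)
    while len(cig) >= 2 and cig[-1][0] == "S" and cig[-2][0] == "I":
        cig = cig[:-2] + [("S", cig[-1][1] + cig[-2][1])]
    if cig and cig[-1][0] == "I":
        cig[-1] = ("S", cig[-1][1])
        cig = merge_cigar(cig)
    # boundary deletions consume target but align nothing; drop them
    if cig and cig[0][0] == "D":
        cig = cig[1:]
    if cig and cig[-1][0] == "D":
        cig = cig[:-1]
    return cig
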