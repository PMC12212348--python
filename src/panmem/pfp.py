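"""Prefix-free parsing: trigger strings, dictionary, and parse.

The input ``S`` is delimited with ``w`` copies of a delimiter on both sides
(cyclic representation ``S' = d^w S d^w``).  Trigger strings are the
``w``-length windows whose rolling hash is 0 mod ``p`` (plus the all-delimiter
window); cutting ``S'`` at every trigger occurrence yields phrases that begin
and end with a trigger and contain no other, forming a lexicographically
sorted dictionary ``D`` and a parse ``P`` of dictionary ranks.  The wrap
phrase (delimiter-only, e.g. ``$$$$$$``) closes the cycle.

An ``explicit_triggers`` override makes parsing hash-independent for tests
and for the worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Set

# Karp-Rabin polynomial rolling hash constants (documented, fixed)
_KR_BASE = 256
_KR_MOD = (1 << 61) - 1


@dataclass
class PFPConfig:
    w: int = 10
    p: int = 100
    delimiter: str = "$"
    explicit_triggers: Optional[Set[str]] = None

    def __post_init__(self):
        if self.w < 2:
            raise ValueError("window length w must be >= 2")
        if self.p < 1:
            raise ValueError("modulus p must be >= 1")
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")


@dataclass
class PFPResult:
    dictionary: List[str]         # lexicographically sorted unique phrases
    parse: List[int]              # 1-based ranks into `dictionary`
    triggers: Set[str]
    cyclic_text: str              # S' = d^w S d^w
    w_overlap: int = 0            # phrase overlap length (= w)


def karp_rabin(window: str) -> int:
    h = 0
    for ch in window:
        h = (h * _KR_BASE + ord(ch)) % _KR_MOD
    return h


def find_triggers(s_prime: str, cfg: PFPConfig) -> List[int]:
    """Sorted start offsets of every trigger-string occurrence in S'.

    With ``explicit_triggers`` set, occurrences of exactly those strings are
    reported; otherwise windows hashing to 0 mod p, plus the all-delimiter
    window, count as triggers.
    """
    w = cfg.w
    n = len(s_prime)
    if n < w:
        raise ValueError("window length larger than delimited text")
    positions: List[int] = []
    all_delim = cfg.delimiter * w
    if cfg.explicit_triggers is not None:
        trig = cfg.explicit_triggers
        for i in range(n - w + 1):
            if s_prime[i:i + w] in trig:
                positions.append(i)
        return positions
    # rolling hash scan
    h = karp_rabin(s_prime[:w])
    top = pow(_KR_BASE, w - 1, _KR_MOD)
    for i in range(n - w + 1):
        if i > 0:
            h = ((h - ord(s_prime[i - 1]) * top) * _KR_BASE
                 + ord(s_prime[i + w - 1])) % _KR_MOD
        if h % cfg.p == 0 or s_prime[i:i + w] == all_delim:
            positions.append(i)
    return positions


def _sort_key(phrase: str, cfg: PFPConfig) -> str:
    # delimiter sorts below every other symbol regardless of its code point
    return phrase.replace(cfg.delimiter, "\x00")


def parse(s: str, cfg: Optional[PFPConfig] = None) -> PFPResult:
    """Prefix-free parse of ``s`` into (dictionary, parse).

    Raises ``ValueError`` on empty input or when ``w`` exceeds the delimited
    text length.
    """
    if cfg is None:
        cfg = PFPConfig()
    if not s:
        raise ValueError("empty input")
    if cfg.w > len(s):
        raise ValueError("window length exceeds the input length")
    if cfg.delimiter in s:
        raise ValueError("delimiter occurs inside the input")
    w = cfg.w
    s_prime = cfg.delimiter * w + s + cfg.delimiter * w
    trig_pos = find_triggers(s_prime, cfg)
    if not trig_pos or trig_pos[0] != 0 or trig_pos[-1] != len(s_prime) - w:
        raise ValueError("boundary delimiter windows must be triggers")

    phrases: List[str] = []
    for a, b in zip(trig_pos, trig_pos[1:]):
        phrases.append(s_prime[a:b + w])
    # wrap phrase closes the cycle: last trigger .. end + start .. first trigger+w
    phrases.append(s_prime[trig_pos[-1]:] + s_prime[:w])

    dictionary = sorted(set(phrases), key=lambda ph: _sort_key(ph, cfg))
    rank = {ph: i + 1 for i, ph in enumerate(dictionary)}
    p_seq = [rank[ph] for ph in phrases]
    triggers = (set(cfg.explicit_triggers) if cfg.explicit_triggers is not None
                else {s_prime[i:i + w] for i in trig_pos})
    res = PFPResult(dictionary=dictionary, parse=p_seq, triggers=triggers,
                    cyclic_text=s_prime)
    res.w_overlap = w
    return res


def reconstruct(result: PFPResult) -> str:
    """Overlap-concatenate the parse phrases back into S'.

    Each phrase ends with the trigger that starts the next phrase, so all but
    the final ``w`` characters of each phrase are emitted; the wrap phrase
    contributes the closing delimiter block.
    """
    w = result.w_overlap
    return "".join(result.dictionary[r - 1][:-w] for r in result.parse)


def check_prefix_free(result: PFPResult) -> bool:
    """Definitional scan: no phrase contains an internal trigger occurrence.

    Internal means strictly between the phrase's leading and trailing
    triggers (occurrences overlapping those are part of them).
    """
    w = result.w_overlap
    for ph in result.dictionary:
        for i in range(w, len(ph) - 2 * w + 1):
            if ph[i:i + w] in result.triggers:
                return False
    return True


def dump(result: PFPResult, dict_path: str, parse_path: str) -> None:
    """Write dictionary (one phrase per line) and parse (space-separated)."""
    with open(dict_path, "w") as fh:
        for ph in result.dictionary:
            fh.write(ph + "\n")
    with open(parse_path, "w") as fh:
        fh.write(" ".join(map(str, result.parse)) + "\n")
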