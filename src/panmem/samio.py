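"""SAM v1.6 text emission and FASTQ input.

Only writing is implemented here (reading is delegated to pysam in tests and
downstream tooling).  Flag arithmetic follows the SAM spec; TLEN carries the
outer distance with opposite signs on the two mates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0                 # 1-based; 0 for unmapped
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flag & FLAG_UNMAPPED:
            assert self.pos == 0 and self.cigar == "*", \
                "unmapped records must have pos 0 and no CIGAR"

    def to_line(self) -> str:
        tag_fields = []
        for key, value in self.tags.items():
            if isinstance(value, int):
                tag_fields.append(f"{key}:i:{value}")
            elif isinstance(value, float):
                tag_fields.append(f"{key}:f:{value:g}")
            else:
                tag_fields.append(f"{key}:Z:{value}")
        cols = [self.qname, str(self.flag), self.rname, str(self.pos),
                str(self.mapq), self.cigar, self.rnext, str(self.pnext),
                str(self.tlen), self.seq, self.qual] + tag_fields
        return "\t".join(cols)


def sam_header(contigs: Sequence[Tuple[str, int]],
               program_args: Optional[str] = None) -> List[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    pg = "@PG\tID:panmem\tPN:panmem"
    if program_args:
        pg += f"\tCL:{program_args}"
    lines.append(pg)
    return lines


def write_sam(path: str, records: Iterable[SamRecord],
              contigs: Sequence[Tuple[str, int]],
              program_args: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        for line in sam_header(contigs, program_args):
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_fastq(path: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a plain or gzipped FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            name = header[1:].rstrip("\n").split()[0]
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield name, seq.upper(), qual
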