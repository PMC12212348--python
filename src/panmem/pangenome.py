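"""Haplotype materialization, the concatenated index text, and liftover.

A pangenome is built from a reference FASTA plus a phased VCF: each (sample,
phase) pair yields one haplotype per contig, together with a :class:`LiftMap`
that translates haplotype coordinates back to the linear reference.  The
haplotype sequences are concatenated into a single :class:`PangenomeText`
(separator byte between documents, terminator byte at the end) which is what
the r-index is built over.

Coordinates are 0-based half-open internally; VCF positions are 1-based.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment import Alignment, normalize_cigar

log = logging.getLogger(__name__)

#: Reserved non-IUPAC bytes.  Byte order gives the documented alphabet order:
#: terminator < separator < '#' < 'A' < 'C' < 'G' < 'N' < 'T'.
TERMINATOR = 0
SEPARATOR = 1

VALID_BASES = frozenset(b"ACGTN")


class PangenomeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Ordered contigs of an uppercase DNA reference."""

    contigs: List[Tuple[str, str]]

    def __post_init__(self):
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise PangenomeError("duplicate contig names")
        for name, seq in self.contigs:
            if not seq:
                raise PangenomeError(f"empty contig {name!r}")
        self._by_name = {n: s for n, s in self.contigs}

    def __getitem__(self, name: str) -> str:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.contigs]


@dataclass
class VariantRecord:
    """One VCF row restricted to what haplotype materialization needs."""

    contig: str
    pos: int                      # 1-based, per VCF
    ref: str
    alts: List[str]
    genotypes: List[Optional[Tuple[int, int]]]  # per sample; None = missing
    phased: List[bool] = field(default_factory=list)

    def allele_index(self, sample: int, phase: int) -> int:
        gt = self.genotypes[sample]
        if gt is None:
            return 0
        return gt[phase - 1]


@dataclass
class Haplotype:
    id: str                       # "<sample>#<phase>"
    sequence: str
    source_contig: str

    @property
    def sample(self) -> str:
        return self.id.rsplit("#", 1)[0]


@dataclass
class LiftSegment:
    """One piece of a haplotype→reference map.

    kind ``M``: ``length`` bases of the haplotype starting at ``hap_start``
    map one-to-one onto the reference starting at ``ref_start``.
    kind ``I`` (insertion in the haplotype): ``length`` haplotype bases with
    no reference counterpart, anchored just before reference ``ref_start``.
    kind ``D`` (deletion in the haplotype): ``length`` reference bases absent
    from the haplotype, anchored at haplotype position ``hap_start``.
    """

    hap_start: int
    ref_start: int
    length: int
    kind: str
    seq: str = ""                 # inserted sequence, for reconstruction


class LiftMap:
    """Monotone haplotype→reference coordinate map for one haplotype/contig."""

    def __init__(self, contig: str, segments: List[LiftSegment],
                 substitutions: Optional[List[Tuple[int, str]]] = None):
        self.contig = contig
        self.segments = segments
        self.substitutions = substitutions or []
        # segments with haplotype extent, for coordinate queries
        self._hap_segs = sorted(
            (s for s in segments if s.kind in "MI"), key=lambda s: s.hap_start)
        self._hap_keys = [s.hap_start for s in self._hap_segs]
        self._m_segs = sorted(
            (s for s in segments if s.kind == "M"), key=lambda s: s.ref_start)
        self._ref_keys = [s.ref_start for s in self._m_segs]

    @classmethod
    def identity(cls, contig: str, length: int) -> "LiftMap":
        return cls(contig, [LiftSegment(0, 0, length, "M")])

    @property
    def hap_length(self) -> int:
        return sum(s.length for s in self._hap_segs)

    @property
    def ref_length(self) -> int:
        return sum(s.length for s in self.segments if s.kind in "MD")

    def _hap_segment_at(self, pos: int) -> LiftSegment:
        i = bisect.bisect_right(self._hap_keys, pos) - 1
        if i < 0 or pos >= self._hap_segs[i].hap_start + self._hap_segs[i].length:
            raise IndexError(f"haplotype position {pos} outside map")
        return self._hap_segs[i]

    def hap_to_ref(self, pos: int) -> Optional[int]:
        """Reference coordinate of haplotype position, None inside insertions."""
        seg = self._hap_segment_at(pos)
        if seg.kind == "I":
            return None
        return seg.ref_start + (pos - seg.hap_start)

    def ref_to_hap(self, pos: int) -> Optional[int]:
        """Inverse map; None for reference bases deleted from the haplotype."""
        i = bisect.bisect_right(self._ref_keys, pos) - 1
        if i >= 0:
            seg = self._m_segs[i]
            if pos < seg.ref_start + seg.length:
                return seg.hap_start + (pos - seg.ref_start)
        return None

    def apply_to(self, ref_seq: str) -> str:
        """Reconstruct the haplotype sequence from the reference."""
        out: List[str] = []
        for seg in sorted(self.segments, key=lambda s: (s.hap_start, s.ref_start)):
            if seg.kind == "M":
                out.append(ref_seq[seg.ref_start:seg.ref_start + seg.length])
            elif seg.kind == "I":
                out.append(seg.seq)
        hap = list("".join(out))
        for pos, base in self.substitutions:
            hap[pos] = base
        return "".join(hap)


@dataclass
class PangenomeText:
    """Concatenated haplotype sequences with document boundaries.

    ``text`` is ``doc0 + SEP + doc1 + SEP + ... + docK + TERM`` as bytes.
    """

    text: bytes
    doc_bounds: List[int]
    doc_names: List[str]
    genome_of_doc: List[str]

    def __len__(self) -> int:
        return len(self.text)

    @property
    def n_docs(self) -> int:
        return len(self.doc_names)

    def doc_length(self, doc: int) -> int:
        end = (self.doc_bounds[doc + 1] - 1 if doc + 1 < self.n_docs
               else len(self.text) - 1)
        return end - self.doc_bounds[doc]

    def doc_seq(self, doc: int) -> bytes:
        start = self.doc_bounds[doc]
        return self.text[start:start + self.doc_length(doc)]

    def global_to_local(self, pos: int) -> Tuple[int, int]:
        """Map a global offset to (doc index, local offset).

        Raises ``ValueError`` for separator/terminator offsets, which are not
        sequence positions.
        """
        if not 0 <= pos < len(self.text):
            raise IndexError(pos)
        doc = bisect.bisect_right(self.doc_bounds, pos) - 1
        local = pos - self.doc_bounds[doc]
        if local >= self.doc_length(doc):
            raise ValueError(f"global offset {pos} is not a sequence position")
        return doc, local

    def local_to_global(self, doc: int, local: int) -> int:
        if not 0 <= local < self.doc_length(doc):
            raise IndexError((doc, local))
        return self.doc_bounds[doc] + local


# ---------------------------------------------------------------------------
# haplotype materialization
# ---------------------------------------------------------------------------

def _decompose(pos0: int, ref_allele: str, alt: str):
    """Break a VCF allele pair into primitive edits (subs / ins / del).

    Returns (primitives, ref_span_end) with primitives as tuples
    ``("sub", ref_pos, base)``, ``("ins", ref_pos, seq)``,
    ``("del", ref_pos, length)`` sorted by reference coordinate.
    """
    cp = 0
    while cp < min(len(ref_allele), len(alt)) and ref_allele[cp] == alt[cp]:
        cp += 1
    cs = 0
    while (cs < min(len(ref_allele), len(alt)) - cp
           and ref_allele[len(ref_allele) - 1 - cs] == alt[len(alt) - 1 - cs]):
        cs += 1
    mid_ref = ref_allele[cp:len(ref_allele) - cs]
    mid_alt = alt[cp:len(alt) - cs]
    base = pos0 + cp
    prims = []
    if len(mid_ref) == len(mid_alt):
        for k, (a, b) in enumerate(zip(mid_ref, mid_alt)):
            if a != b:
                prims.append(("sub", base + k, b))
    elif not mid_ref:
        prims.append(("ins", base, mid_alt))
    elif not mid_alt:
        prims.append(("del", base, len(mid_ref)))
    else:
        prims.append(("del", base, len(mid_ref)))
        prims.append(("ins", base + len(mid_ref), mid_alt))
    return prims, pos0 + len(ref_allele)


def apply_variants(ref: ReferenceGenome, variants: Sequence[VariantRecord],
                   sample: int, phase: int, contig: Optional[str] = None,
                   sample_name: Optional[str] = None,
                   ) -> Tuple[Haplotype, LiftMap]:
    """Materialize one haplotype (sample, phase) for one contig.

    Variants must be position-sorted.  Overlapping records on the same
    haplotype keep the first and skip later overlaps with a logged warning;
    reference-allele mismatches and symbolic alleles are rejected.
    """
    if contig is None:
        if len(ref.contigs) != 1:
            raise PangenomeError("contig must be given for multi-contig references")
        contig = ref.contigs[0][0]
    ref_seq = ref[contig]
    name = sample_name if sample_name is not None else f"S{sample}"
    hap_id = f"{name}#{phase}"

    parts: List[str] = []
    segs: List[LiftSegment] = []
    subs: List[Tuple[int, str]] = []
    hap_pos = 0
    ref_cursor = 0          # next unconsumed reference base
    m_start_hap = 0
    m_start_ref = 0

    def close_m():
        length = ref_cursor - m_start_ref
        if length > 0:
            segs.append(LiftSegment(m_start_hap, m_start_ref, length, "M"))

    last_pos = -1
    occupied_end = 0        # reference coords consumed by applied variants
    for var in variants:
        if var.contig != contig:
            continue
        if var.pos < last_pos:
            raise PangenomeError("variants not sorted by position")
        last_pos = var.pos
        idx = var.allele_index(sample, phase)
        if idx == 0:
            continue
        if var.phased and not var.phased[sample]:
            raise PangenomeError(
                f"unphased genotype for sample {name} at {contig}:{var.pos}")
        if idx > len(var.alts):
            raise PangenomeError(f"genotype index {idx} out of range at {var.pos}")
        alt = var.alts[idx - 1]
        if alt.startswith("<"):
            raise PangenomeError(f"symbolic allele {alt!r} at {contig}:{var.pos}")
        pos0 = var.pos - 1
        if ref_seq[pos0:pos0 + len(var.ref)] != var.ref:
            raise PangenomeError(
                f"ref allele mismatch at {contig}:{var.pos}: "
                f"VCF={var.ref!r} FASTA={ref_seq[pos0:pos0 + len(var.ref)]!r}")
        if pos0 < occupied_end:
            log.warning("skipping overlapping variant at %s:%d on %s",
                        contig, var.pos, hap_id)
            continue
        prims, span_end = _decompose(pos0, var.ref, alt)
        occupied_end = span_end
        for kind, r, payload in prims:
            if kind == "sub":
                parts.append(ref_seq[ref_cursor:r])
                hap_pos += r - ref_cursor
                parts.append(payload)
                subs.append((hap_pos, payload))
                hap_pos += 1
                ref_cursor = r + 1
            elif kind == "ins":
                parts.append(ref_seq[ref_cursor:r])
                hap_pos += r - ref_cursor
                ref_cursor = r
                close_m()
                segs.append(LiftSegment(hap_pos, r, len(payload), "I", payload))
                parts.append(payload)
                hap_pos += len(payload)
                m_start_hap, m_start_ref = hap_pos, ref_cursor
            else:  # del
                parts.append(ref_seq[ref_cursor:r])
                hap_pos += r - ref_cursor
                ref_cursor = r
                close_m()
                segs.append(LiftSegment(hap_pos, r, payload, "D"))
                ref_cursor = r + payload
                m_start_hap, m_start_ref = hap_pos, ref_cursor

    parts.append(ref_seq[ref_cursor:])
    hap_pos += len(ref_seq) - ref_cursor
    ref_cursor = len(ref_seq)
    close_m()

    hap = Haplotype(hap_id, "".join(parts), contig)
    lift = LiftMap(contig, segs, subs)
    assert lift.hap_length == len(hap.sequence)
    return hap, lift


def materialize_haplotypes(ref: ReferenceGenome,
                           variants: Sequence[VariantRecord],
                           sample_names: Sequence[str],
                           ) -> Tuple[List[Haplotype], List[LiftMap]]:
    """All haplotypes for all contigs × samples × phases, in stable order."""
    haps, lifts = [], []
    for contig, _ in ref.contigs:
        for si, sname in enumerate(sample_names):
            for phase in (1, 2):
                hap, lift = apply_variants(ref, variants, si, phase,
                                           contig=contig, sample_name=sname)
                if len(ref.contigs) > 1:
                    hap.id = f"{sname}#{phase}.{contig}"
                haps.append(hap)
                lifts.append(lift)
    return haps, lifts


# ---------------------------------------------------------------------------
# index text
# ---------------------------------------------------------------------------

def build_pangenome_text(haplotypes: Sequence[Haplotype],
                         include_reference: bool = False,
                         reference: Optional[ReferenceGenome] = None,
                         ) -> PangenomeText:
    """Concatenate haplotypes (optionally plus the reference contigs)."""
    docs: List[Tuple[str, str, str]] = [
        (h.id, h.sequence, h.sample) for h in haplotypes]
    if include_reference:
        if reference is None:
            raise PangenomeError("include_reference requires a reference")
        for cname, cseq in reference.contigs:
            docs.append((f"REF#{cname}", cseq, "REF"))
    if not docs:
        raise PangenomeError("no haplotypes to index")

    chunks: List[bytes] = []
    bounds: List[int] = []
    offset = 0
    for i, (_, seq, _) in enumerate(docs):
        b = seq.encode("ascii")
        if set(b) - set(b"ACGTN"):
            bad = sorted(set(b) - set(b"ACGTN"))
            raise PangenomeError(f"non-DNA bytes in haplotype {docs[i][0]}: {bad}")
        bounds.append(offset)
        chunks.append(b)
        offset += len(b)
        if i + 1 < len(docs):
            chunks.append(bytes([SEPARATOR]))
        else:
            chunks.append(bytes([TERMINATOR]))
        offset += 1
    return PangenomeText(
        text=b"".join(chunks),
        doc_bounds=bounds,
        doc_names=[d[0] for d in docs],
        genome_of_doc=[d[2] for d in docs],
    )


# ---------------------------------------------------------------------------
# liftover
# ---------------------------------------------------------------------------

def lift_alignment(aln: Alignment, lift: LiftMap) -> Alignment:
    """Rewrite an on-haplotype alignment into linear-reference coordinates.

    The CIGAR is intersected with the lift segments: haplotype insertions
    become read insertions relative to the reference, haplotype deletions
    introduce reference deletions.  The score is preserved.  Alignments with
    no reference anchor (fully inside an insertion) come back flagged
    ``unliftable`` and keep haplotype coordinates.
    """
    h = aln.hap_start
    out = []
    ref_start: Optional[int] = None
    # deletions anchored by haplotype position; each is emitted at most once
    dels: Dict[int, int] = {s.hap_start: s.length
                            for s in lift.segments if s.kind == "D"}
    emitted_dels: set = set()
    for op, n in aln.cigar:
        if op in ("S", "I"):
            out.append((op, n))
            continue
        remaining = n
        while remaining > 0:
            if h > aln.hap_start and h in dels and h not in emitted_dels:
                # crossing a haplotype-deletion anchor strictly inside the walk
                out.append(("D", dels[h]))
                emitted_dels.add(h)
            seg = lift._hap_segment_at(h)
            take = min(remaining, seg.hap_start + seg.length - h)
            if seg.kind == "M":
                if op != "D" and ref_start is None:
                    ref_start = seg.ref_start + (h - seg.hap_start)
                out.append((op, take))
            else:  # inside a haplotype insertion: no reference counterpart
                if op != "D":
                    out.append(("I", take))
                # alignment deletions of inserted bases vanish
            h += take
            remaining -= take
    if ref_start is None:
        res = aln.copy(unliftable=True)
        return res
    cig = normalize_cigar(out)
    return aln.copy(contig=lift.contig, ref_start=ref_start, cigar=cig)


def dedup_same_position(alns: Iterable[Alignment]) -> List[Alignment]:
    """Keep the higher-scoring alignment per (contig, position, strand)."""
    best: Dict[Tuple, Alignment] = {}
    order: List[Tuple] = []
    for a in alns:
        key = (a.contig if a.contig is not None else a.doc, a.position, a.strand)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif a.score > cur.score:
            best[key] = a
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def load_reference(path: str) -> ReferenceGenome:
    """Read a (possibly gzipped) FASTA into a ReferenceGenome."""
    import pysam

    contigs = []
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            contigs.append((rec.name, rec.sequence.upper()))
    return ReferenceGenome(contigs)


def load_vcf(path: str, ref: Optional[ReferenceGenome] = None,
             ) -> Tuple[List[VariantRecord], List[str]]:
    """Read a VCF v4.x with GT fields into VariantRecords + sample names."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: List[VariantRecord] = []
    for v in vcf:
        if ref is not None and v.CHROM not in ref:
            raise PangenomeError(f"VCF contig {v.CHROM!r} absent from reference")
        gts = []
        phased = []
        for g in v.genotypes:
            alleles = [a for a in g[:-1]]
            if len(alleles) == 1:       # haploid call
                alleles = [alleles[0], alleles[0]]
            if alleles[0] < 0 or alleles[1] < 0:
                gts.append(None)
            else:
                gts.append((alleles[0], alleles[1]))
            phased.append(bool(g[-1]))
        records.append(VariantRecord(
            contig=v.CHROM, pos=v.POS, ref=v.REF, alts=list(v.ALT),
            genotypes=gts, phased=phased))
    records.sort(key=lambda r: (r.contig, r.pos))
    return records, samples
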