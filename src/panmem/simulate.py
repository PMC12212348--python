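"""Synthetic pangenome + Illumina-like read simulation with ground truth.

The generator applies SNPs (Bernoulli per base) and short indels (geometric
lengths) to a random reference, records them as a phased VCF, and builds its
own lift maps by direct string editing — deliberately independent of the
pangenome-construction module so the two can be cross-checked.  Reads are FR
pairs with a normal insert-size distribution and substitution-only errors,
so every read's ground-truth position stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pangenome import (Haplotype, LiftMap, LiftSegment, ReferenceGenome,
                        VariantRecord)

_BASES = "ACGT"


@dataclass
class SimConfig:
    ref_length: int = 20000
    n_haplotypes: int = 4
    snp_rate: float = 0.001
    indel_rate: float = 0.0001
    max_indel_len: int = 10
    read_length: int = 100
    n_pairs: int = 500
    insert_mean: float = 300.0
    insert_sd: float = 25.0
    subst_error_rate: float = 0.002
    seed: int = 0
    contig: str = "chr1"
    # optional segmental duplications copied within the reference, to induce
    # genuine multi-mapping (MAPQ 0) reads
    dup_len: int = 0
    dup_count: int = 1

    def __post_init__(self):
        for rate in (self.snp_rate, self.indel_rate, self.subst_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.read_length <= 0 or self.ref_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class TruthRecord:
    read_id: str
    mate: int               # 1 or 2
    haplotype: str
    hap_pos: int            # 0-based leftmost position on the haplotype
    ref_pos: int            # 0-based leftmost position lifted to the reference
    strand: str
    contig: str = "chr1"


@dataclass
class SimResult:
    reference: ReferenceGenome
    variants: List[VariantRecord]
    sample_names: List[str]
    haplotypes: List[Haplotype]
    lift_maps: List[LiftMap]


def _random_reference(cfg: SimConfig, rng: np.random.Generator) -> str:
    seq = rng.integers(0, 4, size=cfg.ref_length)
    ref = "".join(_BASES[b] for b in seq)
    if cfg.dup_len > 0:
        ref_list = list(ref)
        for _ in range(cfg.dup_count):
            if cfg.dup_len * 2 >= cfg.ref_length:
                break
            src = int(rng.integers(0, cfg.ref_length - cfg.dup_len))
            dst = int(rng.integers(0, cfg.ref_length - cfg.dup_len))
            ref_list[dst:dst + cfg.dup_len] = ref_list[src:src + cfg.dup_len]
        ref = "".join(ref_list)
    return ref


def simulate_pangenome(cfg: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> SimResult:
    """Random reference + per-haplotype variants as a phased VCF + lift maps.

    Indel positions that would overlap an already-drawn variant on the same
    haplotype are resampled (dropped and redrawn elsewhere by the Bernoulli
    process); records at one site are shared across haplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ref_seq = _random_reference(cfg, rng)
    n_hap = cfg.n_haplotypes
    n_samples = (n_hap + 1) // 2
    sample_names = [f"S{i}" for i in range(n_samples)]

    # site -> (ref_allele, alt_allele, set of haplotype indices)
    sites: Dict[int, Tuple[str, str, set]] = {}
    occupied: List[List[Tuple[int, int]]] = [[] for _ in range(n_hap)]

    def overlaps(h: int, a: int, b: int) -> bool:
        return any(not (b <= s or e <= a) for s, e in occupied[h])

    L = cfg.ref_length
    for h in range(n_hap):
        n_snp = rng.binomial(L, cfg.snp_rate)
        for pos in sorted(int(p) for p in rng.integers(1, L - 1, size=n_snp)):
            if pos in sites:
                ra, aa, carriers = sites[pos]
                if len(ra) == 1 and len(aa) == 1 and not overlaps(h, pos, pos + 1):
                    carriers.add(h)
                    occupied[h].append((pos, pos + 1))
                continue
            if overlaps(h, pos, pos + 1):
                continue
            ra = ref_seq[pos]
            aa = _BASES[(_BASES.index(ra) + int(rng.integers(1, 4))) % 4]
            sites[pos] = (ra, aa, {h})
            occupied[h].append((pos, pos + 1))
        n_indel = rng.binomial(L, cfg.indel_rate)
        for pos in sorted(int(p) for p in rng.integers(1, L - cfg.max_indel_len - 2,
                                                       size=n_indel)):
            length = min(cfg.max_indel_len, 1 + int(rng.geometric(0.4)))
            is_del = bool(rng.integers(0, 2))
            span = (pos, pos + length + 1) if is_del else (pos, pos + 1)
            if pos in sites or overlaps(h, *span):
                continue
            if is_del:
                ra = ref_seq[pos:pos + length + 1]
                aa = ref_seq[pos]
            else:
                ra = ref_seq[pos]
                aa = ra + "".join(_BASES[b] for b in
                                  rng.integers(0, 4, size=length))
            sites[pos] = (ra, aa, {h})
            occupied[h].append(span)

    variants: List[VariantRecord] = []
    for pos in sorted(sites):
        ra, aa, carriers = sites[pos]
        gts = []
        for s in range(n_samples):
            h1 = 2 * s
            h2 = 2 * s + 1
            a1 = 1 if h1 in carriers else 0
            a2 = 1 if (h2 < n_hap and h2 in carriers) else 0
            gts.append((a1, a2))
        variants.append(VariantRecord(
            contig=cfg.contig, pos=pos + 1, ref=ra, alts=[aa],
            genotypes=gts, phased=[True] * n_samples))

    haplotypes, lifts = [], []
    for h in range(n_hap):
        hap, lift = _direct_apply(ref_seq, cfg.contig, sites, h)
        hap_id = f"{sample_names[h // 2]}#{h % 2 + 1}"
        haplotypes.append(Haplotype(hap_id, hap, cfg.contig))
        lifts.append(lift)

    reference = ReferenceGenome([(cfg.contig, ref_seq)])
    return SimResult(reference=reference, variants=variants,
                     sample_names=sample_names, haplotypes=haplotypes,
                     lift_maps=lifts)


def _direct_apply(ref_seq: str, contig: str, sites: Dict, h: int,
                  ) -> Tuple[str, LiftMap]:
    """Apply one haplotype's edits by direct string surgery (independent of
    the pangenome-construction module)."""
    parts: List[str] = []
    segs: List[LiftSegment] = []
    subs: List[Tuple[int, str]] = []
    hap_pos = 0
    cursor = 0
    m_hap = m_ref = 0

    def close_m(end_ref: int):
        if end_ref > m_ref:
            segs.append(LiftSegment(m_hap, m_ref, end_ref - m_ref, "M"))

    for pos in sorted(sites):
        ra, aa, carriers = sites[pos]
        if h not in carriers or pos < cursor:
            continue
        parts.append(ref_seq[cursor:pos])
        hap_pos += pos - cursor
        cursor = pos
        if len(ra) == len(aa) == 1:
            parts.append(aa)
            subs.append((hap_pos, aa))
            hap_pos += 1
            cursor += 1
        elif len(aa) > len(ra):            # insertion after shared base
            parts.append(aa)
            hap_pos += 1
            cursor += 1
            close_m(cursor)
            ins = aa[1:]
            segs.append(LiftSegment(hap_pos, cursor, len(ins), "I", ins))
            hap_pos += len(ins)
            m_hap, m_ref = hap_pos, cursor
        else:                              # deletion after shared base
            parts.append(aa)
            hap_pos += 1
            cursor += 1
            close_m(cursor)
            dlen = len(ra) - 1
            segs.append(LiftSegment(hap_pos, cursor, dlen, "D"))
            cursor += dlen
            m_hap, m_ref = hap_pos, cursor
    parts.append(ref_seq[cursor:])
    hap_pos += len(ref_seq) - cursor
    cursor = len(ref_seq)
    close_m(cursor)
    return "".join(parts), LiftMap(contig, segs, subs)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(haplotypes: Sequence[Haplotype],
                   lift_maps: Sequence[LiftMap], cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   ) -> Tuple[List[Tuple[str, str, str]],
                              List[Tuple[str, str, str]],
                              List[TruthRecord]]:
    """FR pairs with normal inserts and substitution errors.

    Returns (reads1, reads2, truth): each read is (id, seq, qual); truth has
    one record per mate with haplotype and reference-lifted positions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rl = cfg.read_length
    reads1, reads2, truth = [], [], []
    for i in range(cfg.n_pairs):
        h = int(rng.integers(0, len(haplotypes)))
        hap = haplotypes[h]
        lift = lift_maps[h]
        hl = len(hap.sequence)
        frag = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        frag = max(rl, min(frag, hl))
        start = int(rng.integers(0, hl - frag + 1))
        fwd_first = bool(rng.integers(0, 2))
        seq_l = hap.sequence[start:start + rl]
        seq_r = _rc(hap.sequence[start + frag - rl:start + frag])
        rid = f"sim{i}"

        def err(seq: str) -> str:
            out = list(seq)
            hits = np.flatnonzero(rng.random(len(seq)) < cfg.subst_error_rate)
            for k in hits:
                cur = out[k]
                out[k] = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4]
            return "".join(out)

        def lifted(p: int) -> int:
            r = lift.hap_to_ref(p)
            if r is None:   # inside an insertion: anchor to the next ref base
                q = p
                while r is None and q < len(hap.sequence) - 1:
                    q += 1
                    r = lift.hap_to_ref(q)
            return r if r is not None else 0

        t_l = TruthRecord(rid, 0, hap.id, start, lifted(start), "+",
                          contig=cfg.contig)
        t_r = TruthRecord(rid, 0, hap.id, start + frag - rl,
                          lifted(start + frag - rl), "-", contig=cfg.contig)
        if fwd_first:
            m1, m2 = (seq_l, t_l), (seq_r, t_r)
        else:
            m1, m2 = (seq_r, t_r), (seq_l, t_l)
        m1[1].mate, m2[1].mate = 1, 2
        reads1.append((rid, err(m1[0]), "I" * rl))
        reads2.append((rid, err(m2[0]), "I" * rl))
        truth.extend([m1[1], m2[1]])
    return reads1, reads2, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    zero_denominator: bool = False


def score_alignments(sam_path: str, truth: Sequence[TruthRecord],
                     tolerance: int = 10) -> AccuracyReport:
    """Precision/recall of a SAM against the simulator's ground truth.

    A read is TP when mapped within ``tolerance`` bp of its true
    reference position (after adding back leading soft-clips), FP when
    mapped farther, FN when unmapped.  Precision is TP/(TP+FP); recall is
    the fraction of all reads recovered, TP/(TP+FP+FN).  Zero denominators
    report 1.0 and are flagged.
    """
    import pysam

    by_key = {(t.read_id, t.mate): t for t in truth}
    tp = fp = fn = 0
    seen = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_read2 else 1
            key = (rec.query_name, mate)
            if key not in by_key:
                raise KeyError(f"read {key} not in truth set")
            if key in seen:
                continue
            seen.add(key)
            t = by_key[key]
            if rec.is_unmapped:
                fn += 1
                continue
            pos = rec.reference_start
            cig = rec.cigartuples or []
            if cig and cig[0][0] == 4:      # leading soft clip
                pos -= cig[0][1]
            if (rec.reference_name == t.contig
                    and abs(pos - t.ref_pos) <= tolerance):
                tp += 1
            else:
                fp += 1
    fn += len(by_key) - len(seen)
    total = tp + fp + fn
    zero = (tp + fp == 0) or (total == 0)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / total if total else 1.0
    return AccuracyReport(tp, fp, fn, precision, recall, zero)


# ---------------------------------------------------------------------------
# text-format emission
# ---------------------------------------------------------------------------

def write_fasta(path: str, contigs: Sequence[Tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(path: str, reference: ReferenceGenome,
              variants: Sequence[VariantRecord],
              sample_names: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.contigs:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for v in variants:
            gts = "\t".join(f"{g[0]}|{g[1]}" if g is not None else ".|."
                            for g in v.genotypes)
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def write_fastq(path: str, reads: Sequence[Tuple[str, str, str]],
                mate: Optional[int] = None) -> None:
    suffix = f"/{mate}" if mate else ""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}{suffix}\n{seq}\n+\n{qual}\n")


def write_truth(path: str, truth: Sequence[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\thaplotype\thap_pos\tref_pos\tstrand\tcontig\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.mate}\t{t.haplotype}\t{t.hap_pos}"
                     f"\t{t.ref_pos}\t{t.strand}\t{t.contig}\n")


def read_truth(path: str) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, mate, hap, hp, rp, strand, contig = \
                line.rstrip("\n").split("\t")
            out.append(TruthRecord(rid, int(mate), hap, int(hp), int(rp),
                                   strand, contig))
    return out
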