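"""End-to-end alignment engine: index bundle + the seed/chain/extend/lift/
pair pipeline that the CLI drives.

The engine is deterministic: ties are broken by (score, contig, position,
strand) everywhere, so repeated runs on identical inputs produce
byte-identical SAM.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment import Alignment, cigar_to_string
from .chaining import Anchor, Chain, ChainConfig, chain_anchors, \
    uniqueness_filter
from .extension import ScoringScheme, fill_between_anchors
from .mems import (Seed, SeedingConfig, extract_mems, frequency_filter,
                   locate_seeds, matching_statistics, mem_stats_rows,
                   orientation_filter, revcomp, split_long_mems)
from .pairing import (InsertSizeModel, PairingConfig, count_secondary_scores,
                      insert_size, mapq_paired, mapq_single, orphan_recover,
                      pair_select)
from .pangenome import (LiftMap, LiftSegment, PangenomeText, ReferenceGenome,
                        VariantRecord, build_pangenome_text, dedup_same_position,
                        lift_alignment, materialize_haplotypes)
from .rindex import RIndex, build_rindex
from . import samio
from .samio import (FLAG_FIRST, FLAG_MATE_REVERSE, FLAG_MATE_UNMAPPED,
                    FLAG_PAIRED, FLAG_PROPER, FLAG_REVERSE, FLAG_SECOND,
                    FLAG_UNMAPPED, SamRecord)


# ---------------------------------------------------------------------------
# index bundle
# ---------------------------------------------------------------------------

class PangenomeIndex:
    """r-index plus lift maps and SAM header metadata."""

    def __init__(self, rindex: RIndex,
                 lift_maps: Optional[Dict[str, LiftMap]],
                 ref_contigs: Optional[List[Tuple[str, int]]]):
        self.rindex = rindex
        self.lift_maps = lift_maps
        self.ref_contigs = ref_contigs

    @property
    def lifted(self) -> bool:
        return self.lift_maps is not None

    @property
    def text(self) -> PangenomeText:
        return self.rindex.text

    def sam_contigs(self) -> List[Tuple[str, int]]:
        docs = [(self.text.doc_names[d], self.text.doc_length(d))
                for d in range(self.text.n_docs)]
        if self.lifted:
            return list(self.ref_contigs) + docs
        return docs

    # -- construction -------------------------------------------------------

    @classmethod
    def build_from_vcf(cls, reference: ReferenceGenome,
                       variants: Sequence[VariantRecord],
                       sample_names: Sequence[str],
                       include_reference: bool = True) -> "PangenomeIndex":
        haps, lifts = materialize_haplotypes(reference, variants, sample_names)
        text = build_pangenome_text(haps, include_reference=include_reference,
                                    reference=reference)
        lift_maps = {h.id: lm for h, lm in zip(haps, lifts)}
        if include_reference:
            for cname, cseq in reference.contigs:
                lift_maps[f"REF#{cname}"] = LiftMap.identity(cname, len(cseq))
        ref_contigs = [(n, len(s)) for n, s in reference.contigs]
        return cls(build_rindex(text), lift_maps, ref_contigs)

    @classmethod
    def build_from_fasta(cls, reference: ReferenceGenome) -> "PangenomeIndex":
        """FASTA-only mode: every record is its own document; no liftover."""
        from .pangenome import Haplotype

        haps = [Haplotype(id=n, sequence=s, source_contig=n)
                for n, s in reference.contigs]
        text = build_pangenome_text(haps)
        return cls(build_rindex(text), None, None)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str) -> None:
        self.rindex.save(directory)
        meta = {"lifted": self.lifted, "ref_contigs": self.ref_contigs}
        with open(os.path.join(directory, "index_meta.json"), "w") as fh:
            json.dump(meta, fh)
        if self.lifted:
            payload = {}
            for name, lm in self.lift_maps.items():
                payload[name] = {
                    "contig": lm.contig,
                    "segments": [[s.hap_start, s.ref_start, s.length,
                                  s.kind, s.seq] for s in lm.segments],
                    "substitutions": [[p, b] for p, b in lm.substitutions],
                }
            with open(os.path.join(directory, "liftmaps.json"), "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def load(cls, directory: str) -> "PangenomeIndex":
        rindex = RIndex.load(directory)
        with open(os.path.join(directory, "index_meta.json")) as fh:
            meta = json.load(fh)
        lift_maps = None
        if meta["lifted"]:
            with open(os.path.join(directory, "liftmaps.json")) as fh:
                payload = json.load(fh)
            lift_maps = {}
            for name, d in payload.items():
                segs = [LiftSegment(*row) for row in d["segments"]]
                subs = [(p, b) for p, b in d["substitutions"]]
                lift_maps[name] = LiftMap(d["contig"], segs, subs)
        ref_contigs = ([tuple(c) for c in meta["ref_contigs"]]
                       if meta["ref_contigs"] else None)
        return cls(rindex, lift_maps, ref_contigs)


# ---------------------------------------------------------------------------
# aligner
# ---------------------------------------------------------------------------

@dataclass
class AlignerConfig:
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    chaining: ChainConfig = field(default_factory=ChainConfig)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    cigar_mode: str = "M"
    collect_mem_stats: bool = False


class Aligner:
    def __init__(self, index: PangenomeIndex,
                 cfg: Optional[AlignerConfig] = None):
        self.index = index
        self.cfg = cfg or AlignerConfig()
        text = index.text
        self._doc_seqs: List[bytes] = [text.doc_seq(d)
                                       for d in range(text.n_docs)]
        self._doc_idx = {n: i for i, n in enumerate(text.doc_names)}
        self._lifts: List[Optional[LiftMap]] = [
            index.lift_maps.get(n) if index.lifted else None
            for n in text.doc_names]
        self.mem_stats_rows: List[list] = []

    # -- seeding ------------------------------------------------------------

    def _strand_seeds(self, oriented: bytes, strand: str) -> List[Seed]:
        cfg = self.cfg.seeding
        ms = matching_statistics(oriented, self.index.rindex)
        mems = extract_mems(ms, cfg)
        if not mems:
            return []
        halves = split_long_mems(mems, cfg)
        return locate_seeds(halves, oriented, strand, self.index.rindex, cfg)

    def seed_read(self, read: bytes, read_id: str = "",
                  ) -> Tuple[List[Seed], List[Seed]]:
        cfg = self.cfg.seeding
        fwd = self._strand_seeds(read, "+")
        rc = self._strand_seeds(revcomp(read), "-")
        pooled = frequency_filter(fwd + rc, cfg)
        after_freq = pooled
        fwd2 = [s for s in pooled if s.strand == "+"]
        rc2 = [s for s in pooled if s.strand == "-"]
        fwd3, rc3 = orientation_filter(fwd2, rc2, cfg)
        if self.cfg.collect_mem_stats:
            self.mem_stats_rows.append(mem_stats_rows(
                read_id, fwd, rc, after_freq, fwd3 + rc3))
        return fwd3, rc3

    # -- candidate generation ----------------------------------------------

    def _chain_lift_key(self, chain: Chain) -> Tuple[str, int]:
        a0 = chain.anchors[0]
        lm = self._lifts[a0.doc]
        if lm is not None:
            r = lm.hap_to_ref(a0.y)
            if r is not None:
                return (lm.contig, r)
        return (self.index.text.doc_names[a0.doc], a0.y)

    def candidates(self, read: bytes, read_id: str = "") -> List[Alignment]:
        """Deduplicated, lifted candidate alignments, best first."""
        ccfg = self.cfg.chaining
        fwd_seeds, rc_seeds = self.seed_read(read, read_id)
        groups: Dict[Tuple[int, str], List[Anchor]] = {}
        for seed in fwd_seeds + rc_seeds:
            for doc, local in seed.occurrences:
                groups.setdefault((doc, seed.strand), []).append(
                    Anchor(x=seed.read_start, y=local, l=seed.length,
                           doc=doc, strand=seed.strand))
        chains: List[Chain] = []
        for (doc, strand), anchors in sorted(groups.items()):
            chains.extend(chain_anchors(anchors, ccfg))
        chains = [c for c in chains if c.score >= ccfg.min_chain_score]
        for c in chains:
            c.leftmost_lifted_pos = self._chain_lift_key(c)
        chains.sort(key=lambda c: (-c.score, c.leftmost_lifted_pos,
                                   c.doc, c.strand))
        chains = uniqueness_filter(chains, ccfg)
        chains = chains[:ccfg.max_chains]

        rc = revcomp(read)
        alns: List[Alignment] = []
        for c in chains:
            query = read if c.strand == "+" else rc
            aln = fill_between_anchors(
                query, self._doc_seqs[c.doc], c, self.cfg.scheme,
                doc_name=self.index.text.doc_names[c.doc], read_id=read_id,
                cigar_mode=self.cfg.cigar_mode)
            lm = self._lifts[c.doc]
            if lm is not None:
                aln = lift_alignment(aln, lm)
            alns.append(aln)
        # unliftable alignments survive only when nothing lifts
        liftable = [a for a in alns if not a.unliftable]
        if liftable:
            alns = liftable
        alns = dedup_same_position(alns)
        alns.sort(key=lambda a: (-a.score,
                                 a.contig if a.contig is not None else a.doc,
                                 a.position, a.strand))
        return alns

    # -- record emission ----------------------------------------------------

    def _record(self, read_id: str, read: bytes, qual: str,
                aln: Optional[Alignment], mapq: int, flag_extra: int,
                mate: Optional[Alignment], s2: float,
                proper: bool) -> SamRecord:
        flag = flag_extra
        if aln is None:
            flag |= FLAG_UNMAPPED
            if mate is not None:
                rnext = (mate.contig if mate.contig is not None else mate.doc)
                pnext = mate.position + 1
            else:
                rnext, pnext = "*", 0
            return SamRecord(qname=read_id, flag=flag, rnext=rnext,
                             pnext=pnext, seq=read.decode(), qual=qual or "*")
        if aln.strand == "-":
            flag |= FLAG_REVERSE
            seq = revcomp(read).decode()
            q = (qual or "")[::-1] or "*"
        else:
            seq = read.decode()
            q = qual or "*"
        if proper:
            flag |= FLAG_PROPER
        rname = aln.contig if aln.contig is not None else aln.doc
        tlen = 0
        rnext, pnext = "*", 0
        if mate is not None:
            mrname = mate.contig if mate.contig is not None else mate.doc
            rnext = "=" if mrname == rname else mrname
            pnext = mate.position + 1
            if mrname == rname:
                size = insert_size(aln, mate)
                if (aln.position, aln.end) <= (mate.position, mate.end):
                    tlen = size
                else:
                    tlen = -size
        tags = {"AS": int(aln.score), "NM": int(aln.nm)}
        if s2 > 0:
            tags["XS"] = int(s2)
        if aln.unliftable:
            tags["XU"] = 1
        return SamRecord(qname=read_id, flag=flag, rname=rname,
                         pos=aln.position + 1, mapq=mapq,
                         cigar=cigar_to_string(aln.cigar), rnext=rnext,
                         pnext=pnext, tlen=tlen, seq=seq, qual=q, tags=tags)

    @staticmethod
    def _second_best(cands: Sequence[Alignment], chosen: Alignment) -> float:
        others = [c.score for c in cands if c is not chosen]
        return max(others) if others else 0.0

    def _single_mapq(self, cands: Sequence[Alignment], chosen: Alignment,
                     read_len: int) -> Tuple[int, float]:
        s2 = self._second_best(cands, chosen)
        n = count_secondary_scores([c.score for c in cands], chosen.score,
                                   self.cfg.pairing.mapq_window_fraction)
        return mapq_single(chosen.score, s2, n, read_len,
                           self.cfg.scheme), s2

    # -- single-end ---------------------------------------------------------

    def align_single(self, reads: Iterable[Tuple[str, str, str]],
                     ) -> List[SamRecord]:
        out = []
        for rid, seq, qual in reads:
            read = seq.upper().encode()
            cands = self.candidates(read, rid)
            if not cands:
                out.append(self._record(rid, read, qual, None, 0, 0, None,
                                        0.0, False))
                continue
            best = cands[0]
            q, s2 = self._single_mapq(cands, best, len(read))
            out.append(self._record(rid, read, qual, best, q, 0, None, s2,
                                    False))
        return out

    # -- paired-end ---------------------------------------------------------

    def estimate_insert_model(self, cand_pairs: Sequence[
            Tuple[List[Alignment], List[Alignment]]]) -> InsertSizeModel:
        """Welford model over the first max_model_pairs uniquely-mapped pairs."""
        model = InsertSizeModel()
        limit = self.cfg.pairing.max_model_pairs
        for c1, c2 in cand_pairs:
            if model.count >= limit:
                break
            if len(c1) == 1 and len(c2) == 1:
                a1, a2 = c1[0], c2[0]
                r1 = a1.contig if a1.contig is not None else a1.doc
                r2 = a2.contig if a2.contig is not None else a2.doc
                if r1 == r2 and a1.strand != a2.strand:
                    model.update(insert_size(a1, a2))
        return model

    def _recover_orphan(self, anchor: Alignment, read: bytes,
                        model: InsertSizeModel) -> Optional[Alignment]:
        doc_i = self._doc_idx.get(anchor.doc)
        if doc_i is None:
            return None
        oriented = read if anchor.strand == "-" else revcomp(read)
        hap_anchor = anchor.copy(contig=None, ref_start=None)
        rec = orphan_recover(hap_anchor, oriented, self._doc_seqs[doc_i],
                             model, self.cfg.scheme, self.cfg.pairing)
        if rec is None:
            return None
        from .alignment import collapse_matches, normalize_cigar
        from .extension import _cigar_nm

        cig = normalize_cigar(rec.cigar)
        nm = _cigar_nm(cig, oriented, self._doc_seqs[doc_i][rec.hap_start:])
        if self.cfg.cigar_mode == "M":
            cig = collapse_matches(cig)
        aln = Alignment(doc=anchor.doc, strand=rec.strand,
                        hap_start=rec.hap_start, cigar=cig, score=rec.score,
                        nm=nm)
        lm = self._lifts[doc_i]
        if lm is not None:
            aln = lift_alignment(aln, lm)
            if aln.unliftable:
                return None
        return aln

    def align_paired(self, reads1: Sequence[Tuple[str, str, str]],
                     reads2: Sequence[Tuple[str, str, str]],
                     ) -> Tuple[List[SamRecord], InsertSizeModel]:
        if len(reads1) != len(reads2):
            raise ValueError("mate FASTQ files differ in read count")
        cand_pairs = []
        for (rid1, s1, _), (rid2, s2, _) in zip(reads1, reads2):
            if rid1 != rid2:
                raise ValueError(f"mate id mismatch: {rid1!r} vs {rid2!r}")
            r1 = s1.upper().encode()
            r2 = s2.upper().encode()
            cand_pairs.append((self.candidates(r1, rid1),
                               self.candidates(r2, rid2)))
        model = self.estimate_insert_model(cand_pairs)

        records: List[SamRecord] = []
        for ((rid, s1, q1), (_, s2_, q2)), (c1, c2) in zip(
                zip(reads1, reads2), cand_pairs):
            r1 = s1.upper().encode()
            r2 = s2_.upper().encode()
            records.extend(self._pair_records(
                rid, r1, q1, r2, q2, c1, c2, model))
        return records, model

    def _pair_records(self, rid: str, r1: bytes, q1: str, r2: bytes, q2: str,
                      c1: List[Alignment], c2: List[Alignment],
                      model: InsertSizeModel) -> List[SamRecord]:
        pcfg = self.cfg.pairing
        base1 = FLAG_PAIRED | FLAG_FIRST
        base2 = FLAG_PAIRED | FLAG_SECOND
        a1, a2, pair_sums = pair_select(c1, c2, model, pcfg)
        proper = bool(pair_sums)

        # orphan recovery: exactly one mate aligned
        if not proper and pcfg.orphan_recovery_enabled and model.usable:
            if a1 is not None and a2 is None:
                rec = self._recover_orphan(a1, r2, model)
                if rec is not None:
                    a2, proper = rec, True
                    c2 = [rec]
                    pair_sums = [a1.score + rec.score]
            elif a2 is not None and a1 is None:
                rec = self._recover_orphan(a2, r1, model)
                if rec is not None:
                    a1, proper = rec, True
                    c1 = [rec]
                    pair_sums = [a2.score + rec.score]

        # mate flag context
        def mate_bits(mate: Optional[Alignment]) -> int:
            if mate is None:
                return FLAG_MATE_UNMAPPED
            return FLAG_MATE_REVERSE if mate.strand == "-" else 0

        out: List[SamRecord] = []
        if proper:
            s1p = a1.score + a2.score
            s2p = pair_sums[1] if len(pair_sums) > 1 else 0.0
            np_ = count_secondary_scores(pair_sums, s1p,
                                         pcfg.mapq_window_fraction)
            qp = mapq_single(s1p, s2p, np_, len(r1) + len(r2),
                             self.cfg.scheme)
            for read, qual, mine, other, cands, base in (
                    (r1, q1, a1, a2, c1, base1), (r2, q2, a2, a1, c2, base2)):
                qs, xs = self._single_mapq(cands, mine, len(read))
                qi = mapq_paired(qs, qp, s1p, s2p, self.cfg.scheme)
                out.append(self._record(rid, read, qual, mine, qi,
                                        base | mate_bits(other), other, xs,
                                        True))
            return out

        for read, qual, mine, other, cands, base in (
                (r1, q1, a1, a2, c1, base1), (r2, q2, a2, a1, c2, base2)):
            if mine is None:
                out.append(self._record(rid, read, qual, None, 0,
                                        base | mate_bits(other), other, 0.0,
                                        False))
            else:
                qs, xs = self._single_mapq(cands, mine, len(read))
                out.append(self._record(rid, read, qual, mine, qs,
                                        base | mate_bits(other), other, xs,
                                        False))
        return out
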