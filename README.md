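# panmem

A pangenome short-read aligner built on a run-length BWT (r-index).

`panmem` indexes a collection of haplotypes — materialized from a reference
FASTA plus a phased VCF, or taken directly from a multi-FASTA — and aligns
Illumina-style reads (100–250 bp, single- or paired-end) against all of them
at once.  Alignments are computed on the haplotypes and then lifted back to
linear-reference coordinates, so the output SAM works with ordinary
downstream tools.

Pipeline:

1. **Index** — prefix-free parsing is provided as the documented
   construction front-end; the desk-scale builder derives the suffix/LCP
   arrays directly and compresses them into a run-length BWT with
   run-boundary SA samples, a φ structure for locating, and per-character
   *thresholds* (the LCP minima between consecutive runs) that guide
   partial matching.
2. **Seeding** — two-pass matching statistics over the r-index yield
   maximal exact matches (MEMs, default minimum 25 bp; MEMs > 50 bp are
   split into two half-MEMs).  Occurrences are capped per genome, with
   optional frequency and orientation filters and a per-read MEM
   statistics CSV.
3. **Chaining & extension** — minimap2-style colinear chaining (score
   cutoff 40, top 5 chains, chain-uniqueness heuristic), then affine-gap
   gap-filling between anchors and extension to the read ends.
4. **Pairing** — insert sizes estimated online (Welford) from the first
   1000 uniquely aligned pairs; concordant pairs must fall within
   μ ± 4σ; orphaned mates are rescued by a fit alignment inside that
   window.
5. **Liftover & MAPQ** — alignments are lifted through per-haplotype
   segment maps, same-position duplicates collapse to the best score, and
   BWA-style mapping qualities (0–60) are assigned from the lifted score
   distribution.

A synthetic-fixtures module (`panmem.simulate`) generates random
pangenomes (SNPs + short indels as a phased VCF), Illumina-like FR read
pairs with substitution errors, ground truth, and precision/recall scoring
at a 10 bp tolerance — so the whole pipeline is testable offline.

## CLI

Build an index (VCF mode enables liftover; FASTA-only mode aligns to the
indexed records without it):

```sh
panmem build ref.fa -v phased.vcf -o index_dir
panmem build haplotypes.fa -o index_dir          # no liftover
```

Align reads (one FASTQ = single-end, two = paired-end):

```sh
panmem align -i index_dir -o out.sam -l 25 -S 1000 r1.fq r2.fq
```

Notable flags: `-l` minimum MEM length, `-S` occurrence cap per genome,
`-f/-F` MEM frequency filter, `-d/-D` orientation filter, `-a/-A`
chain-uniqueness filter, `-u/-U` orphan recovery, `--mem-stats stats.csv`.
Output is deterministic: identical inputs give byte-identical SAM.

## Tests

```sh
python -m pytest tests/
```

The suite includes per-module oracle checks (naive suffix array, naive
matching statistics, exhaustive chaining, full-matrix alignment) and
`tests/test_acceptance.py` with the end-to-end accuracy bar (100 kb
reference, 20 haplotypes, 10,000 read pairs; ≥ 99 % recall, ≥ 95 %
precision at 10 bp tolerance).  The full run takes a few minutes; the
end-to-end case dominates.

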