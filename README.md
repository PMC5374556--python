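# svforge

Simulation of tumor/normal genomes carrying structural variants, and of
GC-biased Illumina-like paired-end reads from mixtures of those genomes —
for benchmarking SV, SNV and CNV callers against an exact truth set.

Benchmarking a variant caller needs data where the answer is known.
`svforge` builds donor genomes with germline and somatic SNVs, indels
and seven structural-variant classes (deletions, insertions, tandem
duplications, inversions, intra- and inter-chromosomal translocations,
and CNVs with copy number 0–6), models the complications that make tumor
sequencing hard — aneuploidy, heterogeneous subclones, normal
contamination — and emits machine-readable truth (VCF 4.2 + BEDPE) with
exact coordinates alongside paired FASTQ.

Three things distinguish the design:

- **Backward variant application.** All variants are planned in
  reference coordinates, kept non-overlapping, and applied from the
  highest coordinate to the lowest, so no edit ever shifts the
  coordinates of another. Truth positions are exact by construction.
- **Provenance-encoding read names.** Every pair is named
  `genome|chrom|haplotype|S1|S2|strand|serial`, where S1 < S2 delimit
  the fragment (the donor segment is S1..S2+r for read length r). Purity
  and depth can be measured without alignment.
- **GC-bias of any shape.** After read generation, each pair is kept
  with probability

  p_S = f(GC_S) / (1 + f(GC_S)),

  where GC_S is the GC fraction of the pair's donor segment and f is any
  user-specified non-negative function of GC, modelled as a piecewise
  polynomial on [0, 1]. Three presets ship: a cubic (`f1`), a parabola
  peaking at GC 0.6 (`f2`), and a piecewise-linear tent (`f3`).

SV breakpoints follow the two formation mechanisms seen in real genomes:
NAHR (non-allelic homologous recombination; breakpoints drawn uniformly
from repeat-annotated bases, RepeatMasker `.out` or BED) and NHR
(breakpoints uniform along the chromosome). Small variants can cluster
around breakpoints with a Poisson count per breakpoint, and germline
SNVs/indels can be drawn from a dbSNP-style VCF instead of at random.

## Worked example

`examples/03_reads_and_mixing.py` simulates reads from a normal and a
tumor genome, mixes 50,000 pairs at 80% purity, and recovers the purity
from the read names alone:

```
requested purity 0.8, realized tumor fraction 0.7991
first read name: normal|chr1|1|166156|166411|+|0
```

The realized fraction differs from 0.8 only by multinomial sampling
noise (binomial sd ≈ 0.0018 at this depth). The read name says this
pair came from haplotype 1 of `chr1` of the normal genome, fragment
coordinates 166156–166511 (S2 + r with r = 100).

`examples/04_gc_bias.py` subsamples reads with preset `f2` and prints
retention per 0.05-wide GC bin against the f/(1+f) prediction:

```
gc_bin  n_total  observed  expected
  0.45     3127  0.4960    0.4905
  0.50     2735  0.5031    0.4958
  0.55     2878  0.5118    0.4996
  0.60     3123  0.5034    0.4996
```

Retention peaks where f2 peaks (f = 1 at GC 0.6, so p = 0.5) and falls
off on both sides, reproducing the depth-vs-GC curves seen in real
sequencing libraries.

The other examples cover the personal genome with truth output
(`01`), aneuploid subclone trees (`02`) and the one-config end-to-end
pipeline (`05`).

## Command line

A thin CLI wraps the pipeline:

```bash
svforge make-reference --length 1000000 --gc 0.41 --seed 1 --out ref.fa
svforge run-all --config run.yaml
svforge apply-gc-bias --config run.yaml --outdir out/   # re-run bias only
```

`run-all` writes the reference, per-genome FASTAs, per-genome truth
VCF/BEDPE, mixed paired FASTQ before and after GC-bias, a per-GC-bin
retention TSV, and a `manifest.json` with per-stage seeds and file
checksums. The same config and seed reproduce every output byte for
byte; `simulate-genome`, `simulate-tumor` and `simulate-reads` run
prefixes of the pipeline.

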