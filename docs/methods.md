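# Methods

## Model overview

`svforge` simulates high-throughput sequencing data in three stages.

1. **Personal genome.** Germline SNVs, indels and structural variants
   are planned against a reference genome and applied to two haplotypes.
2. **Tumor genomes.** A user-specified karyotype (integer copy number
   per chromosome) is applied to the personal genome; subclones are then
   derived iteratively, each inheriting its progenitor's cumulative
   variant set and adding private somatic variants. A linear chain of
   clones emulates stepwise clonal evolution; a star around one
   progenitor emulates a cancer-stem-cell architecture. The tree
   topology is explicit user input.
3. **Reads.** Illumina-like paired-end reads are simulated from every
   genome, mixed at user proportions (purity = summed tumor-clone
   proportions; normal fraction = 1 − purity), and optionally subjected
   to GC-biased subsampling.

## Coordinate discipline and backward application

All internal coordinates are 0-based half-open; conversion to 1-based
happens only in the VCF and RepeatMasker adapters. Variants are planned
in *reference* coordinates and kept pairwise non-overlapping —
structural-event footprints (source segments plus destination points)
additionally keep a minimum gap (default 100 bp) between each other,
because overlapping SVs would make truth coordinates ill-defined.
Placement is rejection-sampled with a bounded retry budget (default
1000) and errors out rather than degrade.

Because footprints are disjoint, a whole plan can be applied to a
haplotype in a single pass from the highest coordinate to the lowest:
no edit ever invalidates the reference coordinates of a later (lower)
edit. The implementation edits a byte buffer in place; an equal-length
substitution (an SNV) costs O(1) and a length-changing edit costs the
length of the tail it shifts, which keeps study-scale runs (10^5 SNVs,
hundreds of SVs) fast. The test suite checks this route against an
independent oracle that rebuilds each haplotype left-to-right from
reference segments and event payloads.

Somatic variants are planned in the same reference frame, disjoint from
all footprints along their clone lineage (sibling branches are
independent), and each clone's sequences are rebuilt from the reference
in one pass over its cumulative plan. Child variant sets are therefore
supersets of their parents' by construction, and truth files for every
genome share one coordinate system. Cross-lineage placements may hit
the same locus in different branches, as in real tumors.

## Structural-variant semantics

- *Deletion* removes its segment; *insertion* splices a payload (random
  bases, or a slice of a user FASTA of known insertion sequences);
  *inversion* substitutes the reverse complement; *tandem duplication*
  inserts extra adjacent copies (default 1).
- *Translocations* move or copy a segment to a destination on the same
  (intra-) or a different (inter-) chromosome. Balanced translocations
  remove the source — no net gain or loss of sequence; unbalanced ones
  keep the source and insert a copy, a net gain.
- *CNV* against the diploid baseline: copy number 0 deletes the segment
  from every haplotype, 1 from one haplotype; copy number k ≥ 3 inserts
  k − 2 extra copies at uniformly sampled, mutually disjoint positions
  on the same chromosome of one haplotype. Copy numbers are drawn
  uniformly from {0, 1, 3, 4, 5, 6} by default (2 is the no-op).
- Mechanism: with probability `mechanism_mix` an event is NAHR and all
  its breakpoints are drawn uniformly from bases covered by the repeat
  annotation; otherwise NHR, uniform over the chromosome.
- Zygosity: heterozygous variants go to one uniformly chosen haplotype
  copy, homozygous to all copies. The het/hom split is deterministic
  (`round(n · het_fraction)`), giving exact, testable counts. Somatic
  variants are het-like by default and land on one uniformly chosen
  copy of the (possibly aneuploid) chromosome.
- Breakpoint-proximal small variants: per breakpoint, a Poisson count
  (user-set mean) of SNVs/indels placed uniformly within ±window
  (default 100 bp), avoiding existing footprints — real breakpoints
  co-occur with small variants.

Truth is emitted as VCF 4.2 (small variants as plain records; SVs as
symbolic ALTs with SVTYPE/END/SVLEN/MECH/CN/CLONE, translocation
destinations in CHR2/POS2) plus a BEDPE with both breakend anchors,
class, mechanism, copy number and clone of origin.

## Read model

The number of pairs is `round(C · G / (2r))` with C the requested
coverage, G the total haplotype length and r the read length, so C is
the mean depth per *haplotype* base (a diploid genome yields 2C at a
reference position, and a chromosome at copy number k yields depth
proportional to k — the k/2 ratio against the diploid baseline that the
tests verify). Fragments start uniformly per haplotype (haplotypes
chosen length-proportionally); insert sizes are normal (default
320 ± 60 bp), resampled until ≥ 2r and within the haplotype. Mates
follow the Illumina FR convention with a random strand flip. The error
model is substitution-only with i.i.d. per-base errors (default
10⁻³); qualities are constant Q30 symbols or an optional linear ramp.
The simulator is internal by design — full control of the
provenance-encoding read names is what lets the purity and GC-bias
stages work without alignment; emulating any particular commercial
error profile is out of scope.

Mixing is multinomial: each output pair's source genome is drawn i.i.d.
from the mixture, and pairs are consumed sequentially from per-genome
streams (capacity-checked with 5% headroom, optional
sampling-with-replacement). Realized fractions therefore fluctuate
around the targets with binomial sd.

## GC-bias stage

Each pair's donor segment S1..S2+r is looked up from its read name and
its GC fraction computed (N bases excluded from numerator and
denominator; an all-N segment has undefined GC and the pair is dropped
and counted separately). The pair is kept with probability
f(GC)/(1 + f(GC)); mates stay together. Bias functions are piecewise
polynomials tiling [0, 1]; raw values below zero (the `f1` cubic dips
negative near GC 0 and 1) are clamped to 0, since a keep probability
must be valid — clamping preserves the shape everywhere else. Bias is
applied after mixing, and the pipeline writes both pre- and post-bias
FASTQ so the retention curve (TSV, 0.05-wide GC bins, observed vs mean
predicted rate) can be audited; the bias stage reads only files on
disk, so it can be re-run in isolation and reproduces its output
exactly.

## Synthetic references

The built-in generator draws i.i.d. bases with P(G) = P(C) =
gc_target/2 (default 0.41, the human genome-wide GC). It emulates
sequence composition only: no repeats, no chromosome-scale GC
structure, no gaps. Consequences: NAHR placement in tests uses
synthetic repeat annotations rather than genuine homology; GC-bin
coverage for retention-curve tests comes from blocks engineered at each
bin's midpoint; and passing tests demonstrate the machinery's
correctness on composition-realistic sequence, not caller performance
on real genomes. Generation is deterministic given (lengths, gc, seed)
and byte-for-byte reproducible.

## Reproducibility and numerical choices

Every stage seed is derived by hashing (master seed, stage name) into
[0, 2³¹), so stages can be re-run independently and a full run is
reproducible to identical file checksums. Sorting ties (same position)
break by variant-class order then insertion order. Proportion sums are
validated to 1 within 10⁻⁹. Capacity violations (more variants than
placeable positions, exhausted read streams, un-placeable events) raise
errors rather than silently truncating.

Problem sizes in the test and acceptance workloads are chosen so each
statistical check has comfortable power at 3-sd tolerances: 1 Mb
fixtures for read-level checks (binomial sd ≈ 1.3–1.6 × 10⁻³ for purity
at 10⁵ pairs), a 20 Mb reference for the 10⁵-SNV count-fidelity run,
50 random instances for the application-oracle equivalence, and 200
replicates for the Poisson breakpoint-variant mean.

## Known limitations

- No nested or chained SVs, microhomology or templated insertions at
  breakpoints, and no phasing beyond the two-haplotype assignment.
- No subclonal copy-number fractions below whole-event resolution, and
  no continuous-time mutation-rate models — the clone tree is explicit
  user input.
- Substitution-only sequencing errors; no indel errors, optical
  duplicates or adapter contamination.
- The GC-bias stage subsamples at the fragment level; it does not model
  amplification mechanisms that produce the bias in the first place,
  and cannot *increase* depth anywhere (f/(1+f) < 1).
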