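"""Simulate a personal genome: germline SNVs, indels and SVs with truth.

Builds a 200 kb synthetic reference, plans a germline variant set with
all seven SV classes, applies it backward to both haplotypes, and writes
the truth VCF/BEDPE.
"""

from pathlib import Path

from svforge import generate_synthetic_reference, plan_svs, sample_indels, sample_snvs
from svforge.tumor import build_haplotypes
from svforge.variants import SV_CLASSES, FootprintIndex, VariantPlan, write_truth

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

reference = generate_synthetic_reference(
    {"chr1": 120_000, "chr2": 80_000}, gc_target=0.41, seed=1
)
footprints = FootprintIndex()
svs = plan_svs(reference, {c: 2 for c in SV_CLASSES},
               size_range=(200, 2000), seed=2, footprints=footprints)
plan = VariantPlan(
    snvs=sample_snvs(reference, 300, het_fraction=0.5, seed=3,
                     footprints=footprints),
    indels=sample_indels(reference, 50, size_range=(1, 10), seed=4,
                         footprints=footprints),
    svs=svs.svs,
)
personal = build_haplotypes(reference, plan, genome_id="personal")
write_truth(plan, reference, out / "truth.vcf", out / "truth.bedpe")

print("variant counts:", plan.counts())
for chrom, hap, seq in personal.copies:
    delta = len(seq) - reference.length_of(chrom)
    print(f"  {chrom} hap{hap}: {len(seq)} bp ({delta:+d} vs reference)")
# The counts are exactly what was requested; each haplotype's length
# change is the net of its deletions, insertions and duplications, and
# every truth coordinate refers to the unmodified reference.
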