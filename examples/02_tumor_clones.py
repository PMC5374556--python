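"""Simulate an aneuploid tumor with two nested subclones.

The progenitor gets trisomy of chr1; subclone c2 descends from c1, so
its cumulative somatic variant set strictly contains c1's.
"""

from svforge import generate_synthetic_reference, sample_snvs
from svforge.tumor import CloneSpec, SomaticConfig, build_clone_set
from svforge.variants import FootprintIndex, VariantPlan

reference = generate_synthetic_reference({"chr1": 80_000, "chr2": 60_000},
                                         gc_target=0.41, seed=5)
footprints = FootprintIndex()
germline = VariantPlan(
    snvs=sample_snvs(reference, 200, seed=6, footprints=footprints)
)
somatic = SomaticConfig(snv_count=40, sv_class_counts={"deletion": 1},
                        sv_size_range=(500, 3000))
clones = build_clone_set(
    reference, germline, {"chr1": 3},
    [CloneSpec("c1", None, somatic, 0.6),
     CloneSpec("c2", "c1", somatic, 0.4)],
    seed=7, normal_fraction=0.0, germline_footprints=footprints,
)
for node in clones:
    print(f"clone {node.clone_id} (parent {node.parent_id}):",
          f"copy numbers {node.haplotype_set.copy_numbers()},",
          f"{len(node.cumulative_somatic.snvs)} cumulative somatic SNVs,",
          f"proportion {node.proportion}")
# c2 carries c1's 40 somatic SNVs plus 40 private ones; both clones share
# the trisomic chr1 karyotype inherited from the progenitor.
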