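import numpy as np
import pytest

from svforge.genome import HaplotypeSet
from svforge.tumor import (
    CloneSpec,
    ConfigError,
    SomaticConfig,
    apply_karyotype,
    build_clone_set,
    build_haplotypes,
    derive_subclone,
    realize_karyotype,
)
from svforge.variants import FootprintIndex, VariantPlan, sample_snvs


@pytest.fixture()
def diploid(small_reference) -> HaplotypeSet:
    return HaplotypeSet.diploid_from_reference(small_reference, "n")


def _germline(reference, n_snv=40, seed=1):
    fp = FootprintIndex()
    plan = VariantPlan(snvs=sample_snvs(reference, n_snv, seed=seed, footprints=fp))
    return plan, fp


def _variant_keys(plan):
    out = set()
    for v in plan.sorted_variants():
        pos = v.position if hasattr(v, "position") else v.start
        out.add((type(v).__name__, v.chromosome, pos))
    return out


class TestKaryotype:
    def test_trisomy_gives_three_copies(self, diploid):
        out = apply_karyotype(diploid, {"chr1": 3}, seed=1)
        assert out.copy_numbers() == {"chr1": 3, "chr2": 2}

    def test_nullisomy_removes_chromosome(self, diploid):
        out = apply_karyotype(diploid, {"chr1": 0}, seed=1)
        assert "chr1" not in out.copy_numbers()

    def test_diploid_karyotype_is_identity(self, diploid):
        out = apply_karyotype(diploid, {"chr1": 2, "chr2": 2}, seed=1)
        assert out.copies == diploid.copies

    def test_unknown_chromosome_rejected(self, diploid):
        with pytest.raises(ConfigError):
            apply_karyotype(diploid, {"chrX": 2})

    def test_realization_matches_copy_numbers(self, small_reference):
        real = realize_karyotype(small_reference, {"chr1": 5, "chr2": 1}, seed=2)
        assert len(real["chr1"]) == 5 and len(real["chr2"]) == 1
        assert set(real["chr1"]) <= {0, 1}

    def test_extra_copies_duplicate_existing_haplotypes(self, small_reference):
        germ, fp = _germline(small_reference)
        real = realize_karyotype(small_reference, {"chr1": 4}, seed=3)
        hs = build_haplotypes(small_reference, germ, None, real, "t")
        germline_seqs = {
            h: build_haplotypes(small_reference, germ, genome_id="n").sequence(
                "chr1", h
            )
            for h in (0, 1)
        }
        for i, src in enumerate(real["chr1"]):
            assert hs.sequence("chr1", i) == germline_seqs[src]


def _progenitor(reference, germ, fp, karyotype=None, seed=5):
    specs = [CloneSpec("p", None, SomaticConfig(snv_count=0), 1.0)]
    (node,) = build_clone_set(
        reference, germ, karyotype or {}, specs, seed=seed,
        normal_fraction=0.0, germline_footprints=fp,
    )
    return node


class TestDeriveSubclone:
    def test_zero_new_variants_is_identity(self, small_reference):
        germ, fp = _germline(small_reference)
        prog = _progenitor(small_reference, germ, fp)
        child = derive_subclone(prog, SomaticConfig(), seed=6, clone_id="c")
        assert child.haplotype_set.copies == prog.haplotype_set.copies
        assert _variant_keys(child.cumulative_somatic) == _variant_keys(
            prog.cumulative_somatic
        )

    def test_chain_accumulates_private_variants(self, small_reference):
        germ, fp = _germline(small_reference)
        prog = _progenitor(small_reference, germ, fp)
        cfg = SomaticConfig(snv_count=50)
        child = derive_subclone(prog, cfg, seed=7, clone_id="c1")
        grand = derive_subclone(child, cfg, seed=8, clone_id="c2")
        n0 = len(prog.cumulative_somatic.snvs)
        assert len(child.cumulative_somatic.snvs) == n0 + 50
        assert len(grand.cumulative_somatic.snvs) == n0 + 100

    def test_monotone_inheritance(self, small_reference):
        germ, fp = _germline(small_reference)
        prog = _progenitor(small_reference, germ, fp)
        child = derive_subclone(
            prog, SomaticConfig(snv_count=30,
                                sv_class_counts={"deletion": 2},
                                sv_size_range=(50, 200)),
            seed=9, clone_id="c",
        )
        parent_keys = _variant_keys(prog.cumulative_somatic)
        child_keys = _variant_keys(child.cumulative_somatic)
        assert parent_keys < child_keys  # strict superset

    def test_private_variants_avoid_inherited_footprints(self, small_reference):
        germ, fp = _germline(small_reference, n_snv=200)
        prog = _progenitor(small_reference, germ, fp)
        parent = derive_subclone(
            prog, SomaticConfig(snv_count=100), seed=10, clone_id="c1"
        )
        child = derive_subclone(
            parent, SomaticConfig(snv_count=100), seed=11, clone_id="c2"
        )
        inherited = {
            (v.chromosome, v.position)
            for v in germ.snvs + parent.cumulative_somatic.snvs
        }
        private = {
            (v.chromosome, v.position) for v in child.private_somatic.snvs
        }
        assert not inherited & private

    def test_somatic_origin_tags_carry_clone_id(self, small_reference):
        germ, fp = _germline(small_reference)
        prog = _progenitor(small_reference, germ, fp)
        child = derive_subclone(
            prog, SomaticConfig(snv_count=5), seed=12, clone_id="cX"
        )
        assert all(
            v.origin == "somatic:cX" for v in child.private_somatic.snvs
        )


class TestBuildCloneSet:
    def test_single_progenitor(self, small_reference):
        germ, fp = _germline(small_reference)
        clones = build_clone_set(
            small_reference, germ, {}, [
                CloneSpec("p", None, SomaticConfig(snv_count=10), 1.0)
            ],
            seed=13, germline_footprints=fp,
        )
        assert [c.clone_id for c in clones] == ["p"]

    def test_linear_chain_of_three(self, small_reference):
        germ, fp = _germline(small_reference)
        cfg = SomaticConfig(snv_count=20)
        clones = build_clone_set(
            small_reference, germ, {}, [
                CloneSpec("a", None, cfg, 0.2),
                CloneSpec("b", "a", cfg, 0.3),
                CloneSpec("c", "b", cfg, 0.5),
            ],
            seed=14, germline_footprints=fp,
        )
        counts = [len(c.cumulative_somatic.snvs) for c in clones]
        assert counts == [20, 40, 60]

    def test_proportions_must_sum_to_one(self, small_reference):
        germ, fp = _germline(small_reference)
        specs = [
            CloneSpec("a", None, SomaticConfig(), 0.4),
            CloneSpec("b", "a", SomaticConfig(), 0.5),
        ]
        with pytest.raises(ConfigError, match="sum"):
            build_clone_set(small_reference, germ, {}, specs,
                            normal_fraction=0.2, germline_footprints=fp)
        # 0.2 + 0.4 + 0.4 is accepted
        build_clone_set(
            small_reference, germ, {},
            [CloneSpec("a", None, SomaticConfig(), 0.4),
             CloneSpec("b", "a", SomaticConfig(), 0.4)],
            normal_fraction=0.2, germline_footprints=fp,
        )

    def test_cycle_rejected(self, small_reference):
        germ, fp = _germline(small_reference)
        specs = [
            CloneSpec("a", "b", SomaticConfig(), 0.5),
            CloneSpec("b", "a", SomaticConfig(), 0.5),
        ]
        with pytest.raises(ConfigError, match="cycle"):
            build_clone_set(small_reference, germ, {}, specs,
                            germline_footprints=fp)

    def test_truth_files_emitted_per_clone(self, small_reference, tmp_path):
        germ, fp = _germline(small_reference)
        build_clone_set(
            small_reference, germ, {}, [
                CloneSpec("a", None, SomaticConfig(snv_count=5), 0.5),
                CloneSpec("b", "a", SomaticConfig(snv_count=5), 0.5),
            ],
            seed=15, germline_footprints=fp, truth_dir=tmp_path,
        )
        for cid in ("a", "b"):
            assert (tmp_path / f"{cid}.truth.vcf").exists()
            assert (tmp_path / f"{cid}.truth.bedpe").exists()

    def test_aneuploid_clone_copy_numbers(self, small_reference):
        germ, fp = _germline(small_reference)
        clones = build_clone_set(
            small_reference, germ, {"chr1": 3, "chr2": 1}, [
                CloneSpec("p", None, SomaticConfig(snv_count=10), 1.0)
            ],
            seed=16, germline_footprints=fp,
        )
        assert clones[0].haplotype_set.copy_numbers() == {"chr1": 3, "chr2": 1}
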