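from collections import Counter

import numpy as np
import pysam
import pytest

from helpers_oracle import expected_length_delta, rebuild_haplotype
from svforge.genome import GenomicInterval, generate_synthetic_reference
from svforge.tumor import build_haplotypes
from svforge.variants import (
    SV_CLASSES,
    CapacityError,
    FootprintIndex,
    PlacementError,
    SNV,
    SVEvent,
    VariantPlan,
    add_breakpoint_proximal_variants,
    apply_edits_backward,
    apply_plan_backward,
    donor_position,
    plan_edits,
    plan_svs,
    sample_indels,
    sample_snvs,
    write_truth,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=30000>\n"
    "##contig=<ID=chr2,length=20000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestSampleSnvs:
    def test_zero_returns_empty(self, small_reference):
        assert sample_snvs(small_reference, 0) == []

    def test_all_het_when_fraction_one(self, small_reference):
        snvs = sample_snvs(small_reference, 100, het_fraction=1.0, seed=1)
        assert len(snvs) == 100
        assert all(s.zygosity == "het" and s.haplotype in (0, 1) for s in snvs)

    def test_exact_het_split(self, small_reference):
        snvs = sample_snvs(small_reference, 1000, het_fraction=0.5, seed=2)
        assert sum(s.zygosity == "het" for s in snvs) == 500

    def test_positions_distinct_and_ref_matches(self, small_reference):
        snvs = sample_snvs(small_reference, 500, seed=3)
        keys = {(s.chromosome, s.position) for s in snvs}
        assert len(keys) == 500
        for s in snvs:
            assert small_reference.chromosomes[s.chromosome][s.position] == s.ref
            assert s.alt != s.ref

    def test_capacity_error(self):
        tiny = generate_synthetic_reference([10], seed=0)
        with pytest.raises(CapacityError):
            sample_snvs(tiny, 100)

    def test_vcf_source_sampling(self, small_reference, tmp_path):
        seq = small_reference.chromosomes["chr1"]
        rows = []
        good = {}
        for pos in (100, 500, 900, 1500, 2500):
            ref = seq[pos]
            alt = "A" if ref != "A" else "C"
            rows.append(f"chr1\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")
            good[pos] = (ref, alt)
        # a record whose REF contradicts the genome must be ignored
        bad_ref = "A" if seq[50] != "A" else "C"
        rows.append(f"chr1\t51\t.\t{bad_ref}\tG\t.\t.\t.\n")
        vcf = tmp_path / "source.vcf"
        vcf.write_text(VCF_HEADER + "".join(rows))
        snvs = sample_snvs(small_reference, 3, source=vcf, seed=4)
        assert len(snvs) == 3
        for s in snvs:
            assert (s.ref, s.alt) == good[s.position]
        with pytest.raises(CapacityError):
            sample_snvs(small_reference, 6, source=vcf, seed=4)


class TestSampleIndels:
    def test_unit_size_range(self, small_reference):
        indels = sample_indels(small_reference, 50, size_range=(1, 1), seed=5)
        assert len(indels) == 50
        assert all(abs(len(v.ref) - len(v.alt)) == 1 for v in indels)

    def test_deletion_alleles_anchored_on_genome(self, small_reference):
        indels = sample_indels(small_reference, 200, size_range=(2, 8), seed=6)
        for v in indels:
            seq = small_reference.chromosomes[v.chromosome]
            assert v.ref[0] == v.alt[0] == seq[v.position]
            if v.is_deletion:
                assert seq[v.position:v.position + len(v.ref)] == v.ref


def _repeats_covering(reference, n=40, width=600, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for chrom, seq in reference.chromosomes.items():
        for _ in range(n):
            s = int(rng.integers(0, len(seq) - width))
            out.append(GenomicInterval(chrom, s, s + width))
    return sorted(out)


class TestPlanSvs:
    def test_exact_class_counts(self, small_reference):
        plan = plan_svs(
            small_reference, {"deletion": 2, "inversion": 1},
            size_range=(50, 500), seed=7,
        )
        assert plan.counts()["deletion"] == 2
        assert plan.counts()["inversion"] == 1
        assert len(plan.svs) == 3

    def test_nahr_breakpoints_inside_repeats(self, small_reference):
        repeats = _repeats_covering(small_reference)
        plan = plan_svs(
            small_reference,
            {"deletion": 3, "inversion": 2, "insertion": 2, "cnv": 2},
            size_range=(50, 400), mechanism_mix=1.0, repeats=repeats,
            seed=8,
        )
        covered = {
            (iv.chromosome, p)
            for iv in repeats
            for p in range(iv.start, iv.end)
        }
        for ev in plan.svs:
            assert ev.mechanism == "NAHR"
            for chrom, bp in ev.breakpoints():
                assert (chrom, bp) in covered

    def test_nahr_without_repeats_rejected(self, small_reference):
        with pytest.raises(PlacementError):
            plan_svs(small_reference, {"deletion": 1}, mechanism_mix=1.0)

    def test_footprints_respect_min_gap(self, small_reference):
        gap = 100
        plan = plan_svs(
            small_reference, {c: 3 for c in SV_CLASSES},
            size_range=(50, 400), seed=9, min_gap=gap,
        )
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for ev in plan.svs:
            for iv in ev.footprints():
                by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= gap

    def test_inter_translocation_needs_two_chromosomes(self):
        one = generate_synthetic_reference([5000], seed=1)
        with pytest.raises(PlacementError):
            plan_svs(one, {"inter_translocation": 1}, size_range=(50, 200))


class TestBreakpointProximal:
    def test_zero_expected_leaves_plan_unchanged(self, small_reference):
        plan = plan_svs(small_reference, {"deletion": 2}, size_range=(50, 200),
                        seed=10)
        out = add_breakpoint_proximal_variants(plan, small_reference, 0.0)
        assert out is plan

    def test_added_variants_lie_within_window(self, small_reference):
        window = 80
        plan = plan_svs(small_reference, {"deletion": 3, "inversion": 2},
                        size_range=(400, 900), seed=11)
        out = add_breakpoint_proximal_variants(
            plan, small_reference, 3.0, window=window, seed=12
        )
        bps = [bp for ev in plan.svs for bp in ev.breakpoints()]
        added = out.snvs + out.indels
        assert added, "expected some proximal variants"
        for v in added:
            assert any(
                chrom == v.chromosome and abs(v.position - p) <= window
                for chrom, p in bps
            )

    def test_poisson_mean_of_added_count(self, small_reference):
        # 5 deletions -> 10 breakpoints; expected 2 per breakpoint -> 20
        plan = plan_svs(small_reference, {"deletion": 5},
                        size_range=(400, 900), seed=13)
        totals = []
        for seed in range(200):
            out = add_breakpoint_proximal_variants(
                plan, small_reference, 2.0, window=100, seed=seed
            )
            totals.append(len(out.snvs) + len(out.indels))
        mean = np.mean(totals)
        assert abs(mean - 20) <= 3 * np.sqrt(20 / 200)


class TestApplyBackward:
    def test_deletion(self):
        plan = VariantPlan(svs=[SVEvent("deletion", "chr1", 2, 4)])
        out, _ = apply_plan_backward("ACGTACGT", plan)
        assert out == "ACACGT"

    def test_inversion(self):
        plan = VariantPlan(svs=[SVEvent("inversion", "chr1", 1, 4)])
        out, _ = apply_plan_backward("AACGT", plan)
        assert out == "ACGTT"

    def test_tandem_duplication(self):
        plan = VariantPlan(svs=[SVEvent("tandem_duplication", "chr1", 0, 2)])
        out, _ = apply_plan_backward("ACGT", plan)
        assert out == "ACACGT"

    def test_inversion_involution(self, small_reference):
        seq = small_reference.chromosomes["chr1"][:2000]
        plan = VariantPlan(svs=[SVEvent("inversion", "chr1", 300, 1200)])
        once, _ = apply_plan_backward(seq, plan)
        twice, _ = apply_plan_backward(once, plan)
        assert twice == seq

    def test_balanced_translocation_conserves_bases(self, small_reference):
        ev = SVEvent(
            "inter_translocation", "chr1", 1000, 2000,
            dest_chromosome="chr2", dest_position=5000, balanced=True,
            haplotype=0,
        )
        plan = VariantPlan(svs=[ev])
        hs = build_haplotypes(small_reference, plan, genome_id="t")
        donor = Counter(hs.sequence("chr1", 0)) + Counter(hs.sequence("chr2", 0))
        ref = Counter(small_reference.chromosomes["chr1"]) + Counter(
            small_reference.chromosomes["chr2"]
        )
        assert donor == ref
        # net length change is zero across the genome
        assert len(hs.sequence("chr1", 0)) + len(hs.sequence("chr2", 0)) == (
            small_reference.total_length
        )

    def test_unbalanced_translocation_is_a_net_gain(self, small_reference):
        ev = SVEvent(
            "intra_translocation", "chr1", 1000, 1500,
            dest_chromosome="chr1", dest_position=5000, balanced=False,
            haplotype=0,
        )
        plan = VariantPlan(svs=[ev])
        out, _ = apply_plan_backward(
            small_reference.chromosomes["chr1"], plan, chrom="chr1"
        )
        assert len(out) == small_reference.length_of("chr1") + 500
        # the source copy is kept in place
        assert out[1000:1500] == small_reference.chromosomes["chr1"][1000:1500]

    def test_ref_mismatch_detected(self):
        plan = VariantPlan(snvs=[SNV("chr1", 0, "A", "T")])
        with pytest.raises(Exception, match="ref"):
            apply_plan_backward("CCCC", plan)


def _random_plan(reference, seed, n_sv=10, n_snv=15, n_indel=5):
    fp = FootprintIndex()
    rng = np.random.default_rng(seed)
    classes = list(SV_CLASSES)
    counts = Counter(rng.choice(classes, size=n_sv))
    plan = plan_svs(reference, dict(counts), size_range=(30, 300),
                    seed=seed, min_gap=20, footprints=fp)
    snvs = sample_snvs(reference, n_snv, seed=seed + 1, footprints=fp)
    indels = sample_indels(reference, n_indel, size_range=(1, 6),
                           seed=seed + 2, footprints=fp)
    return VariantPlan(snvs=snvs, indels=indels, svs=plan.svs, min_gap=20)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_backward_application_equals_rebuild_oracle(self, seed):
        reference = generate_synthetic_reference(
            {"chrA": 6000, "chrB": 4000}, gc_target=0.5, seed=seed
        )
        plan = _random_plan(reference, seed=1000 + seed)
        hs = build_haplotypes(reference, plan, genome_id="x")
        for chrom in reference.chromosomes:
            for hap in (0, 1):
                assert hs.sequence(chrom, hap) == rebuild_haplotype(
                    reference, plan, chrom, hap
                )

    @pytest.mark.parametrize("seed", range(10))
    def test_length_accounting(self, seed):
        reference = generate_synthetic_reference(
            {"chrA": 6000, "chrB": 4000}, gc_target=0.5, seed=seed
        )
        plan = _random_plan(reference, seed=2000 + seed)
        hs = build_haplotypes(reference, plan, genome_id="x")
        for chrom in reference.chromosomes:
            for hap in (0, 1):
                assert len(hs.sequence(chrom, hap)) == (
                    reference.length_of(chrom)
                    + expected_length_delta(plan, reference, chrom, hap)
                )


class TestTruthFidelity:
    def test_snv_donor_base_equals_alt(self, small_reference):
        plan = _random_plan(small_reference, seed=77)
        for chrom in small_reference.chromosomes:
            for hap in (0, 1):
                edits = plan_edits(plan, small_reference, chrom, hap)
                donor = apply_edits_backward(
                    small_reference.chromosomes[chrom], edits
                )
                for v in plan.snvs:
                    if v.chromosome != chrom:
                        continue
                    if v.haplotype is not None and v.haplotype != hap:
                        continue
                    dpos = donor_position(edits, v.position)
                    assert donor[dpos] == v.alt


class TestWriteTruth:
    @pytest.fixture()
    def truth_files(self, small_reference, tmp_path):
        seq = small_reference.chromosomes["chr1"]
        plan = VariantPlan(
            snvs=[SNV("chr1", 99, seq[99], "A" if seq[99] != "A" else "T")],
            svs=[
                SVEvent("deletion", "chr1", 100, 200, event_id="del1"),
                SVEvent("inter_translocation", "chr1", 1000, 1400,
                        dest_chromosome="chr2", dest_position=300,
                        event_id="tra1"),
                SVEvent("cnv", "chr1", 3000, 3500, copy_number=4,
                        dest_positions=(6000, 8000), event_id="cnv1"),
            ],
        )
        vcf, bedpe = tmp_path / "t.vcf", tmp_path / "t.bedpe"
        write_truth(plan, small_reference, vcf, bedpe)
        return vcf, bedpe

    def test_vcf_parses_and_coordinates_convert(self, truth_files):
        vcf, _ = truth_files
        records = list(pysam.VariantFile(str(vcf)))
        snv = next(r for r in records if r.alts and not r.alts[0].startswith("<"))
        assert snv.pos == 100  # 0-based 99
        dele = next(r for r in records if r.alts[0] == "<DEL>")
        assert dele.stop == 200  # END, 1-based inclusive
        assert dele.info["SVLEN"] == -100
        tra = next(r for r in records if r.alts[0] == "<BND>")
        assert tra.info["CHR2"] == "chr2"
        assert tra.info["POS2"] == 301
        cnv = next(r for r in records if r.alts[0] == "<CNV>")
        assert cnv.info["CN"] == 4

    def test_bedpe_anchors_and_interchromosomal_row(self, truth_files):
        _, bedpe = truth_files
        rows = [
            l.split("\t") for l in bedpe.read_text().splitlines()
            if not l.startswith("#")
        ]
        by_name = {r[6]: r for r in rows}
        del_row = by_name["del1"]
        assert (del_row[1], del_row[4]) == ("100", "200")
        tra_row = by_name["tra1"]
        assert tra_row[0] == "chr1" and tra_row[3] == "chr2"
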