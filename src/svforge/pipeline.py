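"""End-to-end orchestration: personal genome, tumor clones, reads, bias.

The pipeline mirrors the simulator's three-component design: (1) a
personal genome with germline variants, (2) tumor genomes with
aneuploidy and iteratively layered subclones, (3) read simulation,
mixing at the requested purity, and GC-biased subsampling. Every stage
draws its seed deterministically from the master seed, so a run is fully
reproducible and single stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from pathlib import Path

from .config import RunConfig
from .genome import (
    HaplotypeSet,
    ReferenceGenome,
    generate_synthetic_reference,
    read_fasta,
    read_repeat_regions,
    write_fasta,
)
from .gcbias import subsample_read_pairs, write_retention_report
from .reads import (
    MixtureSpec,
    ReadConfig,
    expected_pair_count,
    mix_reads,
    read_fastq_pairs,
    simulate_read_pairs,
    write_fastq,
)
from .tumor import CloneSpec, SomaticConfig, build_clone_set
from .variants import (
    FootprintIndex,
    VariantPlan,
    add_breakpoint_proximal_variants,
    plan_svs,
    sample_indels,
    sample_snvs,
    write_truth,
)

logger = logging.getLogger(__name__)

NORMAL_ID = "normal"

__all__ = [
    "run_pipeline",
    "derive_stage_seed",
    "build_personal_genome",
    "run_bias_stage",
    "hapset_from_fasta",
]


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (master seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(config: RunConfig, seed: int) -> ReferenceGenome:
    ref = config.reference
    if ref.path is not None:
        return read_fasta(ref.path)
    return generate_synthetic_reference(
        ref.synthetic.lengths, gc_target=ref.synthetic.gc, seed=seed
    )


def build_personal_genome(
    config: RunConfig, reference: ReferenceGenome, seed: int
) -> tuple[VariantPlan, FootprintIndex]:
    """Plan the germline variants of the personal genome."""
    g = config.germline
    footprints = FootprintIndex()
    repeats = None
    if g.sv.repeats_path is not None:
        repeats = read_repeat_regions(g.sv.repeats_path, g.sv.repeats_dialect)
    insertion_source = (
        read_fasta(g.sv.insertion_fasta) if g.sv.insertion_fasta else None
    )
    sv_plan = plan_svs(
        reference,
        g.sv.counts,
        size_range=g.sv.size_range,
        mechanism_mix=g.sv.p_nahr,
        repeats=repeats,
        seed=derive_stage_seed(seed, "germline_sv"),
        min_gap=g.min_gap,
        footprints=footprints,
        cnv_copy_numbers=g.sv.cnv_copy_numbers,
        insertion_source=insertion_source,
    )
    snvs = sample_snvs(
        reference, g.snv_count, het_fraction=g.het_fraction,
        source=g.snv_source, seed=derive_stage_seed(seed, "germline_snv"),
        footprints=footprints,
    )
    indels = sample_indels(
        reference, g.indel_count, size_range=g.indel_size_range,
        het_fraction=g.het_fraction, source=g.indel_source,
        seed=derive_stage_seed(seed, "germline_indel"), footprints=footprints,
    )
    plan = VariantPlan(snvs=snvs, indels=indels, svs=sv_plan.svs, min_gap=g.min_gap)
    if g.breakpoint_proximal.expected > 0:
        plan = add_breakpoint_proximal_variants(
            plan, reference, g.breakpoint_proximal.expected,
            window=g.breakpoint_proximal.window,
            seed=derive_stage_seed(seed, "germline_bpv"),
            footprints=footprints,
        )
    return plan, footprints


def _clone_specs(config: RunConfig) -> list[CloneSpec]:
    specs = []
    for c in config.tumor.clones:
        specs.append(
            CloneSpec(
                clone_id=c.id,
                parent_id=c.parent,
                proportion=c.proportion,
                somatic=SomaticConfig(
                    snv_count=c.snv_count,
                    indel_count=c.indel_count,
                    sv_class_counts=c.sv_counts,
                    het_fraction=c.het_fraction,
                    snv_source=c.snv_source,
                    sv_size_range=c.sv_size_range,
                ),
            )
        )
    return specs


def hapset_from_fasta(path: str | Path, genome_id: str) -> HaplotypeSet:
    """Rebuild a haplotype set from a FASTA written by the pipeline
    (records named ``<chrom>_hap<index>``)."""
    genome = read_fasta(path)
    copies = []
    for name, seq in genome.chromosomes.items():
        m = re.fullmatch(r"(.+)_hap(\d+)", name)
        if not m:
            raise ValueError(f"{path}: record {name!r} is not a haplotype record")
        copies.append((m.group(1), int(m.group(2)), seq))
    return HaplotypeSet(copies=copies, genome_id=genome_id)


def run_bias_stage(outdir: str | Path, config: RunConfig) -> dict:
    """Apply GC-bias to the stored pre-bias FASTQ of a finished run.

    Operates purely on files in ``outdir`` (the donor genome FASTAs and
    the pre-bias FASTQ), so re-running it reproduces the stored biased
    output byte for byte.
    """
    outdir = Path(outdir)
    if config.bias is None:
        raise ValueError("config has no bias block")
    fspec = config.bias.bias_function()
    genomes: dict[str, HaplotypeSet] = {}
    for fa in sorted((outdir / "genomes").glob("*.fa")):
        gid = fa.stem
        genomes[gid] = hapset_from_fasta(fa, gid)
    pairs = read_fastq_pairs(
        outdir / "reads_prebias_R1.fastq", outdir / "reads_prebias_R2.fastq"
    )
    kept, report = subsample_read_pairs(
        pairs, genomes, fspec, seed=derive_stage_seed(config.seed, "bias")
    )
    n = write_fastq(kept, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    write_retention_report(report, outdir / "retention.tsv")
    return {"pairs_in": len(pairs), "pairs_kept": n}


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Run the whole simulation; returns the output directory.

    Outputs: ``reference.fa``, per-genome FASTAs under ``genomes/``,
    per-genome truth VCF/BEDPE under ``truth/``, mixed paired FASTQ
    (pre- and post-bias when a bias block is present), the GC-retention
    TSV and ``manifest.json``.
    """
    t0 = time.time()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    seed = config.seed
    counts: dict[str, dict] = {}

    logger.info("stage 1: reference + personal genome")
    reference = _load_reference(config, derive_stage_seed(seed, "reference"))
    write_fasta(reference, outdir / "reference.fa")
    germline_plan, footprints = build_personal_genome(config, reference, seed)
    write_truth(
        germline_plan, reference,
        outdir / "truth" / f"{NORMAL_ID}.truth.vcf",
        outdir / "truth" / f"{NORMAL_ID}.truth.bedpe",
    )
    from .tumor import build_haplotypes

    normal_hapset = build_haplotypes(
        reference, germline_plan, genome_id=NORMAL_ID
    )
    write_fasta(normal_hapset, outdir / "genomes" / f"{NORMAL_ID}.fa")
    counts[NORMAL_ID] = germline_plan.counts()

    genomes: dict[str, HaplotypeSet] = {NORMAL_ID: normal_hapset}
    proportions: dict[str, float] = {NORMAL_ID: 1.0}
    if config.tumor is not None:
        logger.info("stage 2: tumor clones")
        clones = build_clone_set(
            reference, germline_plan, config.tumor.karyotype,
            _clone_specs(config),
            seed=derive_stage_seed(seed, "tumor"),
            normal_fraction=config.tumor.normal_fraction,
            germline_footprints=footprints,
            truth_dir=outdir / "truth",
        )
        proportions = {NORMAL_ID: config.tumor.normal_fraction}
        for node in clones:
            genomes[node.clone_id] = node.haplotype_set
            write_fasta(
                node.haplotype_set, outdir / "genomes" / f"{node.clone_id}.fa"
            )
            counts[node.clone_id] = node.full_plan().counts()
            proportions[node.clone_id] = node.proportion

    logger.info("stage 3: reads")
    rb = config.reads
    read_config = ReadConfig(
        read_length=rb.read_length, coverage=rb.coverage,
        insert_mean=rb.insert_mean, insert_sd=rb.insert_sd,
        error_rate=rb.error_rate, base_quality=rb.base_quality,
        quality_model=rb.quality_model,
    )
    active = {g: p for g, p in proportions.items() if p > 0}
    mean_g = sum(genomes[g].total_length * p for g, p in active.items())
    total_pairs = expected_pair_count(round(mean_g), read_config)
    streams = {}
    for gid in sorted(active):
        share = active[gid]
        n_g = int(total_pairs * share * 1.05) + 16  # 5% headroom
        streams[gid] = simulate_read_pairs(
            genomes[gid], read_config,
            seed=derive_stage_seed(seed, f"reads:{gid}"),
            n_pairs=n_g,
        )
    if len(active) == 1:
        (only_id,) = active
        mixed = streams[only_id][:total_pairs]
    else:
        mixed = mix_reads(
            streams, MixtureSpec(active), total_pairs,
            seed=derive_stage_seed(seed, "mix"),
        )
    prefix = "reads_prebias" if config.bias is not None else "reads"
    write_fastq(mixed, outdir / f"{prefix}_R1.fastq", outdir / f"{prefix}_R2.fastq")
    read_counts = {"total_pairs": total_pairs}

    if config.bias is not None:
        logger.info("stage 4: GC bias")
        read_counts.update(run_bias_stage(outdir, config))
        if not config.bias.keep_prebias:
            (outdir / "reads_prebias_R1.fastq").unlink()
            (outdir / "reads_prebias_R2.fastq").unlink()

    manifest = {
        "config": config.model_dump(mode="json"),
        "stage_seeds": {
            s: derive_stage_seed(seed, s)
            for s in ("reference", "germline_sv", "germline_snv",
                      "germline_indel", "tumor", "mix", "bias")
        },
        "variant_counts": counts,
        "read_counts": read_counts,
        "mixture": proportions,
        "checksums": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return outdir
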