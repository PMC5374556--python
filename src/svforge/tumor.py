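"""Tumor genome simulation: aneuploidy and heterogeneous subclones.

A tumor genome starts from the personal (germline-carrying) genome.
Aneuploidy is applied first — each chromosome gets a user-specified
integer copy number, extra copies duplicating uniformly chosen existing
haplotypes — and somatic variants are then layered on top: each subclone
inherits its progenitor's cumulative variant set and adds private ones,
so iterating the procedure produces a clone tree (linear chains emulate
stepwise clonal evolution; a star around one progenitor emulates a
cancer-stem-cell architecture).

All somatic variants are planned in reference coordinates, disjoint from
every inherited footprint along the lineage, and each clone's sequences
are rebuilt from the reference in a single backward pass over its
cumulative plan. Truth coordinates therefore stay exact for every clone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome import GenomicInterval, HaplotypeSet, ReferenceGenome
from .variants import (
    FootprintIndex,
    VariantPlan,
    apply_edits_backward,
    plan_edits,
    plan_svs,
    sample_indels,
    sample_snvs,
    write_truth,
)

logger = logging.getLogger(__name__)

PROPORTION_TOL = 1e-9

__all__ = [
    "Karyotype",
    "SomaticConfig",
    "CloneSpec",
    "CloneNode",
    "apply_karyotype",
    "realize_karyotype",
    "derive_subclone",
    "build_clone_set",
    "build_haplotypes",
]

Karyotype = Mapping[str, int]


class ConfigError(ValueError):
    """Invalid tumor configuration (karyotype, tree or proportions)."""


@dataclass
class SomaticConfig:
    """Counts and sources for one clone's private somatic variants.

    Somatic small variants are heterozygous-like by default (placed on a
    single uniformly chosen haplotype copy); ``snv_source`` may point at
    a COSMIC-style VCF to sample positions and alleles from.
    """

    snv_count: int = 0
    indel_count: int = 0
    sv_class_counts: Mapping[str, int] = field(default_factory=dict)
    het_fraction: float = 1.0
    snv_source: str = "random"
    indel_source: str = "random"
    sv_size_range: tuple[int, int] = (100, 10_000)
    indel_size_range: tuple[int, int] = (1, 10)
    mechanism_mix: float = 0.0
    repeats: Sequence[GenomicInterval] | None = None
    cnv_copy_numbers: Sequence[int] = (0, 1, 3, 4, 5, 6)
    breakpoint_proximal_expected: float = 0.0
    breakpoint_window: int = 100

    @property
    def total_count(self) -> int:
        return self.snv_count + self.indel_count + sum(
            self.sv_class_counts.values()
        )


@dataclass
class CloneSpec:
    """One node of the user-specified clone tree."""

    clone_id: str
    parent_id: str | None
    somatic: SomaticConfig
    proportion: float


@dataclass
class CloneNode:
    """A simulated clone: genome, cumulative variants and mixture share."""

    clone_id: str
    parent_id: str | None
    proportion: float
    reference: ReferenceGenome
    germline_plan: VariantPlan
    karyotype_realization: dict[str, list[int]]
    cumulative_somatic: VariantPlan
    private_somatic: VariantPlan
    footprints: FootprintIndex
    haplotype_set: HaplotypeSet

    def full_plan(self) -> VariantPlan:
        """Germline plus cumulative somatic variants, reference frame."""
        return self.germline_plan.merged_with(self.cumulative_somatic)

    def copy_numbers(self) -> dict[str, int]:
        return {c: len(h) for c, h in self.karyotype_realization.items()}


def realize_karyotype(
    genome: ReferenceGenome,
    karyotype: Karyotype,
    seed: int = 0,
    base_ploidy: int = 2,
) -> dict[str, list[int]]:
    """Map each chromosome to the list of source haplotype indices of its
    copies after aneuploidy.

    A chromosome with copy number k > base ploidy gains extra copies that
    duplicate uniformly chosen existing haplotypes; k < base ploidy drops
    uniformly chosen copies. Chromosomes absent from ``karyotype`` stay
    at base ploidy.
    """
    for name, k in karyotype.items():
        if name not in genome.chromosomes:
            raise ConfigError(f"karyotype names unknown chromosome {name!r}")
        if k < 0:
            raise ConfigError(f"karyotype copy number for {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    realization: dict[str, list[int]] = {}
    for name in genome.chromosomes:
        sources = list(range(base_ploidy))
        k = int(karyotype.get(name, base_ploidy))
        while len(sources) > k:
            sources.pop(int(rng.integers(len(sources))))
        while len(sources) < k:
            sources.append(sources[int(rng.integers(len(sources)))])
        realization[name] = sources
    return realization


def apply_karyotype(
    haplotype_set: HaplotypeSet, karyotype: Karyotype, seed: int = 0
) -> HaplotypeSet:
    """Apply a karyotype directly to a haplotype set.

    Copies are re-indexed 0..k-1 per chromosome; a chromosome with copy
    number 0 disappears from the output.
    """
    by_chrom: dict[str, list[str]] = {}
    for chrom, _, seq in haplotype_set.copies:
        by_chrom.setdefault(chrom, []).append(seq)
    for name in karyotype:
        if name not in by_chrom:
            raise ConfigError(f"karyotype names unknown chromosome {name!r}")
    rng = np.random.default_rng(seed)
    copies: list[tuple[str, int, str]] = []
    for chrom, seqs in by_chrom.items():
        k = int(karyotype.get(chrom, len(seqs)))
        if k < 0:
            raise ConfigError(f"copy number for {chrom!r} must be >= 0")
        pool = list(seqs)
        while len(pool) > k:
            pool.pop(int(rng.integers(len(pool))))
        while len(pool) < k:
            pool.append(pool[int(rng.integers(len(pool)))])
        for i, seq in enumerate(pool):
            copies.append((chrom, i, seq))
    return HaplotypeSet(copies=copies, genome_id=haplotype_set.genome_id)


def build_haplotypes(
    reference: ReferenceGenome,
    germline_plan: VariantPlan,
    somatic_plan: VariantPlan | None = None,
    karyotype_realization: Mapping[str, Sequence[int]] | None = None,
    genome_id: str = "genome",
) -> HaplotypeSet:
    """Rebuild a genome's haplotype sequences from the reference.

    For copy i of a chromosome (sourced from germline haplotype h by the
    karyotype realization), the germline edits of haplotype h and the
    somatic edits of copy i are applied together in one backward pass.
    """
    empty = VariantPlan()
    somatic_plan = somatic_plan or empty
    copies: list[tuple[str, int, str]] = []
    for chrom, refseq in reference.chromosomes.items():
        if karyotype_realization is None:
            sources: Sequence[int] = (0, 1)
        else:
            sources = karyotype_realization.get(chrom, (0, 1))
        for copy_idx, src_hap in enumerate(sources):
            edits = plan_edits(germline_plan, reference, chrom, src_hap)
            edits += plan_edits(somatic_plan, reference, chrom, copy_idx)
            copies.append((chrom, copy_idx, apply_edits_backward(refseq, edits)))
    return HaplotypeSet(copies=copies, genome_id=genome_id)


def _reassign_copy_haplotypes(variants, copy_counts: Mapping[str, int], rng):
    """Redraw het haplotype indices uniformly over the actual copy count
    of each variant's chromosome (aneuploid chromosomes can exceed 2)."""
    from dataclasses import replace

    out = []
    for v in variants:
        if v.haplotype is None:
            out.append(v)
            continue
        k = copy_counts.get(v.chromosome, 2)
        out.append(replace(v, haplotype=int(rng.integers(max(k, 1)))))
    return out


def derive_subclone(
    progenitor: CloneNode,
    somatic_config: SomaticConfig,
    seed: int = 0,
    clone_id: str = "subclone",
    proportion: float = 0.0,
) -> CloneNode:
    """Derive a child clone by layering private somatic variants.

    The child's cumulative set is the progenitor's cumulative set plus
    the newly placed private variants, which avoid every inherited
    footprint; sequences are rebuilt from the reference.
    """
    rng = np.random.default_rng(seed)
    footprints = progenitor.footprints.copy()
    reference = progenitor.reference
    copy_counts = progenitor.copy_numbers()
    origin = f"somatic:{clone_id}"

    sv_plan = plan_svs(
        reference,
        somatic_config.sv_class_counts,
        size_range=somatic_config.sv_size_range,
        mechanism_mix=somatic_config.mechanism_mix,
        repeats=somatic_config.repeats,
        seed=int(rng.integers(2**31)),
        min_gap=progenitor.germline_plan.min_gap,
        footprints=footprints,
        origin=origin,
        cnv_copy_numbers=somatic_config.cnv_copy_numbers,
    )
    snvs = sample_snvs(
        reference,
        somatic_config.snv_count,
        het_fraction=somatic_config.het_fraction,
        source=somatic_config.snv_source,
        seed=int(rng.integers(2**31)),
        footprints=footprints,
        origin=origin,
    )
    indels = sample_indels(
        reference,
        somatic_config.indel_count,
        size_range=somatic_config.indel_size_range,
        het_fraction=somatic_config.het_fraction,
        source=somatic_config.indel_source,
        seed=int(rng.integers(2**31)),
        footprints=footprints,
        origin=origin,
    )
    private = VariantPlan(
        snvs=snvs, indels=indels, svs=sv_plan.svs,
        min_gap=progenitor.germline_plan.min_gap,
    )
    if somatic_config.breakpoint_proximal_expected > 0:
        from .variants import add_breakpoint_proximal_variants

        private = add_breakpoint_proximal_variants(
            private, reference,
            somatic_config.breakpoint_proximal_expected,
            window=somatic_config.breakpoint_window,
            seed=int(rng.integers(2**31)),
            footprints=footprints,
        )
    # het variants live on one uniformly chosen copy of the (possibly
    # aneuploid) chromosome
    reassign_rng = np.random.default_rng(int(rng.integers(2**31)))
    private = VariantPlan(
        snvs=_reassign_copy_haplotypes(private.snvs, copy_counts, reassign_rng),
        indels=_reassign_copy_haplotypes(private.indels, copy_counts, reassign_rng),
        svs=_reassign_copy_haplotypes(private.svs, copy_counts, reassign_rng),
        min_gap=private.min_gap,
    )
    cumulative = progenitor.cumulative_somatic.merged_with(private)
    hapset = build_haplotypes(
        reference,
        progenitor.germline_plan,
        cumulative,
        progenitor.karyotype_realization,
        genome_id=clone_id,
    )
    return CloneNode(
        clone_id=clone_id,
        parent_id=progenitor.clone_id,
        proportion=proportion,
        reference=reference,
        germline_plan=progenitor.germline_plan,
        karyotype_realization=progenitor.karyotype_realization,
        cumulative_somatic=cumulative,
        private_somatic=private,
        footprints=footprints,
        haplotype_set=hapset,
    )


def _topological_order(specs: Sequence[CloneSpec]) -> list[CloneSpec]:
    by_id = {s.clone_id: s for s in specs}
    if len(by_id) != len(specs):
        raise ConfigError("duplicate clone ids in tree")
    ordered: list[CloneSpec] = []
    state: dict[str, int] = {}

    def visit(s: CloneSpec) -> None:
        if state.get(s.clone_id) == 1:
            raise ConfigError(f"cycle in clone tree at {s.clone_id!r}")
        if state.get(s.clone_id) == 2:
            return
        state[s.clone_id] = 1
        if s.parent_id is not None:
            if s.parent_id not in by_id:
                raise ConfigError(
                    f"clone {s.clone_id!r} has unknown parent {s.parent_id!r}"
                )
            visit(by_id[s.parent_id])
        state[s.clone_id] = 2
        ordered.append(s)

    for s in specs:
        visit(s)
    return ordered


def build_clone_set(
    reference: ReferenceGenome,
    germline_plan: VariantPlan,
    karyotype: Karyotype,
    tree_spec: Sequence[CloneSpec],
    seed: int = 0,
    normal_fraction: float = 0.0,
    germline_footprints: FootprintIndex | None = None,
    truth_dir: str | Path | None = None,
) -> list[CloneNode]:
    """Generate all clones of a tree in topological order.

    Root clones (no parent) start from the personal genome with the
    shared karyotype applied; every child derives from its parent via
    :func:`derive_subclone`. Clone proportions plus ``normal_fraction``
    must sum to 1 (purity is the summed proportion of tumor clones).
    If ``truth_dir`` is given, a truth VCF/BEDPE pair is written per
    clone, named by clone id.
    """
    if not tree_spec:
        raise ConfigError("tree_spec must list at least one clone")
    total = normal_fraction + sum(s.proportion for s in tree_spec)
    if any(s.proportion < 0 for s in tree_spec) or normal_fraction < 0:
        raise ConfigError("proportions must be non-negative")
    if abs(total - 1.0) > PROPORTION_TOL:
        raise ConfigError(
            f"clone proportions plus normal fraction sum to {total}, expected 1"
        )
    ordered = _topological_order(tree_spec)
    rng = np.random.default_rng(seed)
    karyo_real = realize_karyotype(
        reference, karyotype, seed=int(rng.integers(2**31))
    )
    if germline_footprints is None:
        germline_footprints = FootprintIndex()
        for v in germline_plan.sorted_variants():
            germline_footprints.add_variant(v)

    nodes: dict[str, CloneNode] = {}
    for spec in ordered:
        if spec.parent_id is None:
            base = CloneNode(
                clone_id="__personal__",
                parent_id=None,
                proportion=0.0,
                reference=reference,
                germline_plan=germline_plan,
                karyotype_realization=karyo_real,
                cumulative_somatic=VariantPlan(min_gap=germline_plan.min_gap),
                private_somatic=VariantPlan(min_gap=germline_plan.min_gap),
                footprints=germline_footprints,
                haplotype_set=HaplotypeSet(copies=[("_", 0, "A")]),
            )
        else:
            base = nodes[spec.parent_id]
        node = derive_subclone(
            base,
            spec.somatic,
            seed=int(rng.integers(2**31)),
            clone_id=spec.clone_id,
            proportion=spec.proportion,
        )
        node.parent_id = spec.parent_id
        nodes[spec.clone_id] = node
    result = [nodes[s.clone_id] for s in ordered]
    if truth_dir is not None:
        truth_dir = Path(truth_dir)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for node in result:
            write_truth(
                node.full_plan(), reference,
                truth_dir / f"{node.clone_id}.truth.vcf",
                truth_dir / f"{node.clone_id}.truth.bedpe",
            )
    return result
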