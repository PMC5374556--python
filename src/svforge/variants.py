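"""Plan and apply germline/somatic small variants and structural variants.

Variants are planned in *reference* coordinates and kept pairwise
non-overlapping (structural-event footprints additionally respect a
minimum gap), so a whole plan can be applied to a haplotype in a single
backward pass — from the highest coordinate to the lowest — without any
coordinate bookkeeping: every edit below an applied edit still refers to
valid positions. This is what keeps the emitted truth coordinates exact.

Seven structural-variant classes are supported: deletion, insertion,
tandem duplication, inversion, intra- and inter-chromosomal translocation,
and CNV (copy-number 0-6 against a diploid baseline). Breakpoints are
placed by mechanism: NAHR draws them uniformly from bases covered by
repeat annotations, NHR uniformly from the whole chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import (
    GenomicInterval,
    ReferenceGenome,
    gc_fraction,
    reverse_complement,
)

logger = logging.getLogger(__name__)

SV_CLASSES = (
    "deletion",
    "insertion",
    "tandem_duplication",
    "inversion",
    "intra_translocation",
    "inter_translocation",
    "cnv",
)

# deterministic tie-break order when sorting variants at equal positions
_CLASS_ORDER = {name: i for i, name in enumerate(("snv", "indel") + SV_CLASSES)}

DEFAULT_MIN_GAP = 100
DEFAULT_MAX_RETRIES = 1000


class CapacityError(RuntimeError):
    """Requested more variants than the genome / source can accommodate."""


class PlacementError(RuntimeError):
    """Could not place an event without overlap within the retry budget."""


class IntegrityError(RuntimeError):
    """A planned variant's REF does not match the genome it is applied to."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide variant in reference coordinates (0-based).

    ``haplotype`` is the copy index carrying the variant; ``None`` means
    all copies (homozygous).
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    zygosity: str = "het"
    origin: str = "germline"
    haplotype: int | None = 0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("SNV ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SNV alleles must be single bases")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class Indel:
    """A VCF-style left-anchored insertion or deletion.

    Exactly one of ref/alt has length 1; ``position`` is the 0-based
    position of the anchor base.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    zygosity: str = "het"
    origin: str = "germline"
    haplotype: int | None = 0

    def __post_init__(self) -> None:
        if (len(self.ref) == 1) == (len(self.alt) == 1):
            raise ValueError("indel must be a pure insertion or deletion")
        if self.ref[0] != self.alt[0]:
            raise ValueError("indel alleles must share the anchor base")

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > 1


@dataclass(frozen=True)
class SVEvent:
    """One structural-variant event in reference coordinates.

    ``start``/``end`` delimit the source segment (for insertions the
    insertion point, with ``end == start``). Translocations carry a
    destination; CNV gains carry one destination per extra copy.
    ``haplotype`` follows the same convention as :class:`SNV`.
    """

    sv_class: str
    chromosome: str
    start: int
    end: int
    mechanism: str = "NHR"
    origin: str = "germline"
    haplotype: int | None = 0
    dest_chromosome: str | None = None
    dest_position: int | None = None
    dest_positions: tuple[int, ...] = ()
    inserted_seq: str = ""
    balanced: bool = True
    copy_number: int | None = None
    extra_copies: int = 1
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}")
        if self.mechanism not in ("NAHR", "NHR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.sv_class == "insertion":
            if self.end != self.start or not self.inserted_seq:
                raise ValueError("insertion needs end == start and a sequence")
        elif self.start >= self.end:
            raise ValueError("source interval must be non-empty")
        if self.sv_class in ("intra_translocation", "inter_translocation"):
            if self.dest_chromosome is None or self.dest_position is None:
                raise ValueError("translocation needs a destination")
            if self.sv_class == "intra_translocation":
                if self.dest_chromosome != self.chromosome:
                    raise ValueError("intra-translocation must stay on chromosome")
            elif self.dest_chromosome == self.chromosome:
                raise ValueError("inter-translocation needs another chromosome")
        if self.sv_class == "cnv":
            if self.copy_number is None or self.copy_number < 0:
                raise ValueError("CNV needs copy_number >= 0")
            if self.copy_number > 2 and len(self.dest_positions) != self.copy_number - 2:
                raise ValueError("CNV gain needs one destination per extra copy")
        if self.sv_class == "tandem_duplication" and self.extra_copies < 1:
            raise ValueError("tandem duplication needs extra_copies >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start

    def footprints(self) -> list[GenomicInterval]:
        """Reference intervals this event occupies (source + destinations)."""
        out: list[GenomicInterval] = []
        if self.sv_class == "insertion":
            out.append(GenomicInterval(self.chromosome, self.start, self.start + 1))
        else:
            out.append(GenomicInterval(self.chromosome, self.start, self.end))
        if self.dest_position is not None:
            out.append(
                GenomicInterval(self.dest_chromosome, self.dest_position,
                                self.dest_position + 1)
            )
        for p in self.dest_positions:
            out.append(GenomicInterval(self.chromosome, p, p + 1))
        return out

    def breakpoints(self) -> list[tuple[str, int]]:
        """All breakpoint coordinates of this event."""
        if self.sv_class == "insertion":
            bps = [(self.chromosome, self.start)]
        else:
            bps = [(self.chromosome, self.start), (self.chromosome, self.end)]
        if self.dest_position is not None:
            bps.append((self.dest_chromosome, self.dest_position))
        bps.extend((self.chromosome, p) for p in self.dest_positions)
        return bps


Variant = SNV | Indel | SVEvent


def _variant_sort_key(v: Variant) -> tuple:
    if isinstance(v, SNV):
        return (v.chromosome, v.position, _CLASS_ORDER["snv"])
    if isinstance(v, Indel):
        return (v.chromosome, v.position, _CLASS_ORDER["indel"])
    return (v.chromosome, v.start, _CLASS_ORDER[v.sv_class])


@dataclass
class VariantPlan:
    """An ordered, non-overlapping set of variants against one genome."""

    snvs: list[SNV] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)
    svs: list[SVEvent] = field(default_factory=list)
    min_gap: int = DEFAULT_MIN_GAP

    def sorted_variants(self) -> list[Variant]:
        return sorted(
            [*self.snvs, *self.indels, *self.svs], key=_variant_sort_key
        )

    def merged_with(self, other: "VariantPlan") -> "VariantPlan":
        return VariantPlan(
            snvs=[*self.snvs, *other.snvs],
            indels=[*self.indels, *other.indels],
            svs=[*self.svs, *other.svs],
            min_gap=self.min_gap,
        )

    def counts(self) -> dict[str, int]:
        out = {"snv": len(self.snvs), "indel": len(self.indels)}
        for cls in SV_CLASSES:
            out[cls] = sum(1 for e in self.svs if e.sv_class == cls)
        return out


class FootprintIndex:
    """Per-chromosome interval index used to keep placements disjoint."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def copy(self) -> "FootprintIndex":
        new = FootprintIndex()
        new._trees = {c: t.copy() for c, t in self._trees.items()}
        return new

    def add(self, chrom: str, start: int, end: int) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def add_variant(self, v: Variant) -> None:
        if isinstance(v, SNV):
            self.add(v.chromosome, v.position, v.position + 1)
        elif isinstance(v, Indel):
            self.add(v.chromosome, v.position, v.position + len(v.ref))
        else:
            for iv in v.footprints():
                self.add(iv.chromosome, iv.start, iv.end)

    def conflicts(self, chrom: str, start: int, end: int, pad: int = 0) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(max(0, start - pad), end + pad))


# ---------------------------------------------------------------------------
# small-variant sampling

_BASES = "ACGT"
_ALT_CHOICES = {b: _BASES.replace(b, "") for b in _BASES}


def _assign_zygosity(
    variants: list, n_het: int, ploidy: int, rng: np.random.Generator
) -> list:
    """Mark the first ``n_het`` (after shuffling) as het on one uniformly
    chosen haplotype, the rest as hom on all copies."""
    order = rng.permutation(len(variants))
    out = [None] * len(variants)
    for rank, idx in enumerate(order):
        v = variants[idx]
        if rank < n_het:
            out[idx] = replace(v, zygosity="het",
                               haplotype=int(rng.integers(ploidy)))
        else:
            out[idx] = replace(v, zygosity="hom", haplotype=None)
    return out


def _position_sampler(genome: ReferenceGenome, rng: np.random.Generator):
    """Uniform sampler over all genome coordinates, returned as
    (chromosome, position) pairs."""
    names = list(genome.chromosomes)
    lengths = np.array([genome.length_of(n) for n in names], dtype=np.int64)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    total = int(bounds[-1])

    def draw(k: int) -> list[tuple[str, int]]:
        flat = rng.integers(0, total, size=k)
        idx = np.searchsorted(bounds, flat, side="right") - 1
        return [(names[i], int(p - bounds[i])) for i, p in zip(idx, flat)]

    return draw, total


def _random_distinct_positions(
    genome: ReferenceGenome,
    n: int,
    rng: np.random.Generator,
    footprints: FootprintIndex | None,
    margin: int = 0,
) -> list[tuple[str, int]]:
    """Sample n distinct (chrom, pos) avoiding N bases and footprints.

    ``margin`` keeps positions at least that many bases from the
    chromosome end (room for anchored deletion alleles).
    """
    draw, total = _position_sampler(genome, rng)
    if n > total:
        raise CapacityError(f"requested {n} positions, genome has {total} bases")
    chosen: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 1000:
            raise CapacityError(
                f"could not find {n} free positions (found {len(chosen)})"
            )
        for chrom, pos in draw(max(1024, 2 * (n - len(chosen)))):
            if (chrom, pos) in seen:
                continue
            if pos + margin >= genome.length_of(chrom):
                continue
            if genome.chromosomes[chrom][pos] == "N":
                continue
            if footprints is not None and footprints.conflicts(
                chrom, pos, pos + margin + 1
            ):
                continue
            seen.add((chrom, pos))
            chosen.append((chrom, pos))
            if len(chosen) == n:
                break
    return chosen


def _load_vcf_records(path: str | Path, genome: ReferenceGenome, kind: str):
    """Collect usable (chrom, pos0, ref, alt) tuples from a VCF.

    Only records whose REF matches the genome are kept; ``kind`` selects
    SNVs or pure indels.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.chrom not in genome.chromosomes or not rec.alts:
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            pos0 = rec.pos - 1
            if kind == "snv":
                if len(ref) != 1 or len(alt) != 1 or ref == alt:
                    continue
            else:
                if (len(ref) == 1) == (len(alt) == 1):
                    continue
                if ref[0] != alt[0]:
                    continue
            if genome.chromosomes[rec.chrom][pos0:pos0 + len(ref)] != ref:
                continue
            out.append((rec.chrom, pos0, ref, alt))
    return out


def sample_snvs(
    genome: ReferenceGenome,
    n: int,
    het_fraction: float = 0.5,
    source: str | Path = "random",
    seed: int = 0,
    footprints: FootprintIndex | None = None,
    origin: str = "germline",
    ploidy: int = 2,
) -> list[SNV]:
    """Sample ``n`` SNVs at distinct positions.

    With ``source="random"`` positions are uniform over non-N bases and
    the alternate base is uniform over the three others; with a VCF path
    the (position, ref, alt) triples are drawn without replacement from
    records whose REF matches the genome. Exactly ``round(n *
    het_fraction)`` variants are heterozygous (assigned to one uniformly
    chosen haplotype); the rest are homozygous.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    out: list[SNV] = []
    if source == "random":
        for chrom, pos in _random_distinct_positions(genome, n, rng, footprints):
            ref = genome.chromosomes[chrom][pos]
            alt = _ALT_CHOICES[ref][rng.integers(3)]
            out.append(SNV(chrom, pos, ref, alt, origin=origin))
    else:
        records = [
            r for r in _load_vcf_records(source, genome, "snv")
            if footprints is None
            or not footprints.conflicts(r[0], r[1], r[1] + 1)
        ]
        # one SNV per position at most
        records = list({(c, p): (c, p, r, a) for c, p, r, a in records}.values())
        if n > len(records):
            raise CapacityError(
                f"VCF source provides {len(records)} usable SNVs, need {n}"
            )
        idx = rng.choice(len(records), size=n, replace=False)
        for i in idx:
            chrom, pos, ref, alt = records[i]
            out.append(SNV(chrom, pos, ref, alt, origin=origin))
    n_het = round(n * het_fraction)
    out = _assign_zygosity(out, n_het, ploidy, rng)
    if footprints is not None:
        for v in out:
            footprints.add_variant(v)
    return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def sample_indels(
    genome: ReferenceGenome,
    n: int,
    size_range: tuple[int, int] = (1, 10),
    het_fraction: float = 0.5,
    source: str | Path = "random",
    seed: int = 0,
    footprints: FootprintIndex | None = None,
    origin: str = "germline",
    ploidy: int = 2,
) -> list[Indel]:
    """Sample ``n`` left-anchored indels.

    Insertion vs deletion is chosen with probability 1/2 each and lengths
    are uniform on ``size_range``; with a VCF source, records are drawn
    without replacement instead.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must satisfy 1 <= min <= max")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    out: list[Indel] = []
    if source == "random":
        positions = _random_distinct_positions(
            genome, n, rng, footprints, margin=hi
        )
        for chrom, pos in positions:
            length = int(rng.integers(lo, hi + 1))
            seq = genome.chromosomes[chrom]
            if rng.random() < 0.5 and "N" not in seq[pos:pos + length + 1]:
                ref = seq[pos:pos + length + 1]         # deletion
                alt = seq[pos]
            else:
                ref = seq[pos]                           # insertion
                alt = ref + _random_seq(rng, length)
            out.append(Indel(chrom, pos, ref, alt, origin=origin))
    else:
        records = [
            r for r in _load_vcf_records(source, genome, "indel")
            if footprints is None
            or not footprints.conflicts(r[0], r[1], r[1] + len(r[2]))
        ]
        records = list({(c, p): (c, p, r, a) for c, p, r, a in records}.values())
        if n > len(records):
            raise CapacityError(
                f"VCF source provides {len(records)} usable indels, need {n}"
            )
        idx = rng.choice(len(records), size=n, replace=False)
        for i in idx:
            chrom, pos, ref, alt = records[i]
            out.append(Indel(chrom, pos, ref, alt, origin=origin))
    n_het = round(n * het_fraction)
    out = _assign_zygosity(out, n_het, ploidy, rng)
    if footprints is not None:
        for v in out:
            footprints.add_variant(v)
    return out


# ---------------------------------------------------------------------------
# SV planning


class _RepeatSampler:
    """Uniform sampler over bases covered by repeat intervals."""

    def __init__(self, repeats: Sequence[GenomicInterval], chroms: Iterable[str]):
        chromset = set(chroms)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in repeats:
            if iv.chromosome in chromset:
                by_chrom.setdefault(iv.chromosome, []).append(iv)
        self.by_chrom = {c: sorted(ivs) for c, ivs in by_chrom.items()}
        self._starts: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for c, ivs in self.by_chrom.items():
            lengths = np.array([len(iv) for iv in ivs], dtype=np.int64)
            self._starts[c] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._cum[c] = np.concatenate([[0], np.cumsum(lengths)])
        self.total = sum(int(self._cum[c][-1]) for c in self.by_chrom)
        if self.total == 0:
            raise PlacementError("repeat annotation covers no bases")
        self._chrom_names = list(self.by_chrom)
        weights = np.array(
            [self._cum[c][-1] for c in self._chrom_names], dtype=float
        )
        self._chrom_probs = weights / weights.sum()

    def draw_base(self, rng: np.random.Generator, chrom: str | None = None):
        """One uniformly chosen repeat-covered base, optionally on a
        fixed chromosome; returns (chrom, pos) or None."""
        if chrom is None:
            chrom = self._chrom_names[
                rng.choice(len(self._chrom_names), p=self._chrom_probs)
            ]
        cum = self._cum.get(chrom)
        if cum is None or cum[-1] == 0:
            return None
        flat = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, flat, side="right")) - 1
        return chrom, int(self._starts[chrom][i] + (flat - cum[i]))

    def draw_base_in_window(
        self, rng: np.random.Generator, chrom: str, lo: int, hi: int
    ) -> int | None:
        """One uniformly chosen repeat-covered base in [lo, hi) on chrom."""
        ivs = self.by_chrom.get(chrom, [])
        pieces = [
            (max(iv.start, lo), min(iv.end, hi))
            for iv in ivs
            if iv.start < hi and iv.end > lo
        ]
        pieces = [(s, e) for s, e in pieces if s < e]
        if not pieces:
            return None
        lengths = np.array([e - s for s, e in pieces], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(lengths)])
        flat = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, flat, side="right")) - 1
        return int(pieces[i][0] + (flat - cum[i]))


def _weighted_chrom(genome: ReferenceGenome, rng: np.random.Generator) -> str:
    names = list(genome.chromosomes)
    lengths = np.array([genome.length_of(n) for n in names], dtype=float)
    return names[rng.choice(len(names), p=lengths / lengths.sum())]


def plan_svs(
    genome: ReferenceGenome,
    class_counts: Mapping[str, int],
    size_range: tuple[int, int] = (100, 10_000),
    mechanism_mix: float = 0.0,
    repeats: Sequence[GenomicInterval] | None = None,
    seed: int = 0,
    min_gap: int = DEFAULT_MIN_GAP,
    max_retries: int = DEFAULT_MAX_RETRIES,
    footprints: FootprintIndex | None = None,
    origin: str = "germline",
    ploidy: int = 2,
    cnv_copy_numbers: Sequence[int] = (0, 1, 3, 4, 5, 6),
    insertion_source: ReferenceGenome | None = None,
) -> VariantPlan:
    """Plan structural variants of the requested classes.

    ``mechanism_mix`` is the probability that an event is NAHR-mediated,
    in which case all of its breakpoints are drawn uniformly from bases
    covered by ``repeats``; NHR breakpoints are uniform over the
    chromosome. Event footprints (source segments and destination
    points) are kept pairwise disjoint with at least ``min_gap`` bases
    between them; placement of an event is retried up to ``max_retries``
    times before a :class:`PlacementError` is raised.

    CNV events draw their copy number uniformly from
    ``cnv_copy_numbers`` (diploid baseline 2 excluded by default); a gain
    of copy number k places k-2 extra copies at sampled positions on the
    same chromosome. Insertion payloads come from ``insertion_source``
    (a FASTA of known insertion sequences) when given, otherwise they are
    i.i.d. random bases with length uniform on ``size_range``.
    """
    for cls, cnt in class_counts.items():
        if cls not in SV_CLASSES:
            raise ValueError(f"unknown SV class {cls!r}")
        if cnt < 0:
            raise ValueError(f"negative count for {cls!r}")
    if not 0.0 <= mechanism_mix <= 1.0:
        raise ValueError("mechanism_mix must be a probability")
    if mechanism_mix > 0 and not repeats:
        raise PlacementError("NAHR requested but no repeat intervals supplied")
    if "inter_translocation" in class_counts and class_counts[
        "inter_translocation"
    ] > 0 and len(genome) < 2:
        raise PlacementError("inter-chromosomal translocation needs >= 2 chromosomes")

    rng = np.random.default_rng(seed)
    if footprints is None:
        footprints = FootprintIndex()
    repeat_sampler = (
        _RepeatSampler(repeats, genome.chromosomes) if repeats else None
    )
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must satisfy 1 <= min <= max")

    events: list[SVEvent] = []
    serial = 0

    def free(chrom: str, start: int, end: int) -> bool:
        return not footprints.conflicts(chrom, start, end, pad=min_gap)

    def sample_interval(nahr: bool) -> tuple[str, int, int] | None:
        """One source interval with both breakpoints honouring mechanism."""
        if nahr:
            drawn = repeat_sampler.draw_base(rng)
            if drawn is None:
                return None
            chrom, start = drawn
            end = repeat_sampler.draw_base_in_window(
                rng, chrom, start + lo, min(start + hi + 1, genome.length_of(chrom))
            )
            if end is None:
                return None
        else:
            chrom = _weighted_chrom(genome, rng)
            clen = genome.length_of(chrom)
            if clen <= lo + 1:
                return None
            start = int(rng.integers(0, clen - lo))
            end = start + int(rng.integers(lo, min(hi, clen - 1 - start) + 1))
        if end >= genome.length_of(chrom):
            return None
        if "N" in genome.chromosomes[chrom][start:end]:
            return None
        return chrom, start, end

    def sample_point(nahr: bool, chrom: str | None = None) -> tuple[str, int] | None:
        if nahr:
            return repeat_sampler.draw_base(rng, chrom)
        if chrom is None:
            chrom = _weighted_chrom(genome, rng)
        return chrom, int(rng.integers(1, genome.length_of(chrom) - 1))

    def place(cls: str) -> SVEvent:
        nonlocal serial
        for _ in range(max_retries):
            nahr = bool(rng.random() < mechanism_mix)
            mech = "NAHR" if nahr else "NHR"
            hap = int(rng.integers(ploidy))
            if cls == "insertion":
                drawn = sample_point(nahr)
                if drawn is None:
                    continue
                chrom, pos = drawn
                if insertion_source is not None:
                    donor_names = list(insertion_source.chromosomes)
                    seq = insertion_source.chromosomes[
                        donor_names[rng.integers(len(donor_names))]
                    ]
                    if len(seq) > hi:
                        off = int(rng.integers(0, len(seq) - hi + 1))
                        seq = seq[off:off + int(rng.integers(lo, hi + 1))]
                else:
                    seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if not seq or not free(chrom, pos, pos + 1):
                    continue
                ev = SVEvent(cls, chrom, pos, pos, mechanism=mech, origin=origin,
                             haplotype=hap, inserted_seq=seq,
                             event_id=f"{origin}_{cls}_{serial}")
            elif cls in ("deletion", "inversion", "tandem_duplication"):
                ivl = sample_interval(nahr)
                if ivl is None:
                    continue
                chrom, start, end = ivl
                if not free(chrom, start, end):
                    continue
                ev = SVEvent(cls, chrom, start, end, mechanism=mech,
                             origin=origin, haplotype=hap,
                             event_id=f"{origin}_{cls}_{serial}")
            elif cls in ("intra_translocation", "inter_translocation"):
                ivl = sample_interval(nahr)
                if ivl is None:
                    continue
                chrom, start, end = ivl
                if cls == "intra_translocation":
                    dest = sample_point(nahr, chrom)
                else:
                    others = [c for c in genome.chromosomes if c != chrom]
                    dest_chrom = others[rng.integers(len(others))]
                    dest = sample_point(nahr, dest_chrom)
                    if dest is not None and dest[0] == chrom:
                        continue
                if dest is None:
                    continue
                dchrom, dpos = dest
                balanced = bool(rng.random() < 0.5)
                if not free(chrom, start, end) or not free(dchrom, dpos, dpos + 1):
                    continue
                # destination may not fall inside the source segment
                if dchrom == chrom and start - min_gap <= dpos < end + min_gap:
                    continue
                ev = SVEvent(cls, chrom, start, end, mechanism=mech,
                             origin=origin, haplotype=hap,
                             dest_chromosome=dchrom, dest_position=dpos,
                             balanced=balanced,
                             event_id=f"{origin}_{cls}_{serial}")
            elif cls == "cnv":
                ivl = sample_interval(nahr)
                if ivl is None:
                    continue
                chrom, start, end = ivl
                if not free(chrom, start, end):
                    continue
                cn = int(rng.choice(list(cnv_copy_numbers)))
                dests: list[int] = []
                if cn > 2:
                    ok = True
                    for _ in range(cn - 2):
                        drawn = sample_point(nahr, chrom)
                        if drawn is None:
                            ok = False
                            break
                        _, dpos = drawn
                        if not free(chrom, dpos, dpos + 1) or any(
                            abs(dpos - q) <= min_gap for q in dests
                        ) or start - min_gap <= dpos < end + min_gap:
                            ok = False
                            break
                        dests.append(dpos)
                    if not ok:
                        continue
                ev = SVEvent(cls, chrom, start, end, mechanism=mech,
                             origin=origin,
                             haplotype=None if cn == 0 else int(rng.integers(ploidy)),
                             dest_positions=tuple(sorted(dests)),
                             copy_number=cn,
                             event_id=f"{origin}_{cls}_{serial}")
            else:  # pragma: no cover
                raise AssertionError(cls)
            footprints.add_variant(ev)
            serial += 1
            return ev
        raise PlacementError(
            f"could not place a {cls} event after {max_retries} retries"
        )

    for cls in SV_CLASSES:  # fixed class order for determinism
        for _ in range(int(class_counts.get(cls, 0))):
            events.append(place(cls))
    return VariantPlan(svs=events, min_gap=min_gap)


def add_breakpoint_proximal_variants(
    plan: VariantPlan,
    genome: ReferenceGenome,
    expected_per_breakpoint: float,
    window: int = 100,
    seed: int = 0,
    footprints: FootprintIndex | None = None,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> VariantPlan:
    """Add small variants clustered around SV breakpoints.

    Breakpoints co-occur with small variants in real genomes; for every
    breakpoint a Poisson(``expected_per_breakpoint``) number of SNVs or
    indels (1:1 on average) is placed uniformly within ±``window`` bases,
    avoiding existing footprints. Returns a new, re-sorted plan.
    """
    if expected_per_breakpoint < 0:
        raise ValueError("expected_per_breakpoint must be >= 0")
    if window < 1:
        raise ValueError("window must be >= 1")
    if expected_per_breakpoint == 0:
        return plan
    rng = np.random.default_rng(seed)
    if footprints is None:
        footprints = FootprintIndex()
        for v in plan.sorted_variants():
            footprints.add_variant(v)
    new_snvs: list[SNV] = []
    new_indels: list[Indel] = []
    for ev in plan.svs:
        for chrom, bp in ev.breakpoints():
            clen = genome.length_of(chrom)
            for _ in range(rng.poisson(expected_per_breakpoint)):
                for _ in range(max_retries):
                    pos = int(
                        rng.integers(max(0, bp - window),
                                     min(clen - 1, bp + window) + 1)
                    )
                    seq = genome.chromosomes[chrom]
                    if seq[pos] == "N":
                        continue
                    hap = ev.haplotype if ev.haplotype is not None else 0
                    if rng.random() < 0.5:
                        if footprints.conflicts(chrom, pos, pos + 1):
                            continue
                        ref = seq[pos]
                        alt = _ALT_CHOICES[ref][rng.integers(3)]
                        v: SNV | Indel = SNV(
                            chrom, pos, ref, alt, zygosity="het",
                            origin=ev.origin, haplotype=hap,
                        )
                        new_snvs.append(v)
                    else:
                        length = int(rng.integers(1, 11))
                        if pos + length + 1 > clen or footprints.conflicts(
                            chrom, pos, pos + length + 1
                        ):
                            continue
                        if rng.random() < 0.5 and "N" not in seq[pos:pos + length + 1]:
                            ref, alt = seq[pos:pos + length + 1], seq[pos]
                        else:
                            ref = seq[pos]
                            alt = ref + _random_seq(rng, length)
                        v = Indel(chrom, pos, ref, alt, zygosity="het",
                                  origin=ev.origin, haplotype=hap)
                        new_indels.append(v)
                    footprints.add_variant(v)
                    break
    return VariantPlan(
        snvs=[*plan.snvs, *new_snvs],
        indels=[*plan.indels, *new_indels],
        svs=list(plan.svs),
        min_gap=plan.min_gap,
    )


# ---------------------------------------------------------------------------
# backward application


@dataclass(frozen=True)
class Edit:
    """Replace reference slice [start, end) with ``replacement`` on one
    (chromosome, haplotype)."""

    start: int
    end: int
    replacement: str


def _applies_to(hap: int | None, haplotype: int) -> bool:
    return hap is None or hap == haplotype


def plan_edits(
    plan: VariantPlan,
    genome: ReferenceGenome,
    chrom: str,
    haplotype: int,
) -> list[Edit]:
    """Collect the edits a plan induces on one (chromosome, haplotype).

    Payload sequences (translocated, duplicated or copied segments) are
    extracted from the reference; footprint disjointness guarantees they
    are unaffected by other events.
    """
    seq = genome.chromosomes[chrom]
    edits: list[Edit] = []
    for v in plan.snvs:
        if v.chromosome == chrom and _applies_to(v.haplotype, haplotype):
            if seq[v.position] != v.ref:
                raise IntegrityError(
                    f"SNV at {chrom}:{v.position}: ref {v.ref!r} != genome "
                    f"{seq[v.position]!r}"
                )
            edits.append(Edit(v.position, v.position + 1, v.alt))
    for v in plan.indels:
        if v.chromosome == chrom and _applies_to(v.haplotype, haplotype):
            if seq[v.position:v.position + len(v.ref)] != v.ref:
                raise IntegrityError(f"indel at {chrom}:{v.position}: ref mismatch")
            edits.append(Edit(v.position, v.position + len(v.ref), v.alt))
    for ev in plan.svs:
        edits.extend(_sv_edits(ev, genome, chrom, haplotype))
    return edits


def _sv_edits(
    ev: SVEvent, genome: ReferenceGenome, chrom: str, haplotype: int
) -> list[Edit]:
    on_hap = _applies_to(ev.haplotype, haplotype)
    edits: list[Edit] = []
    src_seq = genome.chromosomes[ev.chromosome]
    segment = src_seq[ev.start:ev.end]
    if ev.sv_class == "deletion":
        if ev.chromosome == chrom and on_hap:
            edits.append(Edit(ev.start, ev.end, ""))
    elif ev.sv_class == "insertion":
        if ev.chromosome == chrom and on_hap:
            edits.append(Edit(ev.start, ev.start, ev.inserted_seq))
    elif ev.sv_class == "inversion":
        if ev.chromosome == chrom and on_hap:
            edits.append(Edit(ev.start, ev.end, reverse_complement(segment)))
    elif ev.sv_class == "tandem_duplication":
        if ev.chromosome == chrom and on_hap:
            edits.append(Edit(ev.end, ev.end, segment * ev.extra_copies))
    elif ev.sv_class in ("intra_translocation", "inter_translocation"):
        # balanced: segment moves (removed at source); unbalanced: a copy
        # is inserted and the original is kept, a net gain
        if ev.balanced and ev.chromosome == chrom and on_hap:
            edits.append(Edit(ev.start, ev.end, ""))
        if ev.dest_chromosome == chrom and on_hap:
            edits.append(Edit(ev.dest_position, ev.dest_position, segment))
    elif ev.sv_class == "cnv":
        cn = ev.copy_number
        if ev.chromosome == chrom:
            if cn == 0:
                edits.append(Edit(ev.start, ev.end, ""))  # loss on every copy
            elif cn == 1 and on_hap:
                edits.append(Edit(ev.start, ev.end, ""))
            elif cn > 2 and on_hap:
                for dpos in ev.dest_positions:
                    edits.append(Edit(dpos, dpos, segment))
    else:  # pragma: no cover
        raise AssertionError(ev.sv_class)
    return edits


def apply_edits_backward(sequence: str, edits: Sequence[Edit]) -> str:
    """Apply non-overlapping edits from the highest coordinate down.

    Because application proceeds backward, the reference coordinates of
    every not-yet-applied edit remain valid throughout.
    """
    buf = bytearray(sequence, "ascii")
    for e in sorted(edits, key=lambda e: (e.start, e.end), reverse=True):
        if e.end > len(sequence):
            raise IntegrityError(f"edit [{e.start}, {e.end}) beyond sequence end")
        buf[e.start:e.end] = e.replacement.encode("ascii")
    return buf.decode("ascii")


def apply_plan_backward(
    haplotype_sequence: str,
    plan: VariantPlan,
    chrom: str = "chr1",
    haplotype: int = 0,
) -> tuple[str, list[Edit]]:
    """Apply a plan to one haplotype sequence; returns the mutated
    sequence and the edit list (ascending), from which donor coordinates
    can be derived with :func:`donor_position`."""
    genome = ReferenceGenome({chrom: haplotype_sequence}, metadata="in-memory")
    edits = plan_edits(plan, genome, chrom, haplotype)
    mutated = apply_edits_backward(haplotype_sequence, edits)
    return mutated, sorted(edits, key=lambda e: (e.start, e.end))


def donor_position(edits: Sequence[Edit], ref_pos: int) -> int:
    """Map a reference coordinate outside any replaced interval to its
    coordinate on the mutated (donor) sequence."""
    shift = 0
    for e in sorted(edits, key=lambda e: (e.start, e.end)):
        if e.end <= ref_pos:
            shift += len(e.replacement) - (e.end - e.start)
        elif e.start <= ref_pos < e.end and (e.end - e.start) != len(e.replacement):
            raise ValueError(f"position {ref_pos} lies inside a replaced interval")
    return ref_pos + shift


# ---------------------------------------------------------------------------
# truth output


def _vcf_sv_fields(ev: SVEvent, genome: ReferenceGenome) -> tuple[int, str, str, str]:
    """(1-based POS, REF, ALT, INFO) for a symbolic SV record."""
    seq = genome.chromosomes[ev.chromosome]
    pos0 = max(0, ev.start - 1)  # anchor base before the event
    ref = seq[pos0]
    common = f"MECH={ev.mechanism};CLONE={ev.origin};EVENT={ev.event_id}"
    if ev.sv_class == "deletion":
        info = f"SVTYPE=DEL;END={ev.end};SVLEN={-ev.span};{common}"
        return pos0 + 1, ref, "<DEL>", info
    if ev.sv_class == "insertion":
        info = f"SVTYPE=INS;END={ev.start};SVLEN={len(ev.inserted_seq)};{common}"
        return pos0 + 1, ref, "<INS>", info
    if ev.sv_class == "inversion":
        info = f"SVTYPE=INV;END={ev.end};SVLEN={ev.span};{common}"
        return pos0 + 1, ref, "<INV>", info
    if ev.sv_class == "tandem_duplication":
        info = (
            f"SVTYPE=DUP;END={ev.end};SVLEN={ev.span * ev.extra_copies};{common}"
        )
        return pos0 + 1, ref, "<DUP:TANDEM>", info
    if ev.sv_class == "cnv":
        info = f"SVTYPE=CNV;END={ev.end};SVLEN={ev.span};CN={ev.copy_number};{common}"
        return pos0 + 1, ref, "<CNV>", info
    # translocations as a single breakend-style record; the destination
    # lives in CHR2/POS2 (END is reserved for same-chromosome spans)
    info = (
        f"SVTYPE=BND;END={ev.end};CHR2={ev.dest_chromosome};"
        f"POS2={ev.dest_position + 1};"
        f"SVLEN={ev.span};BALANCED={'1' if ev.balanced else '0'};{common}"
    )
    return pos0 + 1, ref, "<BND>", info


def write_truth(
    plan: VariantPlan,
    genome: ReferenceGenome,
    vcf_path: str | Path,
    bedpe_path: str | Path,
) -> None:
    """Write the truth set: all variants as VCF 4.2 (1-based), SVs also
    as a BEDPE with both breakend anchors and mechanism/CN/clone columns.

    Every REF allele is re-verified against the reference before writing.
    """
    vcf_path, bedpe_path = Path(vcf_path), Path(bedpe_path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svforge",
    ]
    for name, seq in genome.chromosomes.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    for key, typ, desc in [
        ("SVTYPE", "String", "Structural variant class"),
        ("END", "Integer", "End coordinate (1-based inclusive)"),
        ("SVLEN", "Integer", "Signed length difference"),
        ("MECH", "String", "Formation mechanism (NAHR or NHR)"),
        ("CN", "Integer", "Copy number for CNV events"),
        ("CLONE", "String", "Genome of origin (germline or somatic clone)"),
        ("EVENT", "String", "Event identifier"),
        ("CHR2", "String", "Destination chromosome of a translocation"),
        ("POS2", "Integer", "Destination position (1-based) of a translocation"),
        ("BALANCED", "Integer", "1 if translocation is balanced"),
        ("ZYG", "String", "het or hom"),
    ]:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows: list[tuple[tuple, str]] = []
    for v in plan.snvs + plan.indels:
        seq = genome.chromosomes[v.chromosome]
        if seq[v.position:v.position + len(v.ref)] != v.ref:
            raise IntegrityError(
                f"truth REF mismatch at {v.chromosome}:{v.position}"
            )
        info = f"CLONE={v.origin};ZYG={v.zygosity}"
        rows.append((
            (v.chromosome, v.position + 1, 0),
            f"{v.chromosome}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}",
        ))
    bedpe_rows: list[str] = []
    for ev in plan.svs:
        pos1, ref, alt, info = _vcf_sv_fields(ev, genome)
        rows.append((
            (ev.chromosome, pos1, 1),
            f"{ev.chromosome}\t{pos1}\t{ev.event_id}\t{ref}\t{alt}\t.\tPASS\t{info}",
        ))
        if ev.sv_class in ("intra_translocation", "inter_translocation"):
            a = (ev.chromosome, ev.start, ev.end)
            b = (ev.dest_chromosome, ev.dest_position, ev.dest_position + 1)
            strands = ("+", "+")
        elif ev.sv_class == "insertion":
            a = (ev.chromosome, ev.start, ev.start + 1)
            b = a
            strands = ("+", "+")
        else:
            a = (ev.chromosome, ev.start, ev.start + 1)
            b = (ev.chromosome, ev.end, ev.end + 1)
            strands = ("+", "-") if ev.sv_class == "inversion" else ("+", "+")
        cn = ev.copy_number if ev.copy_number is not None else "."
        bedpe_rows.append(
            "\t".join(str(x) for x in (
                a[0], a[1], a[2], b[0], b[1], b[2], ev.event_id, ".",
                strands[0], strands[1], ev.sv_class, ev.mechanism, cn, ev.origin,
            ))
        )
    rows.sort(key=lambda r: r[0])
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, row in rows:
            fh.write(row + "\n")
    with open(bedpe_path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore"
            "\tstrand1\tstrand2\tsv_class\tmechanism\tcopy_number\tclone\n"
        )
        for row in bedpe_rows:
            fh.write(row + "\n")
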