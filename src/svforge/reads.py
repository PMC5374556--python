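"""Illumina-like paired-end read simulation, FASTQ I/O and mixing.

Reads carry their full provenance in the read name
(``<genome>|<chrom>|<hap>|<S1>|<S2>|<strand>|<serial>``), where S1 < S2
are the fragment's coordinates on the simulated chromosome: the fragment
is the donor sequence from S1 to S2 + r. Downstream stages (purity
accounting, GC-biased subsampling) work entirely from these names, so no
alignment is ever needed to recover the truth.

Fragment layout follows the Illumina FR convention: one mate reads the
fragment's leading r bases forward, the other the trailing r bases
reverse-complemented. Insert sizes are normal, truncated below at 2r by
resampling. The error model is substitution-only with i.i.d. per-base
errors; qualities are constant Phred symbols by default or a linear
ramp along the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import HaplotypeSet, reverse_complement

logger = logging.getLogger(__name__)

PROPORTION_TOL = 1e-9
NAME_SEP = "|"

__all__ = [
    "ReadConfig",
    "ReadPair",
    "ReadProvenance",
    "MixtureSpec",
    "simulate_read_pairs",
    "expected_pair_count",
    "mix_reads",
    "write_fastq",
    "read_fastq_pairs",
    "parse_read_name",
]


class ProvenanceError(ValueError):
    """A read name does not parse back to valid provenance."""


@dataclass
class ReadConfig:
    """Parameters of the paired-end read simulator.

    Defaults mirror a typical Illumina whole-genome run: 100 bp reads,
    insert size 320 +- 60 bp, 30-fold coverage. ``coverage`` is the mean
    number of sequenced bases per haplotype base, so the number of pairs
    is ``round(coverage * G / (2 * read_length))`` with G the total
    haplotype length.
    """

    read_length: int = 100
    coverage: float = 30.0
    insert_mean: float = 320.0
    insert_sd: float = 60.0
    error_rate: float = 0.001
    base_quality: int = 30
    quality_model: str = "constant"  # or "position_linear"
    end_quality: int = 20            # 3' quality for position_linear

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.quality_model not in ("constant", "position_linear"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")


@dataclass(frozen=True)
class ReadProvenance:
    genome_id: str
    chromosome: str
    haplotype: int
    s1: int
    s2: int
    strand: str
    serial: int


@dataclass
class ReadPair:
    """Two mates plus the provenance encoded in their shared name."""

    name: str
    r1: str
    r2: str
    q1: str
    q2: str

    @property
    def provenance(self) -> ReadProvenance:
        return parse_read_name(self.name)


def make_read_name(
    genome_id: str, chrom: str, hap: int, s1: int, s2: int, strand: str,
    serial: int,
) -> str:
    return NAME_SEP.join(
        (genome_id, chrom, str(hap), str(s1), str(s2), strand, str(serial))
    )


def parse_read_name(name: str) -> ReadProvenance:
    parts = name.split(NAME_SEP)
    if len(parts) != 7:
        raise ProvenanceError(f"read name {name!r} has {len(parts)} fields, not 7")
    genome_id, chrom, hap, s1, s2, strand, serial = parts
    try:
        prov = ReadProvenance(
            genome_id, chrom, int(hap), int(s1), int(s2), strand, int(serial)
        )
    except ValueError as exc:
        raise ProvenanceError(f"read name {name!r}: {exc}") from exc
    if prov.s1 >= prov.s2:
        raise ProvenanceError(f"read name {name!r}: S1 must be < S2")
    if strand not in ("+", "-"):
        raise ProvenanceError(f"read name {name!r}: bad strand {strand!r}")
    return prov


def expected_pair_count(total_bases: int, config: ReadConfig) -> int:
    """round(C * G / (2r)): pairs needed for coverage C over G bases."""
    return round(config.coverage * total_bases / (2 * config.read_length))


def _quality_string(config: ReadConfig) -> str:
    r = config.read_length
    if config.quality_model == "constant":
        return chr(33 + config.base_quality) * r
    qs = np.linspace(config.base_quality, config.end_quality, r)
    return "".join(chr(33 + int(round(q))) for q in qs)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _inject_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute k uniformly chosen positions with a different base."""
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=k, replace=False)
    for p in positions:
        old = chr(arr[p])
        choices = "ACGT".replace(old, "") if old in _BASE_INDEX else "ACGT"
        arr[p] = ord(choices[rng.integers(len(choices))])
    return arr.decode("ascii")


def simulate_read_pairs(
    haplotype_set: HaplotypeSet,
    config: ReadConfig,
    seed: int = 0,
    n_pairs: int | None = None,
) -> list[ReadPair]:
    """Simulate paired-end reads from every haplotype of a genome.

    Fragments start uniformly along each haplotype, haplotypes being
    chosen with probability proportional to their length; haplotypes
    shorter than one insert are skipped with a warning. ``n_pairs``
    overrides the coverage-derived count (used when a downstream mixing
    step dictates how many pairs are needed).
    """
    r = config.read_length
    eligible = [
        (c, h, s) for c, h, s in haplotype_set.copies if len(s) >= 2 * r
    ]
    skipped = len(haplotype_set.copies) - len(eligible)
    if skipped:
        logger.warning(
            "%s: %d haplotype(s) shorter than one fragment skipped",
            haplotype_set.genome_id, skipped,
        )
    if not eligible:
        raise ValueError("no haplotype long enough for a single fragment")
    if NAME_SEP in haplotype_set.genome_id:
        raise ValueError(f"genome id may not contain {NAME_SEP!r}")

    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for _, _, s in eligible], dtype=np.int64)
    total = int(lengths.sum())
    if n_pairs is None:
        n_pairs = expected_pair_count(total, config)
    probs = lengths / lengths.sum()
    copy_idx = rng.choice(len(eligible), size=n_pairs, p=probs)

    # insert sizes: truncated normal, resampled until 2r <= insert <= copy length
    inserts = np.rint(
        rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    ).astype(np.int64)
    max_insert = lengths[copy_idx]
    bad = (inserts < 2 * r) | (inserts > max_insert)
    while bad.any():
        inserts[bad] = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, size=int(bad.sum()))
        ).astype(np.int64)
        bad = (inserts < 2 * r) | (inserts > max_insert)
    starts = rng.integers(0, max_insert - inserts + 1)
    strands = rng.random(n_pairs) < 0.5
    n_errors = rng.binomial(r, config.error_rate, size=(n_pairs, 2))
    qual = _quality_string(config)

    pairs: list[ReadPair] = []
    for serial in range(n_pairs):
        chrom, hap, seq = eligible[copy_idx[serial]]
        s1 = int(starts[serial])
        insert = int(inserts[serial])
        s2 = s1 + insert - r
        fwd = seq[s1:s1 + r]
        rev = reverse_complement(seq[s2:s2 + r])
        if strands[serial]:
            r1, r2, strand = fwd, rev, "+"
        else:
            r1, r2, strand = rev, fwd, "-"
        if n_errors[serial, 0]:
            r1 = _inject_errors(r1, int(n_errors[serial, 0]), rng)
        if n_errors[serial, 1]:
            r2 = _inject_errors(r2, int(n_errors[serial, 1]), rng)
        name = make_read_name(
            haplotype_set.genome_id, chrom, hap, s1, s2, strand, serial
        )
        pairs.append(ReadPair(name=name, r1=r1, r2=r2, q1=qual, q2=qual))
    return pairs


@dataclass
class MixtureSpec:
    """Genome-id to mixture-proportion map; proportions sum to 1."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError("mixture must name at least one genome")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("mixture proportions must be non-negative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > PROPORTION_TOL:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")


def mix_reads(
    streams: Mapping[str, Sequence[ReadPair]],
    mixture: MixtureSpec,
    total_pairs: int,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[ReadPair]:
    """Mix read pairs from several genomes at given proportions.

    The source genome of each output pair is drawn i.i.d. from the
    mixture (multinomial mixing); pairs are then consumed sequentially
    from each stream. Raises a capacity error when a stream runs out,
    unless ``with_replacement`` allows re-drawing pairs uniformly.
    """
    missing = set(mixture.proportions) - set(streams)
    if missing:
        raise ValueError(f"mixture names genomes without streams: {missing}")
    rng = np.random.default_rng(seed)
    ids = sorted(mixture.proportions)
    probs = np.array([mixture.proportions[g] for g in ids])
    labels = rng.choice(len(ids), size=total_pairs, p=probs)
    cursors = {g: 0 for g in ids}
    out: list[ReadPair] = []
    for lab in labels:
        gid = ids[lab]
        stream = streams[gid]
        i = cursors[gid]
        if i >= len(stream):
            if not with_replacement:
                raise RuntimeError(
                    f"stream {gid!r} exhausted after {i} pairs "
                    f"(needed for mixture share {mixture.proportions[gid]})"
                )
            i = int(rng.integers(len(stream)))
        else:
            cursors[gid] += 1
        out.append(stream[i])
    realized = {g: cursors[g] for g in ids}
    logger.info("mixed %d pairs, per-genome counts %s", total_pairs, realized)
    return out


def write_fastq(
    pairs: Iterable[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> int:
    """Write mates to two FASTQ files in identical order; returns the
    number of pairs written."""
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.r1}\n+\n{p.q1}\n")
            f2.write(f"@{p.name}/2\n{p.r2}\n+\n{p.q2}\n")
            n += 1
    return n


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[ReadPair]:
    """Read two mate-synchronized FASTQ files back into pairs."""
    from Bio import SeqIO

    out: list[ReadPair] = []
    with open(path_r1) as f1, open(path_r2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            name1 = rec1.id.removesuffix("/1")
            name2 = rec2.id.removesuffix("/2")
            if name1 != name2:
                raise ProvenanceError(
                    f"mate files out of sync: {rec1.id!r} vs {rec2.id!r}"
                )
            q1 = "".join(
                chr(33 + q) for q in rec1.letter_annotations["phred_quality"]
            )
            q2 = "".join(
                chr(33 + q) for q in rec2.letter_annotations["phred_quality"]
            )
            out.append(
                ReadPair(name=name1, r1=str(rec1.seq), r2=str(rec2.seq),
                         q1=q1, q2=q2)
            )
    return out
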