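"""Sequence containers, FASTA I/O, repeat annotations and GC computation.

All coordinates in this package are 0-based half-open. Conversion to the
1-based conventions of VCF and RepeatMasker happens only in the adapters
that read or write those formats.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "ReferenceGenome",
    "HaplotypeSet",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "gc_fraction",
    "generate_synthetic_reference",
    "read_repeat_regions",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be interpreted."""


class RepeatFormatError(ValueError):
    """Raised when a repeat-annotation file cannot be parsed."""


@dataclass
class ReferenceGenome:
    """A set of named chromosome sequences.

    Parameters
    ----------
    chromosomes
        Ordered mapping from chromosome name to uppercase sequence over
        the alphabet ``ACGTN``.
    metadata
        Free-form provenance string (source path, generator parameters).
    """

    chromosomes: dict[str, str]
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def length_of(self, name: str) -> int:
        return len(self.chromosomes[name])


@dataclass
class HaplotypeSet:
    """Per-haplotype sequences of one (possibly aneuploid) genome.

    ``copies`` holds ``(chromosome name, haplotype index, sequence)``
    triples; a diploid autosome has indices 0 and 1.
    """

    copies: list[tuple[str, int, str]]
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        keys = [(c, h) for c, h, _ in self.copies]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chromosome, haplotype) pairs")

    @classmethod
    def diploid_from_reference(
        cls, genome: ReferenceGenome, genome_id: str = "genome"
    ) -> "HaplotypeSet":
        copies = []
        for name, seq in genome.chromosomes.items():
            copies.append((name, 0, seq))
            copies.append((name, 1, seq))
        return cls(copies=copies, genome_id=genome_id)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, _, s in self.copies)

    def sequence(self, chrom: str, haplotype: int) -> str:
        for c, h, s in self.copies:
            if c == chrom and h == haplotype:
                return s
        raise KeyError(f"no haplotype ({chrom}, {haplotype})")

    def copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c, _, _ in self.copies:
            out[c] = out.get(c, 0) + 1
        return out


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sanitize(seq: str, name: str) -> str:
    """Uppercase a sequence and map non-ACGTN characters to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        n_bad = sum(seq.count(c) for c in bad)
        logger.warning(
            "chromosome %s: %d non-ACGTN characters (%s) converted to N",
            name, n_bad, "".join(sorted(bad)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (possibly gzipped) FASTA file into a :class:`ReferenceGenome`.

    Record order is preserved, sequences are uppercased and characters
    outside ``ACGTN`` are converted to ``N`` (with a logged count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chromosomes: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FastaFormatError(f"{path}: empty file")
        if first != ">":
            raise FastaFormatError(f"{path}: does not start with a FASTA header")
        fh.seek(0)
        for record in SeqIO.parse(fh, "fasta"):
            if not record.id:
                raise FastaFormatError(f"{path}: record with empty header")
            if record.id in chromosomes:
                raise FastaFormatError(f"{path}: duplicate record {record.id!r}")
            chromosomes[record.id] = _sanitize(str(record.seq), record.id)
    if not chromosomes:
        raise FastaFormatError(f"{path}: no FASTA records")
    return ReferenceGenome(chromosomes=chromosomes, metadata=f"read from {path}")


def write_fasta(
    genome: ReferenceGenome | HaplotypeSet,
    path: str | Path,
    line_width: int = 60,
) -> None:
    """Write a genome or haplotype set as FASTA.

    Haplotype copies are written as ``<chrom>_hap<index>`` records so the
    file round-trips through :func:`read_fasta` with unique names.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if isinstance(genome, HaplotypeSet):
        items: Iterable[tuple[str, str]] = (
            (f"{c}_hap{h}", s) for c, h, s in genome.copies
        )
    else:
        items = genome.chromosomes.items()
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in items)
    with _open_maybe_gzip(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def gc_fraction(sequence: str) -> float:
    """GC proportion of a sequence: (#G + #C) / (#A + #C + #G + #T).

    ``N`` bases are excluded from numerator and denominator; an all-N
    sequence yields ``nan`` (GC is undefined there).
    """
    if not sequence:
        raise ValueError("gc_fraction of an empty sequence is undefined")
    sequence = sequence.upper()
    gc = sequence.count("G") + sequence.count("C")
    acgt = gc + sequence.count("A") + sequence.count("T")
    if acgt == 0:
        return math.nan
    return gc / acgt


def generate_synthetic_reference(
    chrom_lengths: Mapping[str, int] | Sequence[int],
    gc_target: float = 0.41,
    seed: int = 0,
) -> ReferenceGenome:
    """Generate an i.i.d. random reference with a target GC content.

    Bases are drawn independently with ``P(G) = P(C) = gc_target / 2`` and
    ``P(A) = P(T) = (1 - gc_target) / 2``; output is deterministic given
    the seed. The default GC of 0.41 matches the genome-wide human value.

    ``chrom_lengths`` may be a mapping ``{name: length}`` or a sequence of
    lengths (named ``chr1``, ``chr2``, ...).
    """
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be in [0, 1]")
    if not isinstance(chrom_lengths, Mapping):
        chrom_lengths = {f"chr{i + 1}": n for i, n in enumerate(chrom_lengths)}
    if not chrom_lengths:
        raise ValueError("at least one chromosome length is required")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chromosomes: dict[str, str] = {}
    for name, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {name!r}: length must be >= 1")
        idx = rng.choice(4, size=length, p=probs)
        chromosomes[name] = alphabet[idx].tobytes().decode("ascii")
    return ReferenceGenome(
        chromosomes=chromosomes,
        metadata=f"synthetic i.i.d. reference, gc_target={gc_target}, seed={seed}",
    )


def read_repeat_regions(
    path: str | Path, dialect: str = "auto"
) -> list[GenomicInterval]:
    """Read repeat annotations from a BED or RepeatMasker ``.out`` file.

    Returns intervals in 0-based half-open coordinates sorted by
    (chromosome, start). RepeatMasker's 1-based inclusive begin/end
    columns are converted. ``dialect`` is ``"bed"``, ``"repeatmasker"``
    or ``"auto"`` (sniffed from the extension: ``.out`` is RepeatMasker).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "repeatmasker" if path.suffix == ".out" else "bed"
    if dialect not in ("bed", "repeatmasker"):
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    intervals: list[GenomicInterval] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                if dialect == "bed":
                    if line.startswith(("track", "browser", "#")):
                        continue
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    # RepeatMasker .out: header lines do not start with a
                    # numeric Smith-Waterman score.
                    if not fields[0].isdigit():
                        continue
                    chrom = fields[4]
                    start, end = int(fields[5]) - 1, int(fields[6])
                intervals.append(GenomicInterval(chrom, start, end))
            except (ValueError, IndexError) as exc:
                raise RepeatFormatError(
                    f"{path}:{lineno}: cannot parse {dialect} row: {line.rstrip()!r}"
                ) from exc
    intervals.sort()
    return intervals
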