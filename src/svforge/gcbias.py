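"""GC-bias introduction by Bernoulli rejection subsampling.

Real HTS depth depends strongly on local GC content, and the dependency
takes many shapes across libraries. This module reproduces any such
shape by subsampling already-simulated read pairs: for a pair whose
fragment spans S1..S2+r on its donor chromosome, the GC fraction GC_S of
that segment is computed and the pair is kept with probability

    p_S = f(GC_S) / (1 + f(GC_S)),

with f a user-specified non-negative bias function of GC. f is modelled
as a piecewise polynomial on [0, 1]; three presets (``f1`` a cubic,
``f2`` a downward parabola peaking at GC 0.6, ``f3`` a piecewise-linear
tent) cover the bias shapes commonly seen in public sequencing data.
Polynomials that dip below zero (the cubic does near GC 0 and 1) are
clamped at 0, i.e. such fragments are never kept.

GC_S is computed from the donor coordinates encoded in read names —
exact by construction; an approximate fallback concatenating the mate
sequences is available for externally generated reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import HaplotypeSet, gc_fraction
from .reads import ProvenanceError, ReadPair, parse_read_name

__all__ = [
    "BiasFunction",
    "SubsampleDecision",
    "RetentionReport",
    "evaluate_bias",
    "subsample_probability",
    "segment_gc",
    "subsample_read_pairs",
    "write_retention_report",
    "PRESETS",
]

GC_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class BiasFunction:
    """A piecewise-polynomial bias function on GC in [0, 1].

    ``pieces`` is an ordered list of ``((lo, hi), coefficients)`` with
    coefficients highest-degree first (``numpy.polyval`` convention);
    intervals must tile [0, 1] without gaps or overlap. Values are
    clamped below at 0 when evaluated.
    """

    name: str
    pieces: tuple[tuple[tuple[float, float], tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ValueError("bias function needs at least one piece")
        lo0 = self.pieces[0][0][0]
        hi_last = self.pieces[-1][0][1]
        if lo0 != 0.0 or hi_last != 1.0:
            raise ValueError("pieces must cover [0, 1]")
        for ((_, hi), _), ((lo, _), _) in zip(self.pieces, self.pieces[1:]):
            if hi != lo:
                raise ValueError("pieces must tile [0, 1] without gaps/overlap")

    @classmethod
    def from_pieces(
        cls,
        pieces: Sequence[tuple[Sequence[float], Sequence[float]]],
        name: str = "custom",
    ) -> "BiasFunction":
        return cls(
            name=name,
            pieces=tuple(
                ((float(lo), float(hi)), tuple(float(c) for c in coeffs))
                for (lo, hi), coeffs in pieces
            ),
        )

    @classmethod
    def constant(cls, value: float, name: str | None = None) -> "BiasFunction":
        return cls.from_pieces(
            [((0.0, 1.0), (float(value),))],
            name=name or f"constant_{value}",
        )

    def __call__(self, gc: float) -> float:
        return evaluate_bias(self, gc)


def evaluate_bias(fspec: BiasFunction, gc: float) -> float:
    """Evaluate the bias function at a GC fraction, clamped below at 0."""
    if math.isnan(gc):
        raise ValueError("GC fraction is undefined (all-N segment)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction {gc} outside [0, 1]")
    for (lo, hi), coeffs in fspec.pieces:
        if lo <= gc < hi or (gc == hi == 1.0):
            return max(0.0, float(np.polyval(coeffs, gc)))
    raise AssertionError("pieces do not cover [0, 1]")  # pragma: no cover


def subsample_probability(f_value: float) -> float:
    """Keep probability p = f / (1 + f); increasing in f, p(0) = 0."""
    if f_value < 0:
        raise ValueError("bias value must be non-negative (clamp upstream)")
    return f_value / (1.0 + f_value)


# the three built-in bias shapes; f2 expanded: -2.5(x-0.6)^2 + 1
PRESETS: dict[str, BiasFunction] = {
    "f1": BiasFunction.from_pieces(
        [((0.0, 1.0), (-8.89, -3.56, 9.13, -1.58))], name="f1"
    ),
    "f2": BiasFunction.from_pieces(
        [((0.0, 1.0), (-2.5, 3.0, 0.1))], name="f2"
    ),
    "f3": BiasFunction.from_pieces(
        [
            ((0.0, 0.2), (0.1,)),
            ((0.2, 0.4), (4.0, -0.6)),
            ((0.4, 1.0), (-2.0, 1.8)),
        ],
        name="f3",
    ),
}


@dataclass(frozen=True)
class SubsampleDecision:
    """Outcome of the biased coin flip for one read pair."""

    name: str
    gc: float
    f_value: float
    probability: float
    kept: bool


def segment_gc(
    pair: ReadPair,
    genomes: Mapping[str, HaplotypeSet] | None,
) -> float:
    """GC fraction of the donor segment [S1, S2 + r) behind a read pair.

    With ``genomes`` available the segment is looked up on the simulated
    chromosome named in the read's provenance (exact). Without genomes,
    the concatenated mate sequences approximate the segment (the middle
    of long inserts is unobserved).
    """
    if genomes is None:
        return gc_fraction(pair.r1 + pair.r2)
    prov = parse_read_name(pair.name)
    if prov.genome_id not in genomes:
        raise ProvenanceError(f"unknown genome {prov.genome_id!r} in {pair.name!r}")
    try:
        donor = genomes[prov.genome_id].sequence(prov.chromosome, prov.haplotype)
    except KeyError as exc:
        raise ProvenanceError(str(exc)) from exc
    r = len(pair.r1)
    end = prov.s2 + r
    if end > len(donor):
        raise ProvenanceError(
            f"{pair.name!r}: segment end {end} beyond chromosome "
            f"({len(donor)} bp)"
        )
    return gc_fraction(donor[prov.s1:end])


@dataclass
class RetentionReport:
    """Per-GC-bin retention bookkeeping (bin width 0.05)."""

    n_total: np.ndarray      # pairs seen per bin
    n_kept: np.ndarray       # pairs kept per bin
    p_sum: np.ndarray        # sum of keep probabilities per bin
    n_undefined: int = 0     # all-N segments, dropped

    @classmethod
    def empty(cls) -> "RetentionReport":
        n = int(round(1 / GC_BIN_WIDTH))
        return cls(
            n_total=np.zeros(n, dtype=np.int64),
            n_kept=np.zeros(n, dtype=np.int64),
            p_sum=np.zeros(n, dtype=float),
        )

    @staticmethod
    def bin_of(gc: float) -> int:
        return min(int(gc / GC_BIN_WIDTH), int(round(1 / GC_BIN_WIDTH)) - 1)

    def rows(self) -> list[tuple[float, int, int, float, float]]:
        out = []
        for i in range(len(self.n_total)):
            tot, kept = int(self.n_total[i]), int(self.n_kept[i])
            observed = kept / tot if tot else math.nan
            expected = self.p_sum[i] / tot if tot else math.nan
            out.append((round(i * GC_BIN_WIDTH, 2), tot, kept, observed, expected))
        return out


def subsample_read_pairs(
    pairs: Iterable[ReadPair],
    genomes: Mapping[str, HaplotypeSet] | None,
    fspec: BiasFunction,
    seed: int = 0,
) -> tuple[list[ReadPair], RetentionReport]:
    """Bernoulli-subsample read pairs according to their segment GC.

    Each pair is kept independently with probability
    ``f(GC_S) / (1 + f(GC_S))``; mates are kept or dropped together.
    Pairs whose segment GC is undefined (all N) are dropped and counted
    separately. Returns the kept pairs and a per-bin retention report.
    """
    rng = np.random.default_rng(seed)
    kept: list[ReadPair] = []
    report = RetentionReport.empty()
    for pair in pairs:
        gc = segment_gc(pair, genomes)
        if math.isnan(gc):
            report.n_undefined += 1
            continue
        f_val = evaluate_bias(fspec, gc)
        p = subsample_probability(f_val)
        b = report.bin_of(gc)
        report.n_total[b] += 1
        report.p_sum[b] += p
        if rng.random() < p:
            report.n_kept[b] += 1
            kept.append(pair)
    return kept, report


def write_retention_report(report: RetentionReport, path: str | Path) -> None:
    """Write the retention report as a TSV (one row per 0.05 GC bin)."""
    with open(path, "w") as fh:
        fh.write("gc_bin\tn_total\tn_kept\tobserved_rate\texpected_rate\n")
        for gc_bin, tot, kept, obs, exp in report.rows():
            obs_s = f"{obs:.6f}" if not math.isnan(obs) else "NA"
            exp_s = f"{exp:.6f}" if not math.isnan(exp) else "NA"
            fh.write(f"{gc_bin:.2f}\t{tot}\t{kept}\t{obs_s}\t{exp_s}\n")
        if report.n_undefined:
            fh.write(f"# undefined_gc_pairs\t{report.n_undefined}\n")
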