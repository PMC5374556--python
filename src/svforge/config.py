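"""Structured run configuration: schema, defaults and validation.

A run is described by one YAML document with blocks for the reference,
the germline variants, the optional tumor model, the read simulator and
the optional GC-bias stage. Unknown keys are rejected and errors are
reported with their key paths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .tumor import PROPORTION_TOL
from .variants import SV_CLASSES


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticReferenceSpec(_Block):
    lengths: dict[str, int] = Field(default={"chr1": 1_000_000})
    gc: float = 0.41


class ReferenceBlock(_Block):
    path: str | None = None
    synthetic: SyntheticReferenceSpec | None = None

    @model_validator(mode="after")
    def _one_source(self) -> "ReferenceBlock":
        if (self.path is None) == (self.synthetic is None):
            raise ValueError("reference needs exactly one of 'path' or 'synthetic'")
        return self


class BreakpointProximalBlock(_Block):
    expected: float = Field(default=0.0, ge=0)
    window: int = Field(default=100, ge=1)


class SVBlock(_Block):
    counts: dict[str, int] = Field(default_factory=dict)
    size_range: tuple[int, int] = (100, 10_000)
    p_nahr: float = Field(default=0.0, ge=0, le=1)
    repeats_path: str | None = None
    repeats_dialect: Literal["auto", "bed", "repeatmasker"] = "auto"
    cnv_copy_numbers: list[int] = Field(default=[0, 1, 3, 4, 5, 6])
    insertion_fasta: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "SVBlock":
        for cls, n in self.counts.items():
            if cls not in SV_CLASSES:
                raise ValueError(f"unknown SV class {cls!r} in counts")
            if n < 0:
                raise ValueError(f"counts.{cls} must be >= 0")
        if self.p_nahr > 0 and self.repeats_path is None:
            raise ValueError("p_nahr > 0 requires repeats_path")
        return self


class GermlineBlock(_Block):
    snv_count: int = Field(default=0, ge=0)
    indel_count: int = Field(default=0, ge=0)
    het_fraction: float = Field(default=0.5, ge=0, le=1)
    snv_source: str = "random"
    indel_source: str = "random"
    indel_size_range: tuple[int, int] = (1, 10)
    sv: SVBlock = Field(default_factory=SVBlock)
    breakpoint_proximal: BreakpointProximalBlock = Field(
        default_factory=BreakpointProximalBlock
    )
    min_gap: int = Field(default=100, ge=0)


class CloneBlock(_Block):
    id: str
    parent: str | None = None
    proportion: float = Field(ge=0, le=1)
    snv_count: int = Field(default=0, ge=0)
    indel_count: int = Field(default=0, ge=0)
    sv_counts: dict[str, int] = Field(default_factory=dict)
    het_fraction: float = Field(default=1.0, ge=0, le=1)
    snv_source: str = "random"
    sv_size_range: tuple[int, int] = (100, 10_000)

    @model_validator(mode="after")
    def _check(self) -> "CloneBlock":
        for cls, n in self.sv_counts.items():
            if cls not in SV_CLASSES:
                raise ValueError(f"unknown SV class {cls!r} in sv_counts")
            if n < 0:
                raise ValueError(f"sv_counts.{cls} must be >= 0")
        return self


class TumorBlock(_Block):
    karyotype: dict[str, int] = Field(default_factory=dict)
    normal_fraction: float = Field(default=0.0, ge=0, le=1)
    clones: list[CloneBlock]

    @model_validator(mode="after")
    def _check(self) -> "TumorBlock":
        if not self.clones:
            raise ValueError("tumor block needs at least one clone")
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")
        total = self.normal_fraction + sum(c.proportion for c in self.clones)
        if abs(total - 1.0) > PROPORTION_TOL:
            raise ValueError(
                f"clone proportions plus normal_fraction sum to {total}, expected 1"
            )
        for k, v in self.karyotype.items():
            if v < 0:
                raise ValueError(f"karyotype.{k} must be >= 0")
        return self

    @property
    def purity(self) -> float:
        return sum(c.proportion for c in self.clones)


class ReadsBlock(_Block):
    read_length: int = Field(default=100, ge=1)
    coverage: float = Field(default=30.0, gt=0)
    insert_mean: float = Field(default=320.0, gt=0)
    insert_sd: float = Field(default=60.0, ge=0)
    error_rate: float = Field(default=0.001, ge=0, lt=1)
    base_quality: int = Field(default=30, ge=2, le=41)
    quality_model: Literal["constant", "position_linear"] = "constant"

    @model_validator(mode="after")
    def _check(self) -> "ReadsBlock":
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        return self


class BiasBlock(_Block):
    preset: str | None = None
    pieces: list[tuple[tuple[float, float], list[float]]] | None = None
    keep_prebias: bool = True

    @model_validator(mode="after")
    def _one_spec(self) -> "BiasBlock":
        if (self.preset is None) == (self.pieces is None):
            raise ValueError("bias needs exactly one of 'preset' or 'pieces'")
        if self.preset is not None:
            from .gcbias import PRESETS

            if self.preset not in PRESETS:
                raise ValueError(
                    f"unknown preset {self.preset!r}; available: "
                    f"{sorted(PRESETS)}"
                )
        return self

    def bias_function(self):
        from .gcbias import PRESETS, BiasFunction

        if self.preset is not None:
            return PRESETS[self.preset]
        return BiasFunction.from_pieces(self.pieces)


class RunConfig(_Block):
    """Fully validated configuration of one simulation run."""

    reference: ReferenceBlock
    germline: GermlineBlock = Field(default_factory=GermlineBlock)
    tumor: TumorBlock | None = None
    reads: ReadsBlock = Field(default_factory=ReadsBlock)
    bias: BiasBlock | None = None
    seed: int = 0
    outdir: str = "svforge_out"


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a YAML config document (or a pre-parsed dict).

    Missing blocks receive defaults; unknown keys and invalid values
    raise with their key paths.
    """
    if isinstance(raw, str):
        data = yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
    else:
        data = raw
    return RunConfig.model_validate(data)


def load_config(path: str | Path) -> RunConfig:
    return validate_config(Path(path).read_text())
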