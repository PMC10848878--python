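"""Core domain types shared across the pipeline.

Genotypes are diploid, biallelic calls encoded as small integers so that
per-cohort genotype matrices can live in compact numpy arrays:

====  ==========  ==============================
code  name        meaning
====  ==========  ==============================
0     HOM_REF     homozygous reference
1     HET         heterozygous
2     HOM_ALT     homozygous alternative
-1    MISSING     no call (./.)
====  ==========  ==============================

All genomic intervals held by these types are 1-based and inclusive at both
ends (the VCF convention); BED input is converted at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genotype",
    "SVRecord",
    "SampleInfo",
    "Trio",
    "GeneModel",
    "RepeatFeature",
    "OverlapCategory",
    "PolarizedCall",
    "RepeatComposition",
    "SV_TYPES",
    "genotype_matrix",
]

SV_TYPES = ("DEL", "DUP", "INV")


class Genotype(enum.IntEnum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class OverlapCategory(str, enum.Enum):
    """Mutually exclusive gene-overlap class, assigned by fixed priority."""

    ENCLOSING = "ENCLOSING"
    PARTIAL_CDS = "PARTIAL_CDS"
    NONCODING = "NONCODING"
    INTERGENIC = "INTERGENIC"


class Ancestral(str, enum.Enum):
    REF = "REF"
    ALT = "ALT"
    UNPOLARIZED = "UNPOLARIZED"


class MutationClass(str, enum.Enum):
    TRUE_DELETION = "TRUE_DELETION"
    INSERTION = "INSERTION"
    COPY_GAIN = "COPY_GAIN"
    COPY_LOSS_IN_REFERENCE = "COPY_LOSS_IN_REFERENCE"
    INVERSION_DERIVED = "INVERSION_DERIVED"
    INVERSION_ANCESTRAL_REF = "INVERSION_ANCESTRAL_REF"
    UNPOLARIZED = "UNPOLARIZED"


@dataclass
class SVRecord:
    """One structural-variant locus with per-sample genotype calls.

    ``genotypes`` is an int8 array aligned with the cohort's sample order
    (one entry per sample, values per :class:`Genotype`). ``dhffc`` is the
    duphold depth fold-change of the variant region relative to its flanks
    (low supports a deletion, high a duplication); it may be NaN for
    inversions, where depth carries no signal. ``mshq`` is the mean smoove
    heterozygosity score, a per-locus genotype-quality summary.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based start
    end: int  # 1-based inclusive end
    svtype: str
    length: int
    genotypes: np.ndarray
    dhffc: float = float("nan")
    mshq: float = float("nan")
    is_autosomal: bool = True
    is_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"svtype must be one of {SV_TYPES}, got {self.svtype!r}")
        if self.end < self.pos:
            raise ValueError(f"{self.variant_id}: end {self.end} < pos {self.pos}")
        if self.length < 1:
            raise ValueError(f"{self.variant_id}: length must be >= 1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.pos, self.end)


@dataclass
class SampleInfo:
    """Cohort individual with population and pedigree-class labels."""

    sample_id: str
    population: str
    generation_class: str | None = None  # F1..F6 / L1..L3, Scandinavian-born only
    coverage: float | None = None

    POPULATIONS = (
        "SCAND_ORIGINAL",
        "SCAND_IMMIGRANT_DESC",
        "FINLAND",
        "RUSSIA",
        "IMMIGRANT_NR",
        "IMMIGRANT_R",
        "FOUNDER",
    )

    def __post_init__(self) -> None:
        if self.population not in self.POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        scand_born = self.population in ("SCAND_ORIGINAL", "SCAND_IMMIGRANT_DESC")
        if self.generation_class is not None and not scand_born:
            raise ValueError(
                f"{self.sample_id}: generation_class set for non-Scandinavian-born "
                f"population {self.population}"
            )


@dataclass(frozen=True)
class Trio:
    child: str
    father: str
    mother: str

    def __post_init__(self) -> None:
        if len({self.child, self.father, self.mother}) != 3:
            raise ValueError(f"trio ids must be distinct: {self}")


@dataclass
class GeneModel:
    """Protein-coding gene: span plus merged, disjoint CDS intervals."""

    gene_id: str
    chrom: str
    gene_span: tuple[int, int]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        lo, hi = self.gene_span
        if hi < lo:
            raise ValueError(f"{self.gene_id}: empty gene span")
        self.cds_intervals = merge_intervals(self.cds_intervals)
        for s, e in self.cds_intervals:
            if s < lo or e > hi:
                raise ValueError(f"{self.gene_id}: CDS [{s},{e}] outside span {self.gene_span}")


@dataclass(frozen=True)
class RepeatFeature:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    repeat_class: str


@dataclass
class PolarizedCall:
    """Ancestral/derived assignment for one variant from two outgroups."""

    variant_id: str
    ancestral: Ancestral
    mutation_class: MutationClass

    @property
    def derived_is_reference(self) -> bool:
        return self.ancestral is Ancestral.ALT

    def __post_init__(self) -> None:
        unpol = self.ancestral is Ancestral.UNPOLARIZED
        if unpol != (self.mutation_class is MutationClass.UNPOLARIZED):
            raise ValueError("mutation_class is UNPOLARIZED iff ancestral is UNPOLARIZED")


@dataclass
class RepeatComposition:
    """Per-variant base counts by repeat class; every base counted once."""

    variant_id: str
    bases_per_class: dict[str, int]
    unannotated_bases: int

    def total(self) -> int:
        return sum(self.bases_per_class.values()) + self.unannotated_bases


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals into a disjoint sorted list.

    Adjacent intervals (e.g. [1,5] and [6,9]) are merged as well, so the
    result is the minimal disjoint cover of the per-base union.
    """
    if not intervals:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e < s:
            raise ValueError(f"empty interval [{s},{e}]")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def genotype_matrix(records: list[SVRecord]) -> np.ndarray:
    """Stack per-record genotype arrays into a (n_loci, n_samples) int8 matrix."""
    if not records:
        return np.zeros((0, 0), dtype=np.int8)
    return np.vstack([r.genotypes for r in records])
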