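"""Shared domain types.

Coordinate convention: all intervals are 0-based half-open ``[start, end)``.
GFF3 files are read/written as 1-based inclusive and converted at the I/O
boundary (see :mod:`lncomp.io`); BED is native 0-based half-open.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ProbeClass(str, enum.Enum):
    """Per-source probe classification."""

    MRNA = "mRNA"
    INTRONIC = "intronic_lncRNA"
    ANTISENSE = "antisense_lncRNA"
    LINCRNA = "lincRNA"
    AMBIGUOUS = "ambiguous"


class FinalClass(str, enum.Enum):
    MRNA = "mRNA"
    LNCRNA = "lncRNA"
    DISCARDED = "discarded"


class Subclass(str, enum.Enum):
    INTRONIC = "intronic"
    ANTISENSE = "antisense"
    LINCRNA = "lincRNA"
    NONE = "none"


class LincDistanceCategory(str, enum.Enum):
    """Distance stratum of an intergenic probe relative to its nearest gene.

    ``FAR`` (> 50 kb) is reported separately although conceptually a subset
    of "more than 1 kb away".
    """

    UTR_EXTENSION_CANDIDATE = "utr_extension_candidate"  # <= 1 kb, same strand
    DISTAL = "distal"  # > 1 kb (or close but opposite strand)
    FAR = "far"  # > 50 kb


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered, non-overlapping exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"gene {self.gene_id}: bad exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (may be empty for single-exon genes)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )


@dataclass(frozen=True)
class AnnotationSource:
    source_name: str
    genes: tuple[GeneModel, ...]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene_ids in source {self.source_name!r}")

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass(frozen=True)
class ProbeAlignment:
    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"probe {self.probe_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"probe {self.probe_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ConsensusLabel:
    """Final probe call after voting across annotation sources."""

    probe_id: str
    final_class: FinalClass
    subclass: Subclass = Subclass.NONE
    nearest_gene_id: Optional[str] = None
    nearest_gene_distance: Optional[int] = None
    same_strand_as_nearest: Optional[bool] = None
    distance_category: Optional[LincDistanceCategory] = None

    def __post_init__(self) -> None:
        if (self.subclass is not Subclass.NONE) != (self.final_class is FinalClass.LNCRNA):
            raise ValueError("subclass must be 'none' iff final_class is not lncRNA")
        if self.nearest_gene_distance is not None and self.nearest_gene_distance < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth from the simulator: every simulated probe appears once."""

    probe_class: dict[str, str] = field(default_factory=dict)
    probe_module: dict[str, str] = field(default_factory=dict)
    probe_tissues: dict[str, tuple[str, ...]] = field(default_factory=dict)
    module_hub: dict[str, str] = field(default_factory=dict)
    perturbed_genes: dict[str, tuple[str, str]] = field(default_factory=dict)
    linc_stratum: dict[str, str] = field(default_factory=dict)
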