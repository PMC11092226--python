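"""Core domain types shared by every stage of the pipeline.

The experimental design these types describe is a pair of inbred parents
(P1, the reference-like parent; P2, the alternate parent) and their two
reciprocal F1 hybrids (H12 = P1 x P2, H21 = P2 x P1), each profiled under a
set of conditions (by default four light treatments) with replicated
RNA-seq.  All genomic coordinates are 1-based closed intervals; BED input
is converted at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Genotype(str, enum.Enum):
    """The four genotypes of a reciprocal-hybrid design."""

    P1 = "P1"
    P2 = "P2"
    H12 = "H12"  # P1 (female) x P2 (male)
    H21 = "H21"  # P2 (female) x P1 (male)

    @property
    def is_hybrid(self) -> bool:
        return self in (Genotype.H12, Genotype.H21)

    @property
    def female_parent(self) -> "Genotype":
        if self is Genotype.H12:
            return Genotype.P1
        if self is Genotype.H21:
            return Genotype.P2
        raise ValueError(f"{self.value} is not a hybrid")


class Direction(str, enum.Enum):
    """Which parental allele is favored (NONE = balanced or untestable)."""

    P1 = "P1"
    P2 = "P2"
    NONE = "NONE"

    def flipped(self) -> "Direction":
        if self is Direction.P1:
            return Direction.P2
        if self is Direction.P2:
            return Direction.P1
        return Direction.NONE


class BiasClass(str, enum.Enum):
    """Cross-condition bias category of an allele-specifically expressed gene.

    BC (bias-consistent): same parental allele favored in every condition.
    BS (bias-specific): one allele favored in some but not all conditions.
    BR (bias-reversal): the favored allele switches between conditions
    (or, for the combined call, between reciprocal hybrids).
    """

    BC = "BC"
    BS = "BS"
    BR = "BR"
    NON_BIAS = "NON_BIAS"


DEFAULT_CONDITIONS: tuple[str, ...] = ("dark", "far_red", "red", "blue")


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identifies one RNA-seq library: genotype x condition x replicate."""

    genotype: Genotype
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    def __str__(self) -> str:
        return f"{self.genotype.value}:{self.condition}:{self.replicate}"

    @classmethod
    def parse(cls, label: str) -> "SampleKey":
        genotype, condition, replicate = label.split(":")
        return cls(Genotype(genotype), condition, int(replicate))


@dataclass
class AlleleCountRecord:
    """Read counts supporting each parental allele at one SNP in one sample."""

    gene_id: str
    snp_id: str
    chrom: str
    pos: int
    sample: SampleKey
    count_p1: int
    count_p2: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.count_p1 < 0 or self.count_p2 < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.count_p1 + self.count_p2


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


@dataclass
class VariantRecord:
    """One sequence variant (SNP or indel) with calling-quality metadata.

    ``allele_frequency`` and ``depth`` carry the caller's quality evidence
    and drive the pre-substitution filter; for fixed inter-parental
    differences they are conventionally 1.0 and a large depth.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float = 1.0
    depth: int = 100

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency must be in [0,1], got {self.allele_frequency}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNP
        if len(self.alt) > len(self.ref):
            return VariantClass.INS
        return VariantClass.DEL

    @property
    def is_snp(self) -> bool:
        return self.variant_class is VariantClass.SNP


@dataclass
class GeneModel:
    """A single-transcript gene model with a strand-aware TSS.

    ``cds_segments`` are 1-based closed intervals in genomic order.  The
    transcription start site is the interval start on '+' and the interval
    end on '-', so promoter extraction can always look strand-upstream.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.cds_segments:
            if s > e:
                raise ValueError(f"{self.gene_id}: CDS segment {s}-{e} inverted")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS segment {s}-{e} outside gene body")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)
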