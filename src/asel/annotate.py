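"""Coding-impact classification and promoter variant profiling.

Effects follow the standard four-tier impact scheme: frameshift and
start/stop-changing variants are HIGH; missense and in-frame indels are
MODERATE; synonymous SNPs are LOW; everything non-coding (intron/UTR,
promoter/upstream, downstream, intergenic) is MODIFIER.  Gene models are
single-transcript, so splice-site effects are out of scope.  Promoters
are the 3,000 bp strand-upstream of the TSS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .types import GeneModel, VariantClass, VariantRecord

DEFAULT_PROMOTER_WINDOW = 3000
DEFAULT_DOWNSTREAM_WINDOW = 1000
DEFAULT_HISTOGRAM_BIN = 100

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class Effect(str, enum.Enum):
    FRAMESHIFT = "frameshift"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    PROMOTER = "promoter/upstream"
    DOWNSTREAM = "downstream"
    INTRON_UTR = "intron/UTR"
    INTERGENIC = "intergenic"


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


EFFECT_IMPACT = {
    Effect.FRAMESHIFT: Impact.HIGH,
    Effect.STOP_GAINED: Impact.HIGH,
    Effect.STOP_LOST: Impact.HIGH,
    Effect.START_LOST: Impact.HIGH,
    Effect.INFRAME_INDEL: Impact.MODERATE,
    Effect.MISSENSE: Impact.MODERATE,
    Effect.SYNONYMOUS: Impact.LOW,
    Effect.PROMOTER: Impact.MODIFIER,
    Effect.DOWNSTREAM: Impact.MODIFIER,
    Effect.INTRON_UTR: Impact.MODIFIER,
    Effect.INTERGENIC: Impact.MODIFIER,
}


class ModelIntegrityError(ValueError):
    """Gene model inconsistent with its coding sequence."""


@dataclass
class ImpactCall:
    variant: VariantRecord
    gene_id: str
    effect: Effect

    @property
    def impact(self) -> Impact:
        return EFFECT_IMPACT[self.effect]


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced sense CDS."""
    offsets = []
    for s, e in gene.cds_segments:
        offsets.append((s, e))
    total = sum(e - s + 1 for s, e in offsets)
    running = 0
    for s, e in offsets:
        if s <= pos <= e:
            plus_offset = running + (pos - s)
            return plus_offset if gene.strand == "+" else total - 1 - plus_offset
        running += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")


def in_promoter(gene: GeneModel, pos: int, window: int = DEFAULT_PROMOTER_WINDOW) -> bool:
    if window <= 0:
        raise ValueError("window must be positive")
    if gene.strand == "+":
        return gene.tss - window <= pos <= gene.tss - 1
    return gene.tss + 1 <= pos <= gene.tss + window


def distance_to_tss(gene: GeneModel, pos: int) -> int:
    """Strand-aware upstream distance (positive in the promoter)."""
    return gene.tss - pos if gene.strand == "+" else pos - gene.tss


def _in_downstream(gene: GeneModel, pos: int, window: int) -> bool:
    if gene.strand == "+":
        return gene.end + 1 <= pos <= gene.end + window
    return gene.start - window <= pos <= gene.start - 1


def annotate_effect(
    variant: VariantRecord,
    gene: GeneModel,
    coding_sequence: str,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> ImpactCall:
    """Classify one variant's effect on one gene.

    ``coding_sequence`` is the spliced sense-strand CDS (starts with the
    start codon, ends with the stop codon).  SNPs in the CDS are decided
    codon-by-codon against the genetic code; indels by whether their
    length change is a multiple of three.  A variant outside the gene and
    its flanks is intergenic (MODIFIER), not an error.
    """
    if len(coding_sequence) % 3 != 0:
        raise ModelIntegrityError(
            f"{gene.gene_id}: CDS length {len(coding_sequence)} not divisible by 3"
        )
    if gene.in_cds(variant.pos):
        if variant.variant_class is not VariantClass.SNP:
            shift = abs(len(variant.ref) - len(variant.alt)) % 3
            effect = Effect.FRAMESHIFT if shift else Effect.INFRAME_INDEL
            return ImpactCall(variant, gene.gene_id, effect)
        return ImpactCall(variant, gene.gene_id, _snp_effect(variant, gene, coding_sequence))
    if gene.contains(variant.pos):
        return ImpactCall(variant, gene.gene_id, Effect.INTRON_UTR)
    if in_promoter(gene, variant.pos, promoter_window):
        return ImpactCall(variant, gene.gene_id, Effect.PROMOTER)
    if _in_downstream(gene, variant.pos, downstream_window):
        return ImpactCall(variant, gene.gene_id, Effect.DOWNSTREAM)
    return ImpactCall(variant, gene.gene_id, Effect.INTERGENIC)


def _snp_effect(variant: VariantRecord, gene: GeneModel, cds: str) -> Effect:
    offset = _cds_offset(gene, variant.pos)
    ref_base = variant.ref.upper()
    alt_base = variant.alt.upper()
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if cds[offset].upper() != ref_base:
        raise ModelIntegrityError(
            f"{gene.gene_id}: CDS base {cds[offset]!r} at offset {offset} "
            f"does not match variant ref {variant.ref!r} at {variant.chrom}:{variant.pos}"
        )
    codon_start = offset - offset % 3
    wt_codon = cds[codon_start : codon_start + 3].upper()
    mut_codon = (
        wt_codon[: offset % 3] + alt_base + wt_codon[offset % 3 + 1 :]
    )
    wt_aa = str(Seq(wt_codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if codon_start == 0 and wt_aa == "M" and mut_aa != "M":
        return Effect.START_LOST
    if wt_aa != "*" and mut_aa == "*":
        return Effect.STOP_GAINED
    if wt_aa == "*" and mut_aa != "*":
        return Effect.STOP_LOST
    if wt_aa == mut_aa:
        return Effect.SYNONYMOUS
    return Effect.MISSENSE


# -------------------------------------------------------- promoter profile

@dataclass
class PromoterProfile:
    """Variants in a gene's strand-aware promoter window."""

    gene_id: str
    window: int
    bin_width: int
    variants: list[VariantRecord] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)

    @property
    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) over distance-to-TSS; edges cover (0, window]."""
        edges = np.arange(0, self.window + self.bin_width, self.bin_width)
        counts, _ = np.histogram(self.distances, bins=edges)
        return counts, edges

    @property
    def class_counts(self) -> dict[str, int]:
        c = {"SNP": 0, "INS": 0, "DEL": 0}
        for v in self.variants:
            c[v.variant_class.value] += 1
        return c


def promoter_profile(
    variants: list[VariantRecord],
    gene: GeneModel,
    window: int = DEFAULT_PROMOTER_WINDOW,
    bin_width: int = DEFAULT_HISTOGRAM_BIN,
) -> PromoterProfile:
    """Collect variants within ``window`` bp strand-upstream of the TSS."""
    if window <= 0:
        raise ValueError("window must be positive")
    profile = PromoterProfile(gene_id=gene.gene_id, window=window, bin_width=bin_width)
    for v in variants:
        if v.chrom != gene.chrom:
            continue
        if in_promoter(gene, v.pos, window):
            profile.variants.append(v)
            profile.distances.append(distance_to_tss(gene, v.pos))
    return profile
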