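"""Variant filtering and SNP substitution into a reference sequence.

A pseudo-genome is the reference with the alternate parent's SNP alleles
written in, so that hybrid reads from either allele map with equal
identity.  Only confidently fixed variants are substituted: the filter
keeps records with allele frequency >= 0.9 and depth >= 20 by default.
Indels are never substituted (they would shift downstream coordinates);
any indel surviving the filter is dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .types import VariantRecord

logger = logging.getLogger("asel")


class IntegrityError(ValueError):
    """Reference base at a SNP position does not match the record's ref."""


@dataclass(frozen=True)
class FilterThresholds:
    """Quality gates applied before substitution."""

    min_allele_frequency: float = 0.9
    min_depth: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_allele_frequency <= 1.0:
            raise ValueError("min_allele_frequency must be in [0,1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def filter_variants(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Keep variants with AF >= min_allele_frequency AND depth >= min_depth.

    Order is preserved; the number of removed records is logged.
    """
    variants = list(variants)
    kept = [
        v
        for v in variants
        if v.allele_frequency >= thresholds.min_allele_frequency
        and v.depth >= thresholds.min_depth
    ]
    removed = len(variants) - len(kept)
    if removed:
        logger.info(
            "filter_variants: removed %d of %d records (AF < %g or depth < %d)",
            removed, len(variants),
            thresholds.min_allele_frequency, thresholds.min_depth,
        )
    return kept


def build_pseudogenome(
    reference: Mapping[str, str],
    variants: Iterable[VariantRecord],
) -> dict[str, str]:
    """Substitute SNP alt bases into the reference, chromosome by chromosome.

    Every record must be a SNP whose ref base matches the reference at its
    position; a mismatch is fatal (a silent substitution against the wrong
    base would corrupt allele assignment downstream).  Sequence lengths are
    unchanged.
    """
    out = {chrom: bytearray(seq, "ascii") for chrom, seq in reference.items()}
    n = 0
    for v in variants:
        if not v.is_snp:
            raise TypeError(
                f"build_pseudogenome accepts SNPs only; got "
                f"{v.variant_class.value} at {v.chrom}:{v.pos}"
            )
        if v.chrom not in out:
            raise IntegrityError(f"unknown chromosome {v.chrom!r}")
        seq = out[v.chrom]
        if v.pos > len(seq):
            raise IntegrityError(f"{v.chrom}:{v.pos} beyond sequence end ({len(seq)})")
        actual = chr(seq[v.pos - 1])
        if actual.upper() != v.ref.upper():
            raise IntegrityError(
                f"reference mismatch at {v.chrom}:{v.pos}: "
                f"expected {v.ref!r}, found {actual!r}"
            )
        seq[v.pos - 1] = ord(v.alt.upper())
        n += 1
    logger.info("build_pseudogenome: substituted %d SNPs", n)
    return {chrom: seq.decode("ascii") for chrom, seq in out.items()}


def snps_only(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop indels (with a logged warning), keeping SNPs in order."""
    variants = list(variants)
    snps = [v for v in variants if v.is_snp]
    dropped = len(variants) - len(snps)
    if dropped:
        logger.warning(
            "snps_only: excluded %d indel(s) from substitution "
            "(indels would shift coordinates)", dropped,
        )
    return snps
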