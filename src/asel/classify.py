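"""Cross-condition and cross-hybrid categorization of ASEGs.

Per hybrid, a gene's per-condition bias directions fall into one of four
classes: bias-consistent (BC, same parental allele favored in every
condition), bias-reversal (BR, both parental directions occur),
bias-specific (BS, a single direction in some but not all conditions) and
non-bias.  The combined call requires BC in BOTH reciprocal hybrids with
the same direction; a reversal in either hybrid, or opposing consensus
directions between hybrids, makes the gene BR; any remaining bias is BS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import ASEGCall, DEFAULT_MIN_TOTAL_DEPTH
from .types import AlleleCountRecord, BiasClass, Direction, Genotype


@dataclass
class HybridBias:
    """Per-hybrid classification of one gene."""

    gene_id: str
    hybrid: Genotype
    category: BiasClass
    direction: Direction  # consensus direction for BC/BS, NONE otherwise
    n_biased_conditions: int
    flagged: bool = False  # True when >= 1 condition was untestable


@dataclass
class BiasCategory:
    """Combined (both-hybrid) classification of one gene."""

    gene_id: str
    category: BiasClass
    direction: Direction  # consensus direction, defined for BC
    per_hybrid: dict[Genotype, HybridBias] = field(default_factory=dict)
    flagged: bool = False


def classify_gene(calls: Sequence[ASEGCall], conditions: Sequence[str]) -> HybridBias:
    """Classify one gene in one hybrid from its per-condition ASEG calls.

    Untestable conditions (no replicate passing the depth gate) are
    excluded from the rules and flag the gene rather than counting as
    balance; a missing condition call is an error.
    """
    if not calls:
        raise ValueError("no calls supplied")
    gene_ids = {c.gene_id for c in calls}
    hybrids = {c.hybrid for c in calls}
    if len(gene_ids) != 1 or len(hybrids) != 1:
        raise ValueError("calls must cover exactly one gene and one hybrid")
    by_condition = {c.condition: c for c in calls}
    missing = [c for c in conditions if c not in by_condition]
    if missing:
        raise ValueError(f"missing condition call(s): {', '.join(missing)}")

    testable = [by_condition[c] for c in conditions if by_condition[c].testable]
    flagged = len(testable) < len(conditions)
    directions = [c.direction for c in testable]
    non_none = [d for d in directions if d is not Direction.NONE]
    has_p1 = Direction.P1 in non_none
    has_p2 = Direction.P2 in non_none

    if has_p1 and has_p2:
        category, direction = BiasClass.BR, Direction.NONE
    elif not non_none:
        category, direction = BiasClass.NON_BIAS, Direction.NONE
    elif len(non_none) == len(testable) and len(testable) > 0:
        category, direction = BiasClass.BC, non_none[0]
    else:
        category, direction = BiasClass.BS, non_none[0]
    return HybridBias(
        gene_id=calls[0].gene_id, hybrid=calls[0].hybrid,
        category=category, direction=direction,
        n_biased_conditions=len(non_none), flagged=flagged,
    )


def combine_hybrids(h12: HybridBias, h21: HybridBias) -> BiasCategory:
    """Merge the two reciprocal-hybrid classifications of one gene.

    Reported BC requires BC in both hybrids with the same direction
    (the shared-BC intersection); a reversal within either hybrid or
    opposing consensus directions between hybrids gives BR; any other
    bias gives BS.
    """
    if h12.gene_id != h21.gene_id:
        raise ValueError(f"gene mismatch: {h12.gene_id!r} vs {h21.gene_id!r}")
    per_hybrid = {h12.hybrid: h12, h21.hybrid: h21}
    flagged = h12.flagged or h21.flagged
    cats = (h12.category, h21.category)
    opposing = (
        h12.direction is not Direction.NONE
        and h21.direction is not Direction.NONE
        and h12.direction is not h21.direction
    )
    if BiasClass.BR in cats or opposing:
        category, direction = BiasClass.BR, Direction.NONE
    elif cats == (BiasClass.BC, BiasClass.BC) and h12.direction is h21.direction:
        category, direction = BiasClass.BC, h12.direction
    elif all(c is BiasClass.NON_BIAS for c in cats):
        category, direction = BiasClass.NON_BIAS, Direction.NONE
    else:
        category = BiasClass.BS
        direction = h12.direction if h12.direction is not Direction.NONE else h21.direction
    return BiasCategory(
        gene_id=h12.gene_id, category=category, direction=direction,
        per_hybrid=per_hybrid, flagged=flagged,
    )


def classify_all(
    calls: Iterable[ASEGCall], conditions: Sequence[str]
) -> list[BiasCategory]:
    """Classify every gene with calls in both hybrids across all conditions."""
    by_gene_hybrid: dict[tuple[str, Genotype], list[ASEGCall]] = {}
    for c in calls:
        by_gene_hybrid.setdefault((c.gene_id, c.hybrid), []).append(c)
    genes = sorted({g for g, _ in by_gene_hybrid})
    out = []
    for gene in genes:
        h12_calls = by_gene_hybrid.get((gene, Genotype.H12))
        h21_calls = by_gene_hybrid.get((gene, Genotype.H21))
        if h12_calls is None or h21_calls is None:
            raise ValueError(f"gene {gene!r} lacks calls for one hybrid")
        out.append(
            combine_hybrids(
                classify_gene(h12_calls, conditions),
                classify_gene(h21_calls, conditions),
            )
        )
    return out


# ------------------------------------------------------------- bias ratios

def bias_ratio_table(
    records: Iterable[AlleleCountRecord],
    min_total_depth: int = DEFAULT_MIN_TOTAL_DEPTH,
) -> pd.DataFrame:
    """Gene x (hybrid, condition) table of P1-allele fractions.

    Per replicate, the gene's SNP counts are summed; replicates below the
    depth gate are dropped; the ratio is the mean over surviving
    replicates.  Cells with no surviving replicate are NaN (flagged, not
    imputed).
    """
    sums: dict[tuple, list[int]] = {}
    for r in records:
        if not r.sample.genotype.is_hybrid:
            continue
        key = (r.gene_id, r.sample.genotype.value, r.sample.condition, r.sample.replicate)
        cell = sums.setdefault(key, [0, 0])
        cell[0] += r.count_p1
        cell[1] += r.count_p2
    ratios: dict[tuple, list[float]] = {}
    for (gene, hybrid, condition, _rep), (a, b) in sums.items():
        if a + b >= min_total_depth:
            ratios.setdefault((gene, hybrid, condition), []).append(a / (a + b))
    if not ratios:
        return pd.DataFrame()
    ser = pd.Series(
        {k: float(np.mean(v)) for k, v in ratios.items()},
    )
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["gene_id", "hybrid", "condition"])
    return ser.unstack(["hybrid", "condition"]).sort_index()


def bias_ratio_correlation(table: pd.DataFrame) -> float:
    """R^2 of P1-allele fractions between the reciprocal hybrids.

    Pairs every gene x condition cell defined in both hybrids; squared
    Pearson correlation (sign-blind by construction).
    """
    if table.empty or Genotype.H12.value not in table.columns.get_level_values(0):
        raise ValueError("need a table with both hybrid column blocks")
    h12 = table[Genotype.H12.value].stack()
    h21 = table[Genotype.H21.value].stack()
    paired = pd.concat([h12, h21], axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(f"need >= 3 paired cells, got {len(paired)}")
    r = np.corrcoef(paired.iloc[:, 0], paired.iloc[:, 1])[0, 1]
    return float(r**2)


# ----------------------------------------------------------------- summary

def percent(numerator: int, denominator: int) -> str:
    """Percentage string with 2 decimals, half-up — '28.40%' for 1350/4754."""
    if denominator == 0:
        return "0.00%"
    value = Decimal(numerator) / Decimal(denominator) * 100
    return f"{value.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


def summarize_categories(
    categories: Sequence[BiasCategory],
    calls: Iterable[ASEGCall] = (),
) -> dict:
    """Counting report over a classified gene set.

    Emits per-category and per-direction counts with percentage strings,
    plus how many genes are biased in exactly 1/2/3/4+ conditions (union
    of conditions biased in either hybrid).
    """
    n = len(categories)
    by_cat = {bc: [c for c in categories if c.category is bc] for bc in BiasClass}
    n_aseg = sum(len(v) for bc, v in by_cat.items() if bc is not BiasClass.NON_BIAS)

    def direction_counts(items: Sequence[BiasCategory]) -> dict:
        d = {
            Direction.P1.value: sum(1 for c in items if c.direction is Direction.P1),
            Direction.P2.value: sum(1 for c in items if c.direction is Direction.P2),
        }
        total = len(items)
        return {
            "counts": d,
            "percent": {k: percent(v, total) for k, v in d.items()},
        }

    multiplicity: dict[int, int] = {}
    biased_asegs = [c for c in categories if c.category is not BiasClass.NON_BIAS]
    cond_by_gene: dict[str, set[str]] = {}
    for call in calls:
        if call.is_aseg:
            cond_by_gene.setdefault(call.gene_id, set()).add(call.condition)
    for c in biased_asegs:
        k = len(cond_by_gene.get(c.gene_id, set()))
        multiplicity[k] = multiplicity.get(k, 0) + 1

    return {
        "n_genes": n,
        "n_aseg": n_aseg,
        "categories": {
            bc.value: {"count": len(v), "percent": percent(len(v), n)}
            for bc, v in by_cat.items()
        },
        "direction_within": {
            bc.value: direction_counts(v)
            for bc, v in by_cat.items()
            if bc in (BiasClass.BC, BiasClass.BS)
        },
        "condition_multiplicity": {
            str(k): {
                "count": v,
                "percent": percent(v, len(biased_asegs)),
            }
            for k, v in sorted(multiplicity.items())
        },
    }
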