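"""Synthetic-data generation with planted ground truth for every stage.

The generator emulates the study design the pipeline targets: two inbred
parents and their reciprocal F1 hybrids under four light conditions with
three replicates.  Hybrid allele counts follow a negative-binomial total
depth split binomially between the parental alleles at the gene's planted
bias ratio; parents are fully homozygous and only ever show their own
allele.  Separate generators plant promoter/CDS variants on a toy genome
and two-population haplotypes with a diversity reduction (sweep) in the
derived population.  Identical seed and configuration give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import HaplotypeMatrix
from .patterns import _DECISION_TABLE, PatternType, State
from .types import (
    DEFAULT_CONDITIONS,
    AlleleCountRecord,
    GeneModel,
    Genotype,
    SampleKey,
    VariantRecord,
)

BIAS_CATEGORIES = ("BC_P1", "BC_P2", "BS", "BR", "NONE")

# mean of 2 f (1 - f) for f ~ Uniform(0.05, 0.95): per-site expected pi of
# a segregating site under binomial haplotype sampling
_SEG_SITE_PI = 2 * (0.5 - ((0.95 - 0.05) ** 2 / 12 + 0.25))


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for the allele-count generator.

    Defaults mirror the emulated design: 4 conditions x 3 replicates,
    ~50 allele-informative reads per gene per sample, favored-allele
    fraction 0.7 for biased genes, and a category mix skewed toward
    P2-ward bias (the direction imbalance seen in reciprocal maize
    hybrids).
    """

    n_genes: int = 200
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    depth_mean: float = 50.0
    snps_per_gene: int = 2
    overdispersion: float = 0.05
    bias_ratio: float = 0.7
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "BC_P1": 0.04, "BC_P2": 0.06, "BS": 0.20, "BR": 0.05, "NONE": 0.65,
        }
    )
    bs_p1_fraction: float = 0.3
    pattern_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 0.35, "dominant": 0.30, "overdominant": 0.15, "no_change": 0.20,
        }
    )
    expression_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if not 0 < self.bias_ratio < 1:
            raise ConfigError("bias_ratio must be in (0, 1)")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion must be >= 0")
        if self.snps_per_gene < 1:
            raise ConfigError("snps_per_gene must be >= 1")
        if set(self.category_proportions) != set(BIAS_CATEGORIES):
            raise ConfigError(f"category_proportions must cover {BIAS_CATEGORIES}")
        if abs(sum(self.category_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("category proportions must sum to 1")
        if abs(sum(self.pattern_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("pattern proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset."""

    bias_category: dict[str, str] = field(default_factory=dict)
    bias_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    pattern_type: dict[str, str | None] = field(default_factory=dict)
    promoter_variants: dict[str, list[int]] = field(default_factory=dict)
    cds_variants: dict[str, list[int]] = field(default_factory=dict)
    sweep_interval: tuple[int, int] | None = None
    sweep_population: str | None = None
    qtl_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _gene_ids(n: int) -> list[str]:
    return [f"gene{str(i + 1).zfill(5)}" for i in range(n)]


def _draw_total(rng: np.random.Generator, mean: float, overdispersion: float, size: int):
    """Negative-binomial totals with Var = mean + overdispersion * mean^2."""
    if overdispersion == 0:
        return rng.poisson(mean, size=size)
    n_param = 1.0 / overdispersion
    p_param = n_param / (n_param + mean)
    return rng.negative_binomial(n_param, p_param, size=size)


def _plant_bias(
    rng: np.random.Generator, config: SimulationConfig, category: str
) -> dict[str, float]:
    """Per-condition P1-allele fraction for one gene of the given category."""
    r, conds = config.bias_ratio, list(config.conditions)
    if category == "BC_P1":
        return {c: r for c in conds}
    if category == "BC_P2":
        return {c: 1 - r for c in conds}
    if category == "NONE":
        return {c: 0.5 for c in conds}
    if category == "BS":
        toward_p1 = rng.random() < config.bs_p1_fraction
        k = int(rng.integers(1, len(conds)))  # biased in 1..n-1 conditions
        biased = rng.choice(len(conds), size=k, replace=False)
        ratio = r if toward_p1 else 1 - r
        return {c: (ratio if i in biased else 0.5) for i, c in enumerate(conds)}
    if category == "BR":
        while True:
            sides = rng.random(len(conds)) < 0.5
            if sides.any() and not sides.all():
                break
        return {c: (r if sides[i] else 1 - r) for i, c in enumerate(conds)}
    raise ConfigError(f"unknown bias category {category!r}")


def simulate_allele_counts(
    config: SimulationConfig,
) -> tuple[list[AlleleCountRecord], GroundTruth]:
    """Generate a full per-SNP allele-count table with planted bias.

    Hybrids of both cross directions share each gene's planted ratios (the
    reciprocal hybrids of inbred parents see the same cis landscape);
    parents receive reads only for their own allele.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    cats = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in cats])
    assignments = rng.choice(len(cats), size=config.n_genes, p=probs)

    truth = GroundTruth()
    records: list[AlleleCountRecord] = []
    samples = [
        SampleKey(gt, cond, rep)
        for gt in Genotype
        for cond in config.conditions
        for rep in range(1, config.n_replicates + 1)
    ]
    snp_probs = np.full(config.snps_per_gene, 1.0 / config.snps_per_gene)
    for gi, gene in enumerate(genes):
        category = cats[assignments[gi]]
        ratios = _plant_bias(rng, config, category)
        truth.bias_category[gene] = category
        truth.bias_ratios[gene] = ratios
        chrom, gene_start = "chr1", gi * 10_000 + 1
        snp_pos = gene_start + 100 * np.arange(config.snps_per_gene)
        for sample in samples:
            total = int(_draw_total(rng, config.depth_mean, config.overdispersion, 1)[0])
            per_snp = rng.multinomial(total, snp_probs)
            for si in range(config.snps_per_gene):
                t = int(per_snp[si])
                if sample.genotype is Genotype.P1:
                    a, b = t, 0
                elif sample.genotype is Genotype.P2:
                    a, b = 0, t
                else:
                    a = int(rng.binomial(t, ratios[sample.condition]))
                    b = t - a
                records.append(
                    AlleleCountRecord(
                        gene_id=gene, snp_id=f"{gene}_snp{si + 1}",
                        chrom=chrom, pos=int(snp_pos[si]), sample=sample,
                        count_p1=a, count_p2=b,
                    )
                )
    return records, truth


# ------------------------------------------------------------- expression

# parent low/high chosen so every planted contrast clears the 1.5-fold
# gate with a clear margin at 3 replicates: parents differ 6-fold, an
# additive hybrid sits at their geometric mean (~2.4-fold from each) and
# transgressive hybrids are >= 2-fold outside the parental range
_PATTERN_MEANS = {"lo": 40.0, "mid": 100.0, "hi": 240.0, "over_hi": 500.0, "over_lo": 16.0}

_STATES_BY_TYPE = {t: s for s, t in _DECISION_TABLE.items()}


def _pattern_means(ptype: PatternType | None) -> tuple[float, float, float]:
    """(P1, P2, H) mean TPM implementing one pattern type's contrast states."""
    m = _PATTERN_MEANS
    if ptype is None:
        return m["mid"], m["mid"], m["mid"]
    d_p, d_1, d_2 = _STATES_BY_TYPE[ptype]
    p1 = {State.UP: m["hi"], State.DOWN: m["lo"], State.NS: m["mid"]}[d_p]
    p2 = {State.UP: m["lo"], State.DOWN: m["hi"], State.NS: m["mid"]}[d_p]
    if d_1 is State.NS:  # hybrid matches P1
        h = p1
    elif d_2 is State.NS:  # hybrid matches P2
        h = p2
    elif (d_1, d_2) == (State.UP, State.UP):
        h = m["over_hi"]
    elif (d_1, d_2) == (State.DOWN, State.DOWN):
        h = m["over_lo"]
    else:  # additive: between the parents, geometric mean for equal folds
        h = float(np.sqrt(p1 * p2))
    return p1, p2, h


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a TPM matrix with planted hybrid expression patterns.

    Each gene gets one pattern type (both hybrids, all conditions);
    replicate TPMs are the type's means under multiplicative lognormal
    noise with the configured coefficient of variation.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_genes)
    groups = list(config.pattern_proportions)
    probs = np.array([config.pattern_proportions[g] for g in groups])
    by_group = {
        "additive": [PatternType.I, PatternType.II],
        "dominant": [PatternType.III, PatternType.IV, PatternType.V, PatternType.VI],
        "overdominant": [
            PatternType.VII, PatternType.VIII, PatternType.IX,
            PatternType.X, PatternType.XI, PatternType.XII,
        ],
        "no_change": [None],
    }
    truth = GroundTruth()
    sigma = config.expression_cv
    columns = pd.MultiIndex.from_tuples(
        [
            (gt.value, cond, rep)
            for gt in Genotype
            for cond in config.conditions
            for rep in range(1, config.n_replicates + 1)
        ],
        names=["genotype", "condition", "replicate"],
    )
    data = np.empty((config.n_genes, len(columns)))
    for gi, gene in enumerate(genes):
        group = groups[int(rng.choice(len(groups), p=probs))]
        ptype = by_group[group][int(rng.integers(len(by_group[group])))]
        truth.pattern_type[gene] = ptype.value if ptype is not None else None
        p1, p2, h = _pattern_means(ptype)
        means = {"P1": p1, "P2": p2, "H12": h, "H21": h}
        for ci, (gt, _cond, _rep) in enumerate(columns):
            noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma)
            data[gi, ci] = means[gt] * noise
    return pd.DataFrame(data, index=genes, columns=columns), truth


# ---------------------------------------------------------------- variants

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


_REVCOMP = str.maketrans("ACGT", "TGCA")


def simulate_parental_variants(
    n_genes: int,
    promoter_density: float = 0.005,
    cds_density: float = 0.002,
    class_mix: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    promoter_window: int = 3000,
    cds_length: int = 1200,
) -> tuple[list[VariantRecord], list[GeneModel], dict[str, str], GroundTruth]:
    """Plant promoter and CDS variants between two parental genomes.

    Builds a toy chromosome of single-exon genes on alternating strands,
    each with a clean reading frame, then scatters variants uniformly at
    the given per-bp densities (counts are Poisson).  ``class_mix`` gives
    the SNP/INS/DEL proportions; indel lengths are 1-6 bp.  Variants
    represent fixed differences (AF 1.0, depth 100).
    """
    if min(promoter_density, cds_density) < 0:
        raise ConfigError("densities must be non-negative")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ConfigError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    slot = promoter_window + cds_length + promoter_window + 1000
    chrom = "chr1"
    length = n_genes * slot + 1000
    seq = rng.choice(_BASES, size=length)

    genes: list[GeneModel] = []
    truth = GroundTruth()
    for gi in range(n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        body_start = gi * slot + promoter_window + 1
        body_end = body_start + cds_length - 1
        cds = _random_cds(rng, cds_length // 3)
        oriented = cds if strand == "+" else cds[::-1].translate(_REVCOMP)
        seq[body_start - 1 : body_end] = list(oriented)
        genes.append(
            GeneModel(
                gene_id=f"gene{str(gi + 1).zfill(5)}", chrom=chrom,
                start=body_start, end=body_end, strand=strand,
                cds_segments=[(body_start, body_end)],
            )
        )
    sequence = "".join(seq)

    variants: list[VariantRecord] = []
    classes = ("SNP", "INS", "DEL")
    for gene in genes:
        if gene.strand == "+":
            prom = (gene.tss - promoter_window, gene.tss - 1)
        else:
            prom = (gene.tss + 1, gene.tss + promoter_window)
        regions = [("promoter", prom, promoter_density), ("cds", (gene.start, gene.end), cds_density)]
        truth.promoter_variants[gene.gene_id] = []
        truth.cds_variants[gene.gene_id] = []
        for region_name, (lo, hi), density in regions:
            n = int(rng.poisson(density * (hi - lo + 1)))
            if n == 0:
                continue
            positions = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(n, hi - lo + 1), replace=False))
            for pos in positions:
                pos = int(pos)
                vclass = classes[int(rng.choice(3, p=class_mix))]
                ref_base = sequence[pos - 1]
                if vclass == "SNP":
                    alt = str(rng.choice(_BASES[_BASES != ref_base]))
                    ref = ref_base
                elif vclass == "INS":
                    ins_len = int(rng.integers(1, 7))
                    ref = ref_base
                    alt = ref_base + "".join(rng.choice(_BASES, size=ins_len))
                else:
                    del_len = int(rng.integers(1, 7))
                    end = min(pos + del_len, len(sequence))
                    ref = sequence[pos - 1 : end]
                    alt = ref_base
                    if len(ref) < 2:
                        continue
                variants.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt))
                getattr(truth, f"{region_name}_variants")[gene.gene_id].append(pos)
    variants.sort(key=lambda v: v.pos)
    return variants, genes, {chrom: sequence}, truth


# -------------------------------------------------------------- haplotypes

def simulate_two_population_haplotypes(
    n_pop1: int = 23,
    n_pop2: int = 200,
    region_length: int = 210_000,
    sweep_interval: tuple[int, int] | None = None,
    pi_background: float = 0.006,
    pi_sweep_factor: float = 0.2,
    seed: int = 0,
    region_start: int = 1,
    populations: tuple[str, str] = ("pop1", "pop2"),
) -> tuple[HaplotypeMatrix, HaplotypeMatrix, GroundTruth]:
    """Two-population haplotypes with a planted diversity reduction.

    Each bp segregates independently with a probability tuned so the
    expected per-bp pi equals ``pi_background``; inside ``sweep_interval``
    the second population's segregation probability is multiplied by
    ``pi_sweep_factor`` (< 1 plants a selected locus).  Site frequencies
    are Uniform(0.05, 0.95) and haplotypes are binomial draws, so the
    pairwise estimator is unbiased for the planted value.
    """
    if n_pop1 < 2 or n_pop2 < 2:
        raise ConfigError("each population needs >= 2 haplotypes (pi undefined otherwise)")
    if not 0 < pi_background < _SEG_SITE_PI:
        raise ConfigError(f"pi_background must be in (0, {_SEG_SITE_PI:.3f})")
    if pi_sweep_factor < 0:
        raise ConfigError("pi_sweep_factor must be >= 0")
    if sweep_interval is None:
        mid = region_start + region_length // 2
        sweep_interval = (mid - 5000, mid + 4999)
    rng = np.random.default_rng(seed)
    base_rate = pi_background / _SEG_SITE_PI
    region_end = region_start + region_length - 1

    def one_population(n_hap: int, population: str, sweep: bool) -> HaplotypeMatrix:
        rates = np.full(region_length, base_rate)
        if sweep:
            lo = max(sweep_interval[0], region_start) - region_start
            hi = min(sweep_interval[1], region_end) - region_start
            rates[lo : hi + 1] *= pi_sweep_factor
        segregating = rng.random(region_length) < rates
        positions = np.flatnonzero(segregating) + region_start
        freqs = rng.uniform(0.05, 0.95, size=positions.size)
        matrix = (rng.random((n_hap, positions.size)) < freqs).astype(np.int8)
        return HaplotypeMatrix(
            positions=positions, matrix=matrix,
            region_start=region_start, region_length=region_length,
            population=population,
        )

    hm1 = one_population(n_pop1, populations[0], sweep=False)
    hm2 = one_population(n_pop2, populations[1], sweep=pi_sweep_factor != 1.0)
    truth = GroundTruth(sweep_interval=sweep_interval, sweep_population=populations[1])
    return hm1, hm2, truth


# ------------------------------------------------------------- QTL overlap

def simulate_qtl_gene_set(
    truth: GroundTruth,
    seed: int = 0,
    p_biased: float = 0.35,
    p_none: float = 0.12,
) -> list[str]:
    """A trait-locus gene set genuinely enriched for planted biased genes."""
    rng = np.random.default_rng(seed)
    qtl = []
    for gene, cat in sorted(truth.bias_category.items()):
        p = p_none if cat == "NONE" else p_biased
        if rng.random() < p:
            qtl.append(gene)
    truth.qtl_genes = qtl
    return qtl
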