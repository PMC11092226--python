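"""Sliding-window nucleotide diversity (pi) and two-population sweep contrast.

Per-site pi is the unbiased pairwise estimator: the number of differing
haplotype pairs among non-missing calls divided by C(m, 2).  Window pi is
the sum of per-site values over the window divided by the window width in
bp (monomorphic and unrepresented positions contribute zero), computed on
a sliding grid (default width 1,000 bp, jump 300 bp).  A domestication
sweep shows as reduced pi in the derived population (maize) relative to
the wild baseline (teosinte) around the selected gene; the contrast
summarizes 100-kb upstream, gene and 100-kb downstream blocks with
per-block pi ratios and a one-sided rank-sum comparison of window values
(an added convenience statistic, labeled as such in output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_WIDTH = 1000
DEFAULT_JUMP = 300
DEFAULT_FLANK = 100_000

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Haplotypes x segregating sites, with 1-based site positions.

    Allele codes are small non-negative integers; ``MISSING`` (-1) marks
    missing calls.  Positions are strictly increasing and live on
    [region_start, region_start + region_length - 1]; positions absent
    from the matrix are monomorphic.
    """

    positions: np.ndarray
    matrix: np.ndarray  # (n_haplotypes, n_sites)
    region_start: int
    region_length: int
    population: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if self.matrix.shape[0] < 2:
            raise ValueError(
                f"need >= 2 haplotypes (pi undefined for {self.matrix.shape[0]})"
            )
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("positions and matrix site dimension disagree")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def region_end(self) -> int:
        return self.region_start + self.region_length - 1


def site_pi(alleles: np.ndarray) -> float:
    """Unbiased per-site pi: differing pairs / all pairs over non-missing calls.

    Raises for fewer than two non-missing haplotypes (the caller decides
    whether to skip such sites).
    """
    alleles = np.asarray(alleles)
    alleles = alleles[alleles != MISSING]
    m = alleles.size
    if m < 2:
        raise ValueError(f"site pi undefined for {m} non-missing haplotype(s)")
    _, counts = np.unique(alleles, return_counts=True)
    total_pairs = m * (m - 1) // 2
    same_pairs = int(np.sum(counts * (counts - 1) // 2))
    return (total_pairs - same_pairs) / total_pairs


def site_pi_all(hm: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site pi; returns (pi, defined) arrays over sites.

    Sites with < 2 non-missing calls get pi 0 and defined False (skipped
    with a flag rather than imputed).
    """
    mat = hm.matrix
    n_sites = mat.shape[1]
    present = mat != MISSING
    m = present.sum(axis=0)
    max_allele = int(mat.max(initial=0))
    same_pairs = np.zeros(n_sites, dtype=np.int64)
    for a in range(max_allele + 1):
        c = np.sum((mat == a) & present, axis=0)
        same_pairs += c * (c - 1) // 2
    total_pairs = m * (m - 1) // 2
    defined = m >= 2
    pi = np.zeros(n_sites, dtype=float)
    np.divide(
        total_pairs - same_pairs, total_pairs,
        out=pi, where=total_pairs > 0,
    )
    pi[~defined] = 0.0
    return pi, defined


@dataclass
class DiversityProfile:
    """Windowed pi along one region for one population."""

    population: str
    width: int
    jump: int
    window_starts: np.ndarray  # 1-based window start positions
    pi: np.ndarray  # per-bp pi per window
    n_skipped_sites: int = 0
    blocks: dict[str, float] = field(default_factory=dict)

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + (self.width - 1) / 2

    @property
    def n_windows(self) -> int:
        return len(self.pi)


def window_pi(
    hm: HaplotypeMatrix,
    width: int = DEFAULT_WIDTH,
    jump: int = DEFAULT_JUMP,
) -> DiversityProfile:
    """Sliding-window pi: windows of ``width`` bp advancing by ``jump`` bp.

    Window count is floor((L - width)/jump) + 1 for region length
    L >= width; a shorter region is an error.
    """
    if width <= 0 or jump <= 0:
        raise ValueError("width and jump must be positive")
    if hm.region_length < width:
        raise ValueError(
            f"region length {hm.region_length} shorter than window width {width}"
        )
    pi_sites, defined = site_pi_all(hm)
    n_windows = (hm.region_length - width) // jump + 1
    starts = hm.region_start + jump * np.arange(n_windows, dtype=np.int64)
    # per-site values summed into windows via cumulative sums over sites
    csum = np.concatenate([[0.0], np.cumsum(pi_sites)])
    lo = np.searchsorted(hm.positions, starts, side="left")
    hi = np.searchsorted(hm.positions, starts + width - 1, side="right")
    window_sums = csum[hi] - csum[lo]
    return DiversityProfile(
        population=hm.population, width=width, jump=jump,
        window_starts=starts, pi=window_sums / width,
        n_skipped_sites=int(np.sum(~defined)),
    )


# ------------------------------------------------------------- sweep scan

@dataclass
class BlockContrast:
    block: str
    pi_pop1: float
    pi_pop2: float
    ratio: float  # pi_pop1 / pi_pop2 (inf when pop2 block is monomorphic)
    rank_sum_p: float  # one-sided (pop1 > pop2); an added statistic
    n_windows: int


@dataclass
class SweepSummary:
    gene_interval: tuple[int, int]
    flank: int
    blocks: dict[str, BlockContrast]


def _assign_blocks(
    centers: np.ndarray, gene_interval: tuple[int, int], flank: int
) -> dict[str, np.ndarray]:
    gs, ge = gene_interval
    return {
        "upstream": (centers >= gs - flank) & (centers < gs),
        "gene": (centers >= gs) & (centers <= ge),
        "downstream": (centers > ge) & (centers <= ge + flank),
    }


def flank_contrast(
    profile1: DiversityProfile,
    profile2: DiversityProfile,
    gene_interval: tuple[int, int],
    flank: int = DEFAULT_FLANK,
) -> SweepSummary:
    """Block-wise diversity contrast between two populations.

    Both profiles must be computed on identical window grids.  Windows are
    assigned to the upstream / gene / downstream blocks by window center;
    block pi is the unweighted mean of window values.
    """
    if (
        profile1.width != profile2.width
        or profile1.jump != profile2.jump
        or not np.array_equal(profile1.window_starts, profile2.window_starts)
    ):
        raise ValueError("profiles must share an identical window grid")
    masks = _assign_blocks(profile1.window_centers, gene_interval, flank)
    blocks = {}
    for name, mask in masks.items():
        w1, w2 = profile1.pi[mask], profile2.pi[mask]
        mean1 = float(w1.mean()) if w1.size else math.nan
        mean2 = float(w2.mean()) if w2.size else math.nan
        if mean2 == 0.0:
            ratio = math.inf if mean1 > 0 else math.nan
        else:
            ratio = mean1 / mean2
        if w1.size and w2.size and (np.ptp(w1) > 0 or np.ptp(w2) > 0):
            p = float(stats.mannwhitneyu(w1, w2, alternative="greater").pvalue)
        else:
            p = 1.0
        blocks[name] = BlockContrast(
            block=name, pi_pop1=mean1, pi_pop2=mean2, ratio=ratio,
            rank_sum_p=p, n_windows=int(mask.sum()),
        )
    return SweepSummary(gene_interval=gene_interval, flank=flank, blocks=blocks)
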