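"""Per-site and windowed nucleotide diversity against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from asel.diversity import (
    MISSING,
    HaplotypeMatrix,
    flank_contrast,
    site_pi,
    site_pi_all,
    window_pi,
)


def brute_force_site_pi(alleles):
    alleles = [a for a in alleles if a != MISSING]
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def hm(matrix, positions=None, region_start=1, region_length=None, population=""):
    matrix = np.asarray(matrix, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, matrix.shape[1] + 1)
    if region_length is None:
        region_length = int(np.max(positions)) - region_start + 1
    return HaplotypeMatrix(positions=np.asarray(positions), matrix=matrix,
                           region_start=region_start, region_length=region_length,
                           population=population)


class TestSitePi:
    def test_monomorphic(self):
        assert site_pi(np.array([0, 0, 0, 0])) == 0.0

    def test_single_differing_pair(self):
        assert site_pi(np.array([0, 1])) == 1.0

    def test_two_by_two(self):
        # 4 differing pairs of 6 total
        assert site_pi(np.array([0, 0, 1, 1])) == pytest.approx(2 / 3)

    def test_multiallelic_matches_brute_force(self, rng):
        for _ in range(50):
            alleles = rng.integers(0, 3, size=int(rng.integers(2, 12)))
            assert site_pi(alleles) == pytest.approx(brute_force_site_pi(alleles))

    def test_missing_reduces_pairs(self):
        alleles = np.array([0, 1, MISSING, MISSING])
        assert site_pi(alleles) == 1.0

    def test_fewer_than_two_calls_rejected(self):
        with pytest.raises(ValueError):
            site_pi(np.array([0, MISSING, MISSING]))

    def test_vectorized_flags_undefined_sites(self):
        matrix = hm([[0, 0], [1, MISSING], [MISSING, MISSING]])
        pi, defined = site_pi_all(matrix)
        assert pi[0] == pytest.approx(1.0)
        assert not defined[1] and pi[1] == 0.0


class TestWindowPi:
    def test_no_segregating_sites(self):
        matrix = hm([[0, 0], [0, 0]], positions=[10, 20], region_length=2000)
        profile = window_pi(matrix, width=1000, jump=300)
        assert np.all(profile.pi == 0.0)

    def test_single_site_scaled_by_width(self):
        matrix = hm([[0], [1]], positions=[500], region_length=1000)
        profile = window_pi(matrix, width=1000, jump=300)
        assert profile.n_windows == 1
        assert profile.pi[0] == pytest.approx(0.001)

    def test_window_count_formula(self):
        matrix = hm([[0, 1], [1, 0]], positions=[1, 2], region_length=5000)
        profile = window_pi(matrix, width=1000, jump=300)
        assert profile.n_windows == (5000 - 1000) // 300 + 1

    def test_region_shorter_than_width_rejected(self):
        matrix = hm([[0], [1]], positions=[5], region_length=500)
        with pytest.raises(ValueError):
            window_pi(matrix, width=1000)

    def test_matches_brute_force_hamming(self, rng):
        """Random 4 x 50 matrices equal the naive all-pairs oracle."""
        for _ in range(20):
            n_sites = 50
            region_length = 3000
            positions = np.sort(rng.choice(region_length, size=n_sites, replace=False)) + 1
            matrix = rng.integers(0, 2, size=(4, n_sites)).astype(np.int8)
            m = hm(matrix, positions=positions, region_length=region_length)
            profile = window_pi(m, width=1000, jump=300)
            for start, value in zip(profile.window_starts, profile.pi):
                in_win = (positions >= start) & (positions <= start + 999)
                total = 0.0
                for col in np.flatnonzero(in_win):
                    pairs = list(itertools.combinations(matrix[:, col], 2))
                    total += sum(a != b for a, b in pairs) / len(pairs)
                assert value == pytest.approx(total / 1000, abs=1e-12)

    def test_haplotype_order_invariance(self, rng):
        positions = np.sort(rng.choice(5000, size=80, replace=False)) + 1
        matrix = rng.integers(0, 2, size=(10, 80)).astype(np.int8)
        base = window_pi(hm(matrix, positions=positions, region_length=5000))
        shuffled = matrix[rng.permutation(10)]
        perm = window_pi(hm(shuffled, positions=positions, region_length=5000))
        assert np.allclose(base.pi, perm.pi)

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError, match="2 haplotypes"):
            hm([[0, 1]])


class TestFlankContrast:
    def test_identical_populations(self, rng):
        positions = np.sort(rng.choice(30_000, size=300, replace=False)) + 1
        matrix = rng.integers(0, 2, size=(6, 300)).astype(np.int8)
        p = window_pi(hm(matrix, positions=positions, region_length=30_000))
        summary = flank_contrast(p, p, gene_interval=(12_000, 18_000), flank=10_000)
        for block in summary.blocks.values():
            assert block.ratio == pytest.approx(1.0)
            assert block.rank_sum_p > 0.3  # clearly not significant

    def test_monomorphic_second_population_flagged_infinite(self, rng):
        positions = np.array([100, 5_000, 9_000])
        poly = hm(rng.integers(0, 2, size=(4, 3)).astype(np.int8),
                  positions=positions, region_length=10_000)
        mono = hm(np.zeros((4, 3), dtype=np.int8),
                  positions=positions, region_length=10_000)
        p1, p2 = window_pi(poly), window_pi(mono)
        summary = flank_contrast(p1, p2, gene_interval=(4_000, 6_000), flank=3_000)
        assert math.isinf(summary.blocks["gene"].ratio)

    def test_mismatched_grids_rejected(self, rng):
        positions = np.array([100, 500])
        m = hm(rng.integers(0, 2, size=(4, 2)).astype(np.int8),
               positions=positions, region_length=5_000)
        p1 = window_pi(m, width=1000, jump=300)
        p2 = window_pi(m, width=1000, jump=500)
        with pytest.raises(ValueError):
            flank_contrast(p1, p2, gene_interval=(1, 100))


class TestSubsampling:
    def test_subsample_estimates_unbiased(self, rng):
        """Mean windowed pi over 23-haplotype subsamples of a 200-haplotype
        population stays within 2 SE of the full-sample estimate."""
        from asel.simulate import simulate_two_population_haplotypes

        _, full, _ = simulate_two_population_haplotypes(
            n_pop1=5, n_pop2=200, region_length=20_000, pi_sweep_factor=1.0, seed=9
        )
        full_pi = window_pi(full).pi.mean()
        means = []
        for _ in range(200):
            idx = rng.choice(full.n_haplotypes, size=23, replace=False)
            sub = HaplotypeMatrix(
                positions=full.positions, matrix=full.matrix[idx],
                region_start=full.region_start, region_length=full.region_length,
            )
            means.append(window_pi(sub).pi.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean() - full_pi) < 2 * se + 1e-6
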