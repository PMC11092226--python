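"""Synthetic-data generator: planted structure, determinism, degenerate inputs."""

import numpy as np
import pytest
from scipy import stats

from asel.diversity import window_pi
from asel.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_allele_counts,
    simulate_expression,
    simulate_parental_variants,
    simulate_qtl_gene_set,
    simulate_two_population_haplotypes,
)
from asel.types import Genotype, VariantClass


def all_category(category, **kwargs):
    props = {c: 0.0 for c in ("BC_P1", "BC_P2", "BS", "BR", "NONE")}
    props[category] = 1.0
    return SimulationConfig(category_proportions=props, **kwargs)


class TestAlleleCounts:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(n_genes=10, seed=7)
        r1, t1 = simulate_allele_counts(cfg)
        r2, t2 = simulate_allele_counts(cfg)
        assert r1 == r2
        assert t1.bias_category == t2.bias_category

    def test_parents_are_homozygous(self):
        records, _ = simulate_allele_counts(SimulationConfig(n_genes=10, seed=1))
        for r in records:
            if r.sample.genotype is Genotype.P1:
                assert r.count_p2 == 0
            elif r.sample.genotype is Genotype.P2:
                assert r.count_p1 == 0

    def test_balanced_genes_hit_half(self):
        """Aggregate P1 fraction of unbiased genes stays within 0.5 +/- 0.02
        (thousands of reads, binomial law of large numbers)."""
        cfg = all_category("NONE", n_genes=50, depth_mean=50, seed=3)
        records, _ = simulate_allele_counts(cfg)
        hybrid = [r for r in records if r.sample.genotype.is_hybrid]
        frac = sum(r.count_p1 for r in hybrid) / sum(r.total for r in hybrid)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_bc_p2_fraction_matches_planted_ratio_per_condition(self):
        cfg = all_category("BC_P2", n_genes=60, depth_mean=80, bias_ratio=0.8, seed=4)
        records, _ = simulate_allele_counts(cfg)
        for condition in cfg.conditions:
            sub = [r for r in records
                   if r.sample.genotype.is_hybrid and r.sample.condition == condition]
            frac = sum(r.count_p1 for r in sub) / sum(r.total for r in sub)
            assert frac == pytest.approx(0.2, abs=0.02)

    def test_br_genes_straddle_half(self):
        cfg = all_category("BR", n_genes=30, seed=5)
        _, truth = simulate_allele_counts(cfg)
        for ratios in truth.bias_ratios.values():
            values = list(ratios.values())
            assert any(v > 0.5 for v in values) and any(v < 0.5 for v in values)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(depth_mean=0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(category_proportions={
                "BC_P1": 0.5, "BC_P2": 0.0, "BS": 0.0, "BR": 0.0, "NONE": 0.0,
            })


class TestParentalVariants:
    def test_zero_density_means_no_variants(self):
        variants, genes, _, _ = simulate_parental_variants(
            10, promoter_density=0.0, cds_density=0.0, seed=1
        )
        assert variants == []
        assert len(genes) == 10

    def test_all_deletion_mix(self):
        variants, _, _, _ = simulate_parental_variants(
            20, class_mix=(0.0, 0.0, 1.0), seed=2
        )
        assert variants
        assert all(v.variant_class is VariantClass.DEL for v in variants)
        assert all(len(v.ref) > len(v.alt) for v in variants)

    def test_promoter_count_within_poisson_interval(self):
        """0.01 / bp over 100 genes x 3,000 bp: total inside the central
        99% interval of Poisson(3000)."""
        variants, genes, _, truth = simulate_parental_variants(
            100, promoter_density=0.01, cds_density=0.0, seed=6
        )
        total = sum(len(v) for v in truth.promoter_variants.values())
        lo, hi = stats.poisson.ppf([0.005, 0.995], 3000)
        assert lo <= total <= hi

    def test_variant_refs_match_reference_sequence(self):
        variants, _, ref, _ = simulate_parental_variants(10, seed=7)
        seq = ref["chr1"]
        for v in variants:
            assert seq[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref

    def test_cds_reading_frames_clean(self):
        from asel.pipeline import _spliced_cds

        _, genes, ref, _ = simulate_parental_variants(10, seed=8)
        for g in genes:
            cds = _spliced_cds(g, ref[g.chrom])
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds.endswith("TAA")


class TestHaplotypes:
    def test_single_haplotype_population_rejected(self):
        with pytest.raises(ConfigError):
            simulate_two_population_haplotypes(n_pop1=1)

    def test_neutral_factor_gives_equal_diversity(self):
        ratios = []
        for seed in range(5):
            hm1, hm2, _ = simulate_two_population_haplotypes(
                region_length=50_000, pi_sweep_factor=1.0, seed=seed
            )
            ratios.append(window_pi(hm2).pi.mean() / window_pi(hm1).pi.mean())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_background_diversity_near_target(self):
        hm1, _, _ = simulate_two_population_haplotypes(region_length=100_000, seed=3)
        assert window_pi(hm1).pi.mean() == pytest.approx(0.006, rel=0.1)

    def test_determinism(self):
        a = simulate_two_population_haplotypes(region_length=20_000, seed=11)
        b = simulate_two_population_haplotypes(region_length=20_000, seed=11)
        assert np.array_equal(a[0].matrix, b[0].matrix)
        assert np.array_equal(a[1].positions, b[1].positions)


class TestExpressionAndQtl:
    def test_no_change_genes_have_flat_means(self):
        cfg = SimulationConfig(
            n_genes=30, seed=2,
            pattern_proportions={"additive": 0.0, "dominant": 0.0,
                                 "overdominant": 0.0, "no_change": 1.0},
        )
        tpm, truth = simulate_expression(cfg)
        assert all(t is None for t in truth.pattern_type.values())
        assert tpm.values.mean() == pytest.approx(100.0, rel=0.05)

    def test_qtl_set_enriched_for_biased_genes(self):
        cfg = SimulationConfig(n_genes=400, seed=3)
        _, truth = simulate_allele_counts(cfg)
        qtl = set(simulate_qtl_gene_set(truth, seed=4))
        biased = {g for g, c in truth.bias_category.items() if c != "NONE"}
        none = set(truth.bias_category) - biased
        rate_biased = len(qtl & biased) / len(biased)
        rate_none = len(qtl & none) / len(none)
        assert rate_biased > rate_none
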