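"""Coding-impact classification and strand-aware promoter profiling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from asel.annotate import (
    Effect,
    Impact,
    ModelIntegrityError,
    annotate_effect,
    distance_to_tss,
    promoter_profile,
)
from asel.types import GeneModel, VariantRecord

# 4 codons: M A W * -> ATG GCT TGG TAA, placed at 101..112 on '+'
CDS = "ATGGCTTGGTAA"
GENE = GeneModel("g1", "chr1", 101, 112, "+", [(101, 112)])


def variant(pos, ref, alt):
    return VariantRecord("chr1", pos, ref, alt)


class TestCodingImpact:
    def test_one_bp_deletion_is_frameshift_high(self):
        call = annotate_effect(variant(105, "CT", "C"), GENE, CDS)
        assert call.effect is Effect.FRAMESHIFT
        assert call.impact is Impact.HIGH

    def test_triplet_deletion_is_inframe_moderate(self):
        call = annotate_effect(variant(104, "GCTT", "G"), GENE, CDS)
        assert call.effect is Effect.INFRAME_INDEL
        assert call.impact is Impact.MODERATE

    def test_synonymous_third_position(self):
        # GCT -> GCC, Ala -> Ala at codon 2 (position 106)
        call = annotate_effect(variant(106, "T", "C"), GENE, CDS)
        assert call.effect is Effect.SYNONYMOUS
        assert call.impact is Impact.LOW

    def test_stop_gained(self):
        # TGG -> TGA at codon 3 (position 109)
        call = annotate_effect(variant(109, "G", "A"), GENE, CDS)
        assert call.effect is Effect.STOP_GAINED
        assert call.impact is Impact.HIGH

    def test_stop_lost_and_start_lost(self):
        assert annotate_effect(variant(110, "T", "C"), GENE, CDS).effect is Effect.STOP_LOST
        assert annotate_effect(variant(101, "A", "G"), GENE, CDS).effect is Effect.START_LOST

    def test_missense(self):
        # GCT -> GAT, Ala -> Asp (position 105)
        assert annotate_effect(variant(105, "C", "A"), GENE, CDS).effect is Effect.MISSENSE

    def test_non_coding_placements_are_modifier(self):
        gene = GeneModel("g2", "chr1", 101, 130, "+", [(101, 112)])
        in_gene = annotate_effect(variant(120, "A", "G"), gene, CDS)
        assert (in_gene.effect, in_gene.impact) == (Effect.INTRON_UTR, Impact.MODIFIER)
        upstream = annotate_effect(variant(50, "A", "G"), gene, CDS)
        assert upstream.effect is Effect.PROMOTER
        far = annotate_effect(variant(50_000, "A", "G"), gene, CDS)
        assert far.effect is Effect.INTERGENIC

    def test_broken_reading_frame_rejected(self):
        with pytest.raises(ModelIntegrityError):
            annotate_effect(variant(101, "A", "G"), GENE, CDS + "A")

    def test_minus_strand_codon_logic(self):
        # same CDS on '-': genomic segment is the reverse complement
        gene = GeneModel("g3", "chr1", 201, 212, "-", [(201, 212)])
        # CDS offset 8 (TGG codon, third base) is genomic 201 + (12-1-8) = 204
        call = annotate_effect(variant(204, "C", "T"), gene, CDS)  # G->A sense
        assert call.effect is Effect.STOP_GAINED

    def test_every_variant_gets_exactly_one_effect(self, rng):
        gene = GeneModel("g4", "chr1", 1000, 1011, "+", [(1000, 1011)])
        for _ in range(50):
            pos = int(rng.integers(1, 6000))
            ref, alt = "A", "G"
            call = annotate_effect(VariantRecord("chr1", pos, ref, alt,), gene, CDS)
            assert call.effect in Effect
            assert call.impact is not None

    def test_random_cds_snps_agree_with_full_translation_oracle(self, rng):
        """Impact of 1,000 random CDS SNPs equals naive whole-protein
        comparison of mutant vs wild-type."""
        bases = np.array(list("ACGT"))
        n_checked = 0
        while n_checked < 1000:
            n_codons = int(rng.integers(4, 30))
            internal = []
            while len(internal) < n_codons - 2:
                c = "".join(rng.choice(bases, 3))
                if c not in ("TAA", "TAG", "TGA"):
                    internal.append(c)
            cds = "ATG" + "".join(internal) + "TAA"
            start = 500
            gene = GeneModel("gx", "chr1", start, start + len(cds) - 1, "+",
                             [(start, start + len(cds) - 1)])
            offset = int(rng.integers(len(cds)))
            ref = cds[offset]
            alt = str(rng.choice(bases[bases != ref]))
            call = annotate_effect(variant(start + offset, ref, alt), gene, cds)
            mutant = cds[:offset] + alt + cds[offset + 1 :]
            wt_protein = str(Seq(cds).translate())
            mut_protein = str(Seq(mutant).translate())
            if offset < 3 and not mut_protein.startswith("M"):
                expect = Impact.HIGH  # start lost
            elif mut_protein.count("*") > wt_protein.count("*"):
                expect = Impact.HIGH  # stop gained
            elif mut_protein.count("*") < wt_protein.count("*"):
                expect = Impact.HIGH  # stop lost
            elif mut_protein == wt_protein:
                expect = Impact.LOW
            else:
                expect = Impact.MODERATE
            assert call.impact is expect, (cds, offset, ref, alt)
            n_checked += 1


class TestPromoterProfile:
    def test_plus_strand_window_arithmetic(self):
        gene = GeneModel("g1", "chr1", 10_000, 12_000, "+")
        inside = variant(9_500, "A", "G")
        boundary_out = variant(6_999, "A", "G")  # distance 3,001
        profile = promoter_profile([inside, boundary_out], gene)
        assert profile.distances == [500]
        assert len(profile.variants) == 1

    def test_minus_strand_mirror(self):
        gene = GeneModel("g1", "chr1", 3_000, 5_000, "-")
        profile = promoter_profile([variant(5_200, "A", "G")], gene)
        assert profile.distances == [200]

    def test_strand_mirror_property(self, rng):
        """Reflecting a '+' gene and its variants around the TSS reproduces
        the '-' construction's distances exactly."""
        tss = 50_000
        plus = GeneModel("gp", "chr1", tss, tss + 1_000, "+")
        minus = GeneModel("gm", "chr1", tss - 1_000, tss, "-")
        positions = rng.integers(tss - 3_500, tss, size=50)
        plus_vars = [variant(int(p), "A", "G") for p in positions]
        minus_vars = [variant(int(2 * tss - p), "A", "G") for p in positions]
        p_profile = promoter_profile(plus_vars, plus)
        m_profile = promoter_profile(minus_vars, minus)
        assert sorted(p_profile.distances) == sorted(m_profile.distances)

    def test_histogram_sums_to_variant_count(self, rng):
        gene = GeneModel("g1", "chr1", 10_000, 11_000, "+")
        variants = [variant(int(p), "A", "G")
                    for p in rng.integers(7_000, 10_000, size=200)]
        profile = promoter_profile(variants, gene)
        counts, edges = profile.histogram
        assert counts.sum() == len(profile.variants)
        assert len(counts) == 30  # 3,000 bp / 100 bp bins

    def test_class_counts(self):
        gene = GeneModel("g1", "chr1", 10_000, 11_000, "+")
        vs = [variant(9_000, "A", "G"), variant(9_100, "A", "AT"),
              variant(9_200, "AT", "A")]
        profile = promoter_profile(vs, gene)
        assert profile.class_counts == {"SNP": 1, "INS": 1, "DEL": 1}

    def test_invalid_window_rejected(self):
        gene = GeneModel("g1", "chr1", 10_000, 11_000, "+")
        with pytest.raises(ValueError):
            promoter_profile([], gene, window=0)
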