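"""BC / BS / BR categorization, reciprocal-hybrid combination, reporting."""

import numpy as np
import pandas as pd
import pytest

from asel.classify import (
    bias_ratio_correlation,
    bias_ratio_table,
    classify_gene,
    combine_hybrids,
    percent,
    summarize_categories,
)
from asel.types import BiasClass, Direction, Genotype
from conftest import make_call, make_record

CONDITIONS = ["dark", "far_red", "red", "blue"]


def hybrid_bias(directions, hybrid=Genotype.H12, gene="g1"):
    calls = [
        make_call(gene=gene, hybrid=hybrid, condition=c, direction=d)
        for c, d in zip(CONDITIONS, directions)
    ]
    return classify_gene(calls, CONDITIONS)


P1, P2, NO = Direction.P1, Direction.P2, Direction.NONE


class TestPerHybrid:
    @pytest.mark.parametrize(
        "directions,category",
        [
            ((P2, P2, P2, P2), BiasClass.BC),   # same allele in all conditions
            ((NO, P1, NO, NO), BiasClass.BS),   # only some conditions
            ((P2, NO, P1, P1), BiasClass.BR),   # directional shift
            ((NO, NO, NO, NO), BiasClass.NON_BIAS),
        ],
    )
    def test_rule_examples(self, directions, category):
        assert hybrid_bias(directions).category is category

    def test_bc_keeps_consensus_direction(self):
        hb = hybrid_bias((P2, P2, P2, P2))
        assert hb.direction is P2

    def test_missing_condition_rejected(self):
        calls = [make_call(condition="dark", direction=P1)]
        with pytest.raises(ValueError, match="far_red"):
            classify_gene(calls, CONDITIONS)

    def test_untestable_condition_flags_not_vetoes(self):
        calls = [
            make_call(condition=c, direction=P2) for c in CONDITIONS[:3]
        ] + [make_call(condition="blue", direction=NO, testable=False)]
        hb = classify_gene(calls, CONDITIONS)
        assert hb.category is BiasClass.BC  # all testable conditions biased
        assert hb.flagged


class TestCombined:
    def test_shared_bc_same_direction(self):
        combined = combine_hybrids(
            hybrid_bias((P2,) * 4, Genotype.H12),
            hybrid_bias((P2,) * 4, Genotype.H21),
        )
        assert combined.category is BiasClass.BC
        assert combined.direction is P2

    def test_bc_in_one_hybrid_only_downgrades_to_bs(self):
        combined = combine_hybrids(
            hybrid_bias((P1,) * 4, Genotype.H12),
            hybrid_bias((NO,) * 4, Genotype.H21),
        )
        assert combined.category is BiasClass.BS

    def test_opposing_bc_directions_are_reversal(self):
        combined = combine_hybrids(
            hybrid_bias((P1,) * 4, Genotype.H12),
            hybrid_bias((P2,) * 4, Genotype.H21),
        )
        assert combined.category is BiasClass.BR

    def test_reversal_in_either_hybrid_dominates(self):
        combined = combine_hybrids(
            hybrid_bias((P1, P2, NO, NO), Genotype.H12),
            hybrid_bias((P1,) * 4, Genotype.H21),
        )
        assert combined.category is BiasClass.BR

    def test_partition_is_exhaustive_and_exclusive(self):
        """Every per-hybrid category pair maps to exactly one combined class."""
        reps = {
            BiasClass.BC: (P1,) * 4,
            BiasClass.BS: (P1, NO, NO, NO),
            BiasClass.BR: (P1, P2, NO, NO),
            BiasClass.NON_BIAS: (NO,) * 4,
        }
        for c12, d12 in reps.items():
            for c21, d21 in reps.items():
                combined = combine_hybrids(
                    hybrid_bias(d12, Genotype.H12), hybrid_bias(d21, Genotype.H21)
                )
                assert combined.category in BiasClass


class TestBiasRatios:
    def _records(self, ratio_h12, ratio_h21, n_genes=40, rng=None):
        rng = rng or np.random.default_rng(0)
        records = []
        for gi in range(n_genes):
            for cond in CONDITIONS:
                for hybrid, ratio in ((Genotype.H12, ratio_h12), (Genotype.H21, ratio_h21)):
                    r = ratio(gi) if callable(ratio) else ratio
                    a = int(round(100 * r))
                    records.append(
                        make_record(gene=f"g{gi}", genotype=hybrid, condition=cond,
                                    count_p1=a, count_p2=100 - a)
                    )
        return records

    def test_identical_tables_r2_one(self):
        rng = np.random.default_rng(3)
        ratio = lambda gi: 0.2 + 0.6 * (gi % 7) / 6
        table = bias_ratio_table(self._records(ratio, ratio))
        assert bias_ratio_correlation(table) == pytest.approx(1.0)

    def test_anticorrelated_tables_r2_one(self):
        ratio = lambda gi: 0.2 + 0.6 * (gi % 7) / 6
        anti = lambda gi: 1 - ratio(gi)
        table = bias_ratio_table(self._records(ratio, anti))
        assert bias_ratio_correlation(table) == pytest.approx(1.0)

    def test_independent_cells_r2_near_zero(self, rng):
        u1 = rng.uniform(0.05, 0.95, size=1000)
        u2 = rng.uniform(0.05, 0.95, size=1000)
        table = pd.DataFrame(
            {("H12", "dark"): u1, ("H21", "dark"): u2},
            index=[f"g{i}" for i in range(1000)],
        )
        table.columns = pd.MultiIndex.from_tuples(table.columns)
        assert bias_ratio_correlation(table) < 0.05

    def test_too_few_pairs_rejected(self):
        table = pd.DataFrame(
            {("H12", "dark"): [0.5, 0.6], ("H21", "dark"): [0.5, 0.6]},
            index=["g1", "g2"],
        )
        table.columns = pd.MultiIndex.from_tuples(table.columns)
        with pytest.raises(ValueError):
            bias_ratio_correlation(table)

    def test_low_depth_cells_undefined_not_imputed(self):
        records = [make_record(count_p1=3, count_p2=2)]  # total 5 < 10
        assert bias_ratio_table(records).empty


class TestSummary:
    def test_percent_rounding_half_up(self):
        assert percent(1350, 4754) == "28.40%"
        assert percent(330, 4754) == "6.94%"
        assert percent(1, 8) == "12.50%"
        assert percent(0, 0) == "0.00%"

    def test_empty_input_no_division_error(self):
        report = summarize_categories([], [])
        assert report["n_genes"] == 0
        assert report["categories"]["BC"]["percent"] == "0.00%"

    def test_counts_partition_gene_total(self):
        cats = [
            combine_hybrids(hybrid_bias(d, Genotype.H12, gene=f"g{i}"),
                            hybrid_bias(d, Genotype.H21, gene=f"g{i}"))
            for i, d in enumerate([(P1,) * 4, (P1, NO, NO, NO), (P1, P2, NO, NO), (NO,) * 4])
        ]
        report = summarize_categories(cats, [])
        total = sum(report["categories"][c]["count"] for c in ("BC", "BS", "BR", "NON_BIAS"))
        assert total == report["n_genes"] == 4
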