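import numpy as np
import pytest

from asel.calling import ASEGCall, SnpTestResult
from asel.types import AlleleCountRecord, Direction, GeneModel, Genotype, SampleKey


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(gene="g1", snp="s1", genotype=Genotype.H12, condition="dark",
                replicate=1, count_p1=10, count_p2=10, pos=100):
    return AlleleCountRecord(
        gene_id=gene, snp_id=snp, chrom="chr1", pos=pos,
        sample=SampleKey(genotype, condition, replicate),
        count_p1=count_p1, count_p2=count_p2,
    )


def make_call(gene="g1", hybrid=Genotype.H12, condition="dark",
              direction=Direction.NONE, testable=True):
    """ASEGCall with the given consensus direction (is_aseg iff directed)."""
    return ASEGCall(
        gene_id=gene, hybrid=hybrid, condition=condition,
        is_aseg=direction is not Direction.NONE, direction=direction,
        n_supporting_replicates=3 if direction is not Direction.NONE else 0,
        replicate_directions=[direction] * 3,
        n_testable_replicates=3 if testable else 0,
    )


def make_snp_result(direction=Direction.NONE, gene="g1", passed_depth=True):
    significant = direction is not Direction.NONE
    a, b = (30, 10) if direction is Direction.P1 else (10, 30)
    if not significant:
        a = b = 20
    return SnpTestResult(
        count_p1=a, count_p2=b, chi2=10.0 if significant else 0.0,
        p_value=0.001 if significant else 1.0,
        passed_depth=passed_depth, significant=significant and passed_depth,
        direction=direction if passed_depth else Direction.NONE,
        gene_id=gene,
    )


@pytest.fixture
def plus_gene():
    return GeneModel(gene_id="gplus", chrom="chr1", start=10_000, end=10_899,
                     strand="+", cds_segments=[(10_000, 10_899)])


@pytest.fixture
def minus_gene():
    return GeneModel(gene_id="gminus", chrom="chr1", start=5_000, end=5_899,
                     strand="-", cds_segments=[(5_000, 5_899)])
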