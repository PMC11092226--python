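"""Hypergeometric overlap tests and generic term enrichment.

Over-representation only (upper tail): the p-value for observing k or
more of the n query genes inside an annotated set of K genes drawn from a
universe of N is  p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapTest:
    """One upper-tail hypergeometric overlap."""

    universe: int  # N
    annotated: int  # K
    query: int  # n
    overlap: int  # k
    p_value: float
    term: str = ""
    fdr: float | None = None


def hypergeom_overlap(N: int, K: int, n: int, k: int, term: str = "") -> OverlapTest:
    """Upper-tail hypergeometric test of an overlap of k genes."""
    if min(N, K, n, k) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError(f"set sizes exceed universe: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(universe=N, annotated=K, query=n, overlap=k,
                       p_value=min(p, 1.0), term=term)


def term_enrichment(
    query: Iterable[str],
    term_map: Mapping[str, Sequence[str]],
    universe: Iterable[str],
) -> list[OverlapTest]:
    """One overlap test per term, BH-corrected, sorted by ascending p.

    Term gene sets are intersected with the universe; query genes must all
    be universe members.
    """
    universe_set = set(universe)
    query_set = set(query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query gene(s) absent from universe: {', '.join(offenders)}")
    tests = []
    for term, genes in term_map.items():
        annotated = set(genes) & universe_set
        tests.append(
            hypergeom_overlap(
                N=len(universe_set), K=len(annotated), n=len(query_set),
                k=len(annotated & query_set), term=term,
            )
        )
    if tests:
        fdrs = multipletests([t.p_value for t in tests], method="fdr_bh")[1]
        for t, q in zip(tests, fdrs):
            t.fdr = float(q)
    return sorted(tests, key=lambda t: t.p_value)
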