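"""Hybrid expression-pattern typing from three differential contrasts.

Each gene is described by the states of three contrasts — P1 vs P2
(``d_p``), hybrid vs P1 (``d_1``) and hybrid vs P2 (``d_2``), each
``up``/``down``/``ns`` with "up" meaning the first member is higher — and
mapped onto twelve types in three super-groups:

* additive (I, II): the hybrid sits between the parents;
* complete-incomplete dominant (III-VI): the hybrid matches one parent
  and differs from the other (expression-level dominance, ELD);
* overdominant (VII-XII): the hybrid is above (VII-IX) or below (X-XII)
  both parents (transgressive expression).

State triples matching none of the twelve (for example all-ns) are
unclassified and excluded from the typed set.  The contrast engine here
is a deliberately simple stand-in for synthetic data — Welch's t on
log2(TPM+1) with Benjamini-Hochberg correction across genes — and the
classifier accepts :class:`ContrastResult` rows from any external DE
engine instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import percent
from .types import Genotype

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_FDR_THRESHOLD = 0.01


class State(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"

    def flipped(self) -> "State":
        if self is State.UP:
            return State.DOWN
        if self is State.DOWN:
            return State.UP
        return State.NS


class PatternType(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"
    XII = "XII"


SUPER_GROUP = {
    PatternType.I: "additive",
    PatternType.II: "additive",
    PatternType.III: "dominant",
    PatternType.IV: "dominant",
    PatternType.V: "dominant",
    PatternType.VI: "dominant",
    PatternType.VII: "overdominant",
    PatternType.VIII: "overdominant",
    PatternType.IX: "overdominant",
    PatternType.X: "overdominant",
    PatternType.XI: "overdominant",
    PatternType.XII: "overdominant",
}

# Decision table over (d_p, d_1, d_2).  The overdominant blocks absorb any
# parent-contrast state; labels within each block are a documented
# convention (VII/X: parents differ with P1 higher; VIII/XI: P2 higher;
# IX/XII: parents not different).
_DECISION_TABLE: dict[tuple[State, State, State], PatternType] = {
    (State.UP, State.DOWN, State.UP): PatternType.I,
    (State.DOWN, State.UP, State.DOWN): PatternType.II,
    (State.UP, State.NS, State.UP): PatternType.III,
    (State.UP, State.DOWN, State.NS): PatternType.IV,
    (State.DOWN, State.NS, State.DOWN): PatternType.V,
    (State.DOWN, State.UP, State.NS): PatternType.VI,
    (State.UP, State.UP, State.UP): PatternType.VII,
    (State.DOWN, State.UP, State.UP): PatternType.VIII,
    (State.NS, State.UP, State.UP): PatternType.IX,
    (State.UP, State.DOWN, State.DOWN): PatternType.X,
    (State.DOWN, State.DOWN, State.DOWN): PatternType.XI,
    (State.NS, State.DOWN, State.DOWN): PatternType.XII,
}


@dataclass
class ContrastResult:
    """One differential-expression contrast for one gene."""

    gene_id: str
    contrast: str  # P1_vs_P2 | H_vs_P1 | H_vs_P2
    log2fc: float  # first member over second
    fdr: float

    def state(
        self,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    ) -> State:
        different = self.fdr < fdr_threshold and 2.0 ** abs(self.log2fc) > fc_threshold
        if not different:
            return State.NS
        return State.UP if self.log2fc > 0 else State.DOWN


@dataclass
class ExpressionPatternCall:
    """Typed hybrid expression pattern of one gene (None = unclassified)."""

    gene_id: str
    hybrid: Genotype
    pattern: PatternType | None
    states: tuple[State, State, State]

    @property
    def super_group(self) -> str | None:
        return SUPER_GROUP[self.pattern] if self.pattern is not None else None

    @property
    def is_nonadditive(self) -> bool | None:
        if self.pattern is None:
            return None
        return self.super_group != "additive"

    @property
    def eld_label(self) -> str | None:
        """ELD-F / ELD-M for dominant types: which parent the hybrid matches.

        The female parent is the first genotype of the cross name, so
        H12's female is P1 and H21's female is P2.
        """
        if self.pattern not in (PatternType.III, PatternType.IV, PatternType.V, PatternType.VI):
            return None
        # III, V: hybrid ~ P1 (d_1 = ns); IV, VI: hybrid ~ P2 (d_2 = ns)
        matches = Genotype.P1 if self.pattern in (PatternType.III, PatternType.V) else Genotype.P2
        female = self.hybrid.female_parent
        return "ELD-F" if matches is female else "ELD-M"


def classify_pattern(
    d_p: State | str,
    d_1: State | str,
    d_2: State | str,
    gene_id: str = "",
    hybrid: Genotype = Genotype.H12,
) -> ExpressionPatternCall:
    """Map one contrast-state triple onto the twelve-type table."""
    states = (State(d_p), State(d_1), State(d_2))
    return ExpressionPatternCall(
        gene_id=gene_id, hybrid=hybrid,
        pattern=_DECISION_TABLE.get(states), states=states,
    )


# ------------------------------------------------------------ DE stand-in

def _welch_log2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    la, lb = np.log2(np.asarray(a, float) + 1), np.log2(np.asarray(b, float) + 1)
    log2fc = float(la.mean() - lb.mean())
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
        return log2fc, 1.0
    p = stats.ttest_ind(la, lb, equal_var=False).pvalue
    return log2fc, float(p) if np.isfinite(p) else 1.0


def call_contrast(
    tpm_a: Sequence[float], tpm_b: Sequence[float]
) -> tuple[float, float]:
    """Single-gene contrast: (log2fc, raw p) from Welch's t on log2(TPM+1).

    Significance is decided only after Benjamini-Hochberg correction
    across genes (see :func:`call_contrasts`).
    """
    if len(tpm_a) < 2 or len(tpm_b) < 2:
        raise ValueError("need >= 2 replicates per side")
    return _welch_log2(np.asarray(tpm_a), np.asarray(tpm_b))


def call_contrasts(
    tpm: pd.DataFrame,
    contrast: str,
    hybrid: Genotype,
    condition: str,
) -> list[ContrastResult]:
    """One named contrast for every gene, BH-corrected across genes.

    ``tpm`` is a genes x samples frame with (genotype, condition,
    replicate) MultiIndex columns.
    """
    tpm = tpm.sort_index(axis=1)
    pair = {
        "P1_vs_P2": (Genotype.P1.value, Genotype.P2.value),
        "H_vs_P1": (hybrid.value, Genotype.P1.value),
        "H_vs_P2": (hybrid.value, Genotype.P2.value),
    }[contrast]
    a = tpm.loc[:, (pair[0], condition)]
    b = tpm.loc[:, (pair[1], condition)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per side")
    stats_rows = [
        _welch_log2(a.loc[g].to_numpy(), b.loc[g].to_numpy()) for g in tpm.index
    ]
    pvals = np.array([p for _, p in stats_rows])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return [
        ContrastResult(gene_id=g, contrast=contrast, log2fc=lfc, fdr=float(q))
        for g, (lfc, _), q in zip(tpm.index, stats_rows, fdr)
    ]


def classify_patterns(
    tpm: pd.DataFrame,
    hybrid: Genotype,
    condition: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[ExpressionPatternCall]:
    """Type every gene for one hybrid x condition from a TPM matrix."""
    by_contrast = {
        name: {r.gene_id: r for r in call_contrasts(tpm, name, hybrid, condition)}
        for name in ("P1_vs_P2", "H_vs_P1", "H_vs_P2")
    }
    calls = []
    for gene in tpm.index:
        states = tuple(
            by_contrast[name][gene].state(fc_threshold, fdr_threshold)
            for name in ("P1_vs_P2", "H_vs_P1", "H_vs_P2")
        )
        calls.append(
            ExpressionPatternCall(gene_id=gene, hybrid=hybrid,
                                  pattern=_DECISION_TABLE.get(states), states=states)
        )
    return calls


def classify_from_contrasts(
    contrasts: Iterable[ContrastResult],
    hybrid: Genotype = Genotype.H12,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[ExpressionPatternCall]:
    """Type genes from externally computed contrast results."""
    by_gene: dict[str, dict[str, ContrastResult]] = {}
    for r in contrasts:
        by_gene.setdefault(r.gene_id, {})[r.contrast] = r
    calls = []
    for gene, row in sorted(by_gene.items()):
        missing = {"P1_vs_P2", "H_vs_P1", "H_vs_P2"} - set(row)
        if missing:
            raise ValueError(f"gene {gene!r}: missing contrast(s) {sorted(missing)}")
        states = tuple(
            row[name].state(fc_threshold, fdr_threshold)
            for name in ("P1_vs_P2", "H_vs_P1", "H_vs_P2")
        )
        calls.append(
            ExpressionPatternCall(gene_id=gene, hybrid=hybrid,
                                  pattern=_DECISION_TABLE.get(states), states=states)
        )
    return calls


def consensus_patterns(
    calls: Iterable[ExpressionPatternCall],
) -> list[ExpressionPatternCall]:
    """Per-gene modal pattern across hybrid x condition calls.

    A single condition's call can mistype a gene when one of its three
    contrasts narrowly misses the significance gates (at 3 replicates the
    unequal-variance test's effective df can collapse, inflating p for a
    real difference).  The mode over a gene's calls is a more stable
    gene-level summary; ties go to the type seen first, and genes typed
    in no call stay unclassified.
    """
    by_gene: dict[str, list[ExpressionPatternCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    out = []
    for gene, gene_calls in sorted(by_gene.items()):
        typed = [c for c in gene_calls if c.pattern is not None]
        if not typed:
            out.append(ExpressionPatternCall(
                gene_id=gene, hybrid=gene_calls[0].hybrid,
                pattern=None, states=gene_calls[0].states,
            ))
            continue
        counts: dict[PatternType, int] = {}
        for c in typed:
            counts[c.pattern] = counts.get(c.pattern, 0) + 1
        winner = max(counts, key=lambda t: counts[t])
        rep = next(c for c in typed if c.pattern is winner)
        out.append(ExpressionPatternCall(
            gene_id=gene, hybrid=rep.hybrid, pattern=winner, states=rep.states,
        ))
    return out


def pattern_spectrum(calls: Iterable[ExpressionPatternCall]) -> dict:
    """Per-type and per-super-group counts and percentages of typed genes."""
    typed = [c for c in calls if c.pattern is not None]
    n = len(typed)
    by_type = {t.value: sum(1 for c in typed if c.pattern is t) for t in PatternType}
    groups = ("additive", "dominant", "overdominant")
    by_group = {g: sum(1 for c in typed if c.super_group == g) for g in groups}
    return {
        "n_typed": n,
        "types": {t: {"count": k, "percent": percent(k, n)} for t, k in by_type.items()},
        "super_groups": {
            g: {"count": k, "percent": percent(k, n)} for g, k in by_group.items()
        },
    }
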