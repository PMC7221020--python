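"""Pairwise co-occurrence / mutual-exclusivity testing of gene mutations.

For each pair of sufficiently mutated genes a 2x2 contingency table of joint
mutation status is tested with Pearson's chi-square (no continuity
correction) or, whenever any expected cell count falls below 5, the
two-sided Fisher exact test.  Significant pairs with odds ratio > 1 are
co-occurrent, < 1 mutually exclusive.  Raw p-values at alpha = 0.05 by
default — no multiplicity correction — matching common panel-report
practice; an optional Benjamini-Hochberg correction is available.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, PanelError
from .matrix import MutationMatrix

#: A gene enters the pairwise scan only with at least this many mutated
#: samples (strictly more than 10, the ">1.5% of 639" convention).
MIN_MUTATIONS = 11


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint status counts; rows = gene A (wt, mut), cols = gene B (wt, mut)."""

    a: int  # wtA & wtB
    b: int  # wtA & mutB
    c: int  # mutA & wtB
    d: int  # mutA & mutB

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / self.total

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


class TestMethod(str, enum.Enum):
    AUTO = "auto"
    CHI2 = "chi2"
    FISHER = "fisher"


class Direction(str, enum.Enum):
    CO_OCCURRENCE = "co_occurrence"
    EXCLUSIVITY = "exclusivity"
    NONE = "none"


def eligible_genes(m: MutationMatrix, min_mutations: int = MIN_MUTATIONS) -> list[str]:
    """Genes with >= ``min_mutations`` mutated samples, in panel order."""
    counts = m.df.sum(axis=0)
    return [g for g in m.genes if counts[g] >= min_mutations]


def contingency_2x2(m: MutationMatrix, gene_a: str, gene_b: str) -> ContingencyTable2x2:
    if gene_a == gene_b:
        raise ValueError("gene pair must be distinct")
    for g in (gene_a, gene_b):
        if g not in m.df.columns:
            raise PanelError(f"{g!r} not in matrix")
    sa = m.df[gene_a].to_numpy().astype(bool)
    sb = m.df[gene_b].to_numpy().astype(bool)
    return ContingencyTable2x2(
        a=int((~sa & ~sb).sum()),
        b=int((~sa & sb).sum()),
        c=int((sa & ~sb).sum()),
        d=int((sa & sb).sum()),
    )


def _has_zero_margin(t: ContingencyTable2x2) -> bool:
    arr = t.as_array()
    return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())


def test_association(
    t: ContingencyTable2x2, method: TestMethod | str = TestMethod.AUTO
) -> tuple[str, float]:
    """(test_used, p_value) for one 2x2 table.

    ``auto`` picks Fisher whenever any expected count is below 5 (or a
    margin is zero), else chi-square.  Chi-square is Pearson's, df = 1,
    without Yates continuity correction; Fisher is the standard two-sided
    test summing all tables at fixed margins with point probability at most
    that of the observed table.
    """
    method = TestMethod(method)
    degenerate = _has_zero_margin(t)
    if method is TestMethod.AUTO:
        method = (
            TestMethod.FISHER
            if degenerate or t.expected().min() < 5
            else TestMethod.CHI2
        )
    if method is TestMethod.CHI2:
        if degenerate:
            raise DegenerateInputError(
                "chi-square undefined for a table with a zero margin"
            )
        res = stats.chi2_contingency(t.as_array(), correction=False)
        p = float(res.pvalue)
    else:
        p = float(stats.fisher_exact(t.as_array(), alternative="two-sided").pvalue)
    return method.value, float(np.clip(p, 0.0, 1.0))


test_association.__test__ = False  # not a test despite the name


def odds_ratio(t: ContingencyTable2x2) -> tuple[float, bool]:
    """(odds ratio, corrected-flag).

    (a*d)/(b*c); with any zero cell, the Haldane-Anscombe +0.5 correction is
    applied to every cell and flagged.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


@dataclass(frozen=True)
class PairwiseResult:
    gene_a: str
    gene_b: str
    table: ContingencyTable2x2
    test_used: str
    p_value: float
    odds_ratio: float
    or_corrected: bool
    significant: bool
    direction: Direction


def _direction(or_: float, significant: bool) -> Direction:
    if not significant or or_ == 1.0:
        return Direction.NONE
    return Direction.CO_OCCURRENCE if or_ > 1.0 else Direction.EXCLUSIVITY


def pairwise_scan(
    m: MutationMatrix,
    alpha: float = 0.05,
    min_mutations: int = MIN_MUTATIONS,
    method: TestMethod | str = TestMethod.AUTO,
    fdr: bool = False,
) -> list[PairwiseResult]:
    """Test every unordered pair of eligible genes; results sorted by p.

    With ``fdr=True`` significance is judged on Benjamini-Hochberg adjusted
    p-values instead of raw ones (off by default).
    """
    genes = eligible_genes(m, min_mutations)
    if len(genes) < 2:
        raise DegenerateInputError(
            f"pairwise scan needs >=2 eligible genes, found {len(genes)}"
        )
    rows = []
    for ga, gb in itertools.combinations(genes, 2):
        t = contingency_2x2(m, ga, gb)
        test_used, p = test_association(t, method)
        or_, corrected = odds_ratio(t)
        rows.append((ga, gb, t, test_used, p, or_, corrected))
    pvals = np.array([r[4] for r in rows])
    if fdr:
        from statsmodels.stats.multitest import multipletests

        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals < alpha
    results = [
        PairwiseResult(ga, gb, t, test_used, p, or_, corr, bool(s), _direction(or_, bool(s)))
        for (ga, gb, t, test_used, p, or_, corr), s in zip(rows, sig)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.gene_a, r.gene_b))


def results_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a pairwise scan."""
    return pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "test": r.test_used,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "direction": r.direction.value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
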