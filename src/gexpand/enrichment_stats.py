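"""Statistics over precomputed functional-enrichment score tables.

Enrichment scores come from upstream pangenome comparisons of gut genomes
against their closest non-gut relatives: positive means gut-enriched,
negative means enriched elsewhere, zero means no signal.  This module asks
the directional questions the downstream analysis needs — do more
annotations point toward the gut than away from it (sign test), is a gene
category such as CRISPR overrepresented among enriched families relative to
unenriched ones (two-sided Fisher exact, minimum-likelihood convention),
and does anything survive Benjamini–Hochberg correction?
"""
from __future__ import annotations

import dataclasses
import math

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .divergence_stats import SignTestResult, sign_test

__all__ = [
    "ContingencyTable2x2",
    "enrichment_sign_test",
    "category_contingency",
    "fisher_exact_two_sided",
    "bh_adjust",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: category yes/no; columns: focal group / reference group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


def enrichment_sign_test(scores: pd.DataFrame, source: str | None = None) -> SignTestResult:
    """Directional sign test over nonzero enrichment scores.

    n counts annotations with a nonzero score (optionally restricted to one
    annotation ``source``), k those pointing toward the gut (positive).
    With no nonzero scores the test is undefined (p = NaN).
    """
    df = scores if source is None else scores[scores["source"] == source]
    nonzero = df[df["score"] != 0.0]
    n = len(nonzero)
    if n == 0:
        return SignTestResult(n=0, k=0, p_one_sided=math.nan)
    k = int((nonzero["score"] > 0).sum())
    return sign_test(k, n)


def category_contingency(
    scores: pd.DataFrame,
    category: str,
    group: str = "positive",
    reference: str = "zero",
) -> ContingencyTable2x2:
    """Build the category-vs-group 2×2 table the overrepresentation test uses.

    Groups partition annotations by score sign: 'positive' (gut-enriched),
    'negative' (other-enriched), or 'zero' (unenriched reference).  Flags are
    matched within the semicolon-separated ``category_flags`` column.
    """

    def _members(name: str) -> pd.DataFrame:
        if name == "positive":
            return scores[scores["score"] > 0]
        if name == "negative":
            return scores[scores["score"] < 0]
        if name == "zero":
            return scores[scores["score"] == 0]
        raise ValueError(f"unknown group {name!r}")

    def _in_category(df: pd.DataFrame) -> pd.Series:
        flags = df["category_flags"].fillna("").astype(str)
        return flags.str.split(";").apply(lambda fs: category in fs)

    g = _members(group)
    r = _members(reference)
    a = int(_in_category(g).sum())
    c = int(_in_category(r).sum())
    return ContingencyTable2x2(a=a, b=len(g) - a, c=c, d=len(r) - c)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total probability of all same-margin tables
    no more likely than the observed one (minimum-likelihood convention)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(p)


def bh_adjust(pvalues: list[float] | pd.Series) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    pv = list(pvalues)
    if any((p < 0 or p > 1 or not math.isfinite(p)) for p in pv):
        raise ValueError("p-values must lie in [0, 1]")
    if not pv:
        return []
    return list(multipletests(pv, method="fdr_bh")[1])
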