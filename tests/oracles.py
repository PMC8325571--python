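"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own tree container and algorithms:
the comparison-extraction oracle parses Newick with Bio.Phylo and evaluates
the reciprocal-monophyly predicate at every internal node by direct set
inspection; the sign-test oracle enumerates all 2^n equally likely outcome
sequences; the Fisher oracle enumerates every table with the observed
margins using exact rational hypergeometric probabilities.
"""
from __future__ import annotations

import io
import itertools
from fractions import Fraction
from math import comb

from Bio import Phylo


def brute_force_comparisons(
    newick: str,
    habitats: dict[str, str],
    genera: dict[str, str],
    genus_required: bool = True,
) -> set[tuple[frozenset, frozenset]]:
    """All (gut tip set, non-gut tip set) pairs anchored by the predicate:
    every child subtree pure for one side, both sides present, single genus."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    found = set()
    for clade in tree.find_clades():
        if not clade.clades:
            continue
        child_tip_sets = [frozenset(t.name for t in ch.get_terminals()) for ch in clade.clades]
        gut_pool, nongut_pool = [], []
        ok = True
        for tips in child_tip_sets:
            sides = {habitats[t] == "gut" for t in tips}
            if len(sides) != 1:
                ok = False
                break
            (gut_pool if sides == {True} else nongut_pool).append(tips)
        if not ok or not gut_pool or not nongut_pool:
            continue
        all_tips = frozenset().union(*child_tip_sets)
        if genus_required and len({genera[t] for t in all_tips}) != 1:
            continue
        found.add(
            (frozenset().union(*gut_pool), frozenset().union(*nongut_pool))
        )
    return found


def sign_test_enumeration(k: int, n: int) -> float:
    """P(#successes >= k) by explicit enumeration of all 2^n outcomes."""
    hits = sum(1 for seq in itertools.product((0, 1), repeat=n) if sum(seq) >= k)
    return hits / 2**n


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing point probabilities of all tables with
    the observed margins that are no more likely than the observed table."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int) -> Fraction:
        # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point(x)
        if p <= p_obs:
            total += p
    return float(total)
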