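"""Per-comparison size divergences and the exact tests applied to them.

Each independent comparison contributes one direction-of-divergence
observation: is the mean genome size of the gut clade larger than that of
its non-gut sister?  Under the null of no habitat effect the directions are
fair coin flips, so the one-sided exact binomial (sign) test applies; it is
computed exactly with rational arithmetic, never by normal approximation.
Assembly sizes can be corrected for completeness (size × 100/completeness),
which maps an assembly back to its estimated true genome length.

The module also provides habitat-stratified tests, t/bootstrap confidence
intervals on mean percent differences, the chance probability that a set of
m independent comparisons all fall in the minority direction ((1 − q)^m),
paired sign tests over arbitrary precomputed per-tip features, and a
simulation-based phylogenetic ANOVA: the observed one-way F statistic is
referred to a null distribution of F values from Brownian-motion traits
simulated on the same tree (rate = mean squared standardized contrast).
"""
from __future__ import annotations

import dataclasses
import enum
import math
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .comparative_regression import pic
from .comparison_extraction import IndependentComparison
from .phylo_io import AnnotatedTree

__all__ = [
    "ComparisonSummary",
    "SignTestResult",
    "IntervalEstimate",
    "HabitatStratum",
    "PhyloAnovaResult",
    "corrected_size",
    "summarize_comparison",
    "sign_test",
    "sign_test_from_summaries",
    "mean_percent_diff_ci",
    "pattern_probability",
    "stratify_by_habitat",
    "phylogenetic_anova",
    "paired_feature_sign_test",
    "summaries_to_frame",
]


class Direction(str, enum.Enum):
    GUT_LARGER = "gut_larger"
    GUT_SMALLER = "gut_smaller"


@dataclasses.dataclass(frozen=True)
class ComparisonSummary:
    """Size divergence of one comparison, raw and completeness-corrected.

    ``percent_diff`` = 100·(mean_gut − mean_nongut)/mean_nongut;
    ``log_fold_diff`` = log(mean_gut/mean_nongut) (natural log by default).
    ``gut_larger`` is None when the clade means tie exactly, in which case
    the comparison is dropped from sign tests.
    """

    comparison_id: str
    mean_gut_size: float
    mean_nongut_size: float
    mean_gut_size_corrected: float
    mean_nongut_size_corrected: float
    percent_diff: float
    percent_diff_corrected: float
    log_fold_diff: float
    log_fold_diff_corrected: float
    gut_larger: bool | None

    @property
    def tie(self) -> bool:
        return self.gut_larger is None


@dataclasses.dataclass(frozen=True)
class SignTestResult:
    n: int
    k: int
    p_one_sided: float
    direction: Direction = Direction.GUT_LARGER


@dataclasses.dataclass(frozen=True)
class IntervalEstimate:
    mean: float
    ci_low: float
    ci_high: float
    method: str
    level: float = 0.95
    n_boot: int = 0
    seed: int | None = None


def corrected_size(assembly_size: float, completeness: float) -> float:
    """Estimated true genome size: assembly length scaled by completeness."""
    if not (0.0 < completeness <= 100.0):
        raise ValueError(f"completeness must lie in (0, 100], got {completeness}")
    return assembly_size * 100.0 / completeness


def summarize_comparison(
    comparison: IndependentComparison,
    records: Mapping[str, object],
    log_base: float = math.e,
) -> ComparisonSummary:
    """Clade-mean sizes and their divergence for one comparison.

    ``records`` maps tip id to any object with ``assembly_size`` and
    ``completeness`` attributes (TipRecords for isolates, MAG rows adapted
    likewise).  Missing tips are reported by name.
    """
    missing = [t for t in comparison.tips if t not in records]
    if missing:
        raise ValueError(f"size/completeness missing for tips {sorted(missing)}")

    def means(tips: Iterable[str]) -> tuple[float, float]:
        raw = [float(records[t].assembly_size) for t in tips]
        corr = [corrected_size(records[t].assembly_size, records[t].completeness) for t in tips]
        return sum(raw) / len(raw), sum(corr) / len(corr)

    g_raw, g_corr = means(sorted(comparison.gut_tips))
    o_raw, o_corr = means(sorted(comparison.nongut_tips))
    log_div = math.log(log_base)
    return ComparisonSummary(
        comparison_id=comparison.comparison_id,
        mean_gut_size=g_raw,
        mean_nongut_size=o_raw,
        mean_gut_size_corrected=g_corr,
        mean_nongut_size_corrected=o_corr,
        percent_diff=100.0 * (g_raw - o_raw) / o_raw,
        percent_diff_corrected=100.0 * (g_corr - o_corr) / o_corr,
        log_fold_diff=math.log(g_raw / o_raw) / log_div,
        log_fold_diff_corrected=math.log(g_corr / o_corr) / log_div,
        gut_larger=None if g_raw == o_raw else g_raw > o_raw,
    )


def sign_test(k: int, n: int, direction: Direction | str = Direction.GUT_LARGER) -> SignTestResult:
    """One-sided exact binomial upper tail: P(X ≥ k), X ~ Binomial(n, 1/2).

    Computed with exact rational arithmetic (Σ C(n,i)/2^n) and only then
    converted to float, so printed p-values are correct to full double
    precision even deep in the tail.
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid sign-test counts k={k}, n={n}")
    tail = sum(math.comb(n, i) for i in range(k, n + 1))
    p = float(Fraction(tail, 2**n))
    return SignTestResult(n=n, k=k, p_one_sided=p, direction=Direction(direction))


def sign_test_from_summaries(
    summaries: Sequence[ComparisonSummary],
    direction: Direction | str = Direction.GUT_LARGER,
    corrected: bool = False,
) -> SignTestResult:
    """Sign test over non-tied comparisons; ties are excluded from n."""
    direction = Direction(direction)
    diffs = [
        (s.percent_diff_corrected if corrected else s.percent_diff)
        for s in summaries
    ]
    nonzero = [d for d in diffs if d != 0.0]
    n = len(nonzero)
    if n == 0:
        return SignTestResult(n=0, k=0, p_one_sided=math.nan, direction=direction)
    if direction is Direction.GUT_LARGER:
        k = sum(d > 0 for d in nonzero)
    else:
        k = sum(d < 0 for d in nonzero)
    return sign_test(k, n, direction)


def mean_percent_diff_ci(
    percent_diffs: Sequence[float],
    method: str = "t",
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> IntervalEstimate:
    """Two-sided CI on the mean percent difference.

    ``t``: mean ± t_{1−α/2, n−1}·sd/√n.  ``bootstrap``: seeded percentile
    interval over n_boot resamples (deterministic for a given seed).
    """
    x = np.asarray(percent_diffs, dtype=float)
    mean = float(np.mean(x))
    if method == "t":
        if len(x) < 2:
            raise ValueError("t interval requires at least 2 values")
        sd = float(np.std(x, ddof=1))
        half = stats.t.ppf(0.5 + level / 2.0, len(x) - 1) * sd / math.sqrt(len(x))
        return IntervalEstimate(mean, mean - half, mean + half, "t", level)
    if method == "bootstrap":
        if len(x) < 1:
            raise ValueError("bootstrap requires at least 1 value")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boots = x[idx].mean(axis=1)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        return IntervalEstimate(mean, float(lo), float(hi), "bootstrap", level, n_boot, seed)
    raise ValueError(f"unknown CI method {method!r}")


def pattern_probability(q: float, m: int) -> float:
    """Chance that m independent comparisons all fall in the minority
    direction when a fraction q of comparisons goes the other way."""
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return (1.0 - q) ** m


@dataclasses.dataclass(frozen=True)
class HabitatStratum:
    habitat: str
    sign: SignTestResult
    mean_percent_diff: float
    mean_percent_diff_corrected: float
    interval: IntervalEstimate | None


def stratify_by_habitat(
    comparisons: Sequence[IndependentComparison],
    summaries: Sequence[ComparisonSummary],
    ci_method: str = "t",
    level: float = 0.95,
) -> dict[str, HabitatStratum]:
    """Split the sign test by non-gut habitat.

    A comparison belongs to habitat h iff all its non-gut tips come from h;
    heterogeneous comparisons go into a 'mixed' stratum.  Empty strata are
    omitted.
    """
    by_id = {s.comparison_id: s for s in summaries}
    groups: dict[str, list[ComparisonSummary]] = {}
    for c in comparisons:
        if c.comparison_id in by_id:
            groups.setdefault(c.stratum(), []).append(by_id[c.comparison_id])
    out: dict[str, HabitatStratum] = {}
    for habitat in sorted(groups):
        ss = groups[habitat]
        diffs = [s.percent_diff for s in ss]
        interval = None
        if ci_method == "t" and len(diffs) >= 2:
            interval = mean_percent_diff_ci(diffs, "t", level)
        elif ci_method == "bootstrap":
            interval = mean_percent_diff_ci(diffs, "bootstrap", level)
        out[habitat] = HabitatStratum(
            habitat=habitat,
            sign=sign_test_from_summaries(ss),
            mean_percent_diff=float(np.mean(diffs)),
            mean_percent_diff_corrected=float(np.mean([s.percent_diff_corrected for s in ss])),
            interval=interval,
        )
    return out


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


@dataclasses.dataclass(frozen=True)
class PhyloAnovaResult:
    f_obs: float
    p_phylo: float
    n_sim: int
    sigma2: float


def _anova_f(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized one-way ANOVA F over rows of a (n_sim, n_tips) matrix."""
    if values.ndim == 1:
        values = values[None, :]
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in range(n_groups):
        sel = values[:, group_idx == g]
        gm = sel.mean(axis=1, keepdims=True)
        ssb += sel.shape[1] * (gm[:, 0] - grand[:, 0]) ** 2
        ssw += ((sel - gm) ** 2).sum(axis=1)
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def phylogenetic_anova(
    tree: AnnotatedTree | dendropy.Tree,
    trait: Mapping[str, float],
    groups: Mapping[str, object],
    n_sim: int = 1000,
    seed: int | None = None,
) -> PhyloAnovaResult:
    """Simulation-based phylogenetic ANOVA (Garland-style null).

    The observed one-way F of tip trait values by group is compared against
    F statistics from ``n_sim`` Brownian-motion traits simulated on the same
    tree, with the BM rate set to the mean squared standardized contrast of
    the observed trait; p = (1 + #{F_sim ≥ F_obs})/(1 + n_sim).  Because F is
    scale-invariant, the null p-value is uniform on its discrete grid.
    """
    import warnings

    dtree = tree.tree if isinstance(tree, AnnotatedTree) else tree
    nodes = list(dtree.preorder_node_iter())
    labels = [n.taxon.label for n in nodes if n.is_leaf()]
    values = np.array([float(trait[l]) for l in labels])
    group_labels = sorted({str(groups[l]) for l in labels})
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    group_idx = np.array([group_labels.index(str(groups[l])) for l in labels])
    counts = np.bincount(group_idx, minlength=len(group_labels))
    if (counts < 2).any():
        small = [group_labels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 tips: {small}")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a very coarse p-value grid", stacklevel=2)

    if np.ptp(values) == 0.0:
        # A constant trait carries no signal at all: F is 0 by convention.
        return PhyloAnovaResult(f_obs=0.0, p_phylo=1.0, n_sim=n_sim, sigma2=0.0)
    f_obs = float(_anova_f(values, group_idx, len(group_labels))[0])
    sigma2 = float(np.mean(pic(dtree, trait).contrasts ** 2))

    # Vectorized BM on the tree: one normal increment per edge per replicate.
    rng = np.random.default_rng(seed)
    node_pos = {id(node): i for i, node in enumerate(nodes)}
    sims = np.zeros((n_sim, len(nodes)))
    tip_cols = []
    for i, node in enumerate(nodes):
        parent = node.parent_node
        if parent is not None:
            length = node.edge.length or 0.0
            sims[:, i] = sims[:, node_pos[id(parent)]]
            if length > 0.0 and sigma2 > 0.0:
                sims[:, i] += rng.standard_normal(n_sim) * math.sqrt(sigma2 * length)
        if node.is_leaf():
            tip_cols.append(i)
    f_sim = _anova_f(sims[:, tip_cols], group_idx, len(group_labels))
    p = (1.0 + float(np.sum(f_sim >= f_obs))) / (1.0 + n_sim)
    return PhyloAnovaResult(f_obs=f_obs, p_phylo=p, n_sim=n_sim, sigma2=sigma2)


# ---------------------------------------------------------------------------
# Paired tests on arbitrary per-tip features


@dataclasses.dataclass(frozen=True)
class FeatureSignTest:
    sign: SignTestResult
    mean_paired_diff: float
    n_ties: int


def paired_feature_sign_test(
    comparisons: Sequence[IndependentComparison],
    feature: Mapping[str, float],
) -> FeatureSignTest:
    """Sign test on the direction of a per-tip feature across comparisons.

    For each comparison the clade-mean feature of the gut side is compared
    with the non-gut side; ties are excluded.  With every comparison tied,
    the test is undefined and the p-value is NaN.
    """
    diffs = []
    ties = 0
    for c in comparisons:
        missing = [t for t in c.tips if t not in feature]
        if missing:
            raise ValueError(f"feature values missing for tips {sorted(missing)}")
        g = float(np.mean([feature[t] for t in sorted(c.gut_tips)]))
        o = float(np.mean([feature[t] for t in sorted(c.nongut_tips)]))
        if g == o:
            ties += 1
        else:
            diffs.append(g - o)
    if not diffs:
        return FeatureSignTest(
            sign=SignTestResult(n=0, k=0, p_one_sided=math.nan),
            mean_paired_diff=0.0,
            n_ties=ties,
        )
    k = sum(d > 0 for d in diffs)
    return FeatureSignTest(
        sign=sign_test(k, len(diffs)),
        mean_paired_diff=float(np.mean(diffs)),
        n_ties=ties,
    )


def summaries_to_frame(summaries: Sequence[ComparisonSummary]):
    """Tabular view with a stable column order, for TSV output."""
    import pandas as pd

    cols = [
        "comparison_id",
        "mean_gut_size",
        "mean_nongut_size",
        "mean_gut_size_corrected",
        "mean_nongut_size_corrected",
        "percent_diff",
        "percent_diff_corrected",
        "log_fold_diff",
        "log_fold_diff_corrected",
        "gut_larger",
    ]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in cols} for s in summaries], columns=cols
    )
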