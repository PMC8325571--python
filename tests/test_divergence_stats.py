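"""Size divergences, exact sign tests, CIs, and the phylogenetic ANOVA."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gexpand.comparison_extraction import (
    IndependentComparison,
    Level,
    Polarity,
    find_independent_comparisons,
)
from gexpand.divergence_stats import (
    Direction,
    corrected_size,
    mean_percent_diff_ci,
    paired_feature_sign_test,
    pattern_probability,
    phylogenetic_anova,
    sign_test,
    sign_test_from_summaries,
    stratify_by_habitat,
    summarize_comparison,
)
from gexpand.phylo_io import Habitat, TipRecord

from conftest import annotate
from oracles import sign_test_enumeration


class TestCorrectedSize:
    @pytest.mark.parametrize(
        "size,completeness,expected",
        [(1_800_000, 90.0, 2_000_000), (123, 100.0, 123), (3_000_000, 50.0, 6_000_000)],
    )
    def test_scales_by_completeness(self, size, completeness, expected):
        assert corrected_size(size, completeness) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 100.5])
    def test_rejects_out_of_range_completeness(self, bad):
        with pytest.raises(ValueError):
            corrected_size(1000, bad)


def _comparison(gut, nongut):
    return IndependentComparison(
        comparison_id="c0",
        group="X",
        gut_tips=frozenset(gut),
        nongut_tips=frozenset(nongut),
        nongut_habitats=frozenset({Habitat.ORAL}),
        polarity=Polarity.UNPOLARIZED,
        level=Level.CONGENERIC,
    )


def _records(sizes, completeness=None):
    return {
        t: TipRecord(t, "X", Habitat.GUT if t.startswith("g") else Habitat.ORAL,
                     s, (completeness or {}).get(t, 100.0))
        for t, s in sizes.items()
    }


class TestSummaries:
    def test_percent_and_direction(self):
        s = summarize_comparison(
            _comparison({"g1"}, {"o1"}), _records({"g1": 2_100_000, "o1": 2_000_000})
        )
        assert s.percent_diff == pytest.approx(5.0)
        assert s.gut_larger is True
        assert s.log_fold_diff == pytest.approx(math.log(1.05))

    def test_tie_flagged_and_dropped_from_test(self):
        s = summarize_comparison(
            _comparison({"g1"}, {"o1"}), _records({"g1": 2_000_000, "o1": 2_000_000})
        )
        assert s.tie and s.log_fold_diff == 0.0
        res = sign_test_from_summaries([s])
        assert res.n == 0 and math.isnan(res.p_one_sided)

    def test_negative_difference(self):
        s = summarize_comparison(
            _comparison({"g1"}, {"o1"}), _records({"g1": 1_900_000, "o1": 2_000_000})
        )
        assert s.percent_diff == pytest.approx(-5.0)
        assert s.log_fold_diff == pytest.approx(math.log(0.95))

    def test_correction_inflates_incomplete_assemblies(self):
        s = summarize_comparison(
            _comparison({"g1"}, {"o1"}),
            _records({"g1": 1_800_000, "o1": 2_000_000}, {"g1": 90.0}),
        )
        assert s.mean_gut_size_corrected == pytest.approx(2_000_000)
        assert s.mean_gut_size_corrected >= s.mean_gut_size
        assert s.percent_diff_corrected == pytest.approx(0.0)

    def test_equal_completeness_leaves_percent_diff_unchanged(self):
        s = summarize_comparison(
            _comparison({"g1"}, {"o1"}),
            _records({"g1": 2_100_000, "o1": 2_000_000}, {"g1": 92.0, "o1": 92.0}),
        )
        assert s.percent_diff_corrected == pytest.approx(s.percent_diff)

    def test_missing_tip_named(self):
        with pytest.raises(ValueError, match="o1"):
            summarize_comparison(_comparison({"g1"}, {"o1"}), _records({"g1": 1}))


class TestSignTest:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (16, 21, 27_896 / 2_097_152),  # 0.013302
            (10, 15, 0.15087890625),
            (5, 5, 0.03125),
            (45, 59, 3.265315222456683e-05),
            (17, 24, 0.03196), (16, 23, 0.04657), (19, 29, 0.06802),
            (22, 25, 2_626 / 33_554_432),
        ],
    )
    def test_exact_tail_values(self, k, n, expected):
        assert sign_test(k, n).p_one_sided == pytest.approx(expected, rel=2e-4)

    def test_matches_exhaustive_enumeration(self):
        for n in (1, 2, 3, 5, 8, 12, 15):
            for k in range(n + 1):
                assert sign_test(k, n).p_one_sided == pytest.approx(
                    sign_test_enumeration(k, n), abs=1e-15
                )

    def test_matches_scipy_binomtest(self):
        for k, n in [(16, 21), (45, 59), (0, 7), (7, 7), (3, 10)]:
            expected = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
            assert sign_test(k, n).p_one_sided == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 40).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_tail_complement_inequality(self, nk):
        n, k = nk
        p_hi = sign_test(k, n).p_one_sided
        p_lo = sign_test(n - k + 1, n).p_one_sided if k >= 1 else 0.0
        assert p_hi + p_lo <= 1.0 + 1e-12

    def test_invalid_counts_rejected(self):
        for k, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                sign_test(k, n)

    def test_direction_reciprocal_counts_smaller(self):
        summaries = [
            summarize_comparison(_comparison({"g1"}, {"o1"}), _records({"g1": g, "o1": 2_000_000}))
            for g in (1_900_000, 1_950_000, 2_100_000)
        ]
        res = sign_test_from_summaries(summaries, Direction.GUT_SMALLER)
        assert (res.k, res.n) == (2, 3)


class TestIntervals:
    def test_t_interval_closed_form(self):
        iv = mean_percent_diff_ci([1.0, 2.0, 3.0], "t", 0.95)
        assert iv.mean == pytest.approx(2.0)
        assert iv.ci_low == pytest.approx(-0.48414, abs=1e-4)
        assert iv.ci_high == pytest.approx(4.48414, abs=1e-4)

    def test_constant_values_zero_width(self):
        iv = mean_percent_diff_ci([5.0, 5.0, 5.0], "t")
        assert iv.ci_low == iv.ci_high == iv.mean == 5.0

    def test_bootstrap_deterministic_under_seed(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        a = mean_percent_diff_ci(x, "bootstrap", n_boot=2000, seed=3)
        b = mean_percent_diff_ci(x, "bootstrap", n_boot=2000, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.mean <= a.ci_high

    def test_t_needs_two_values(self):
        with pytest.raises(ValueError):
            mean_percent_diff_ci([1.0], "t")


class TestPatternProbability:
    def test_surveillance_pattern_value(self):
        p = pattern_probability(0.763, 5)
        assert p == pytest.approx(7.477e-4, rel=1e-3)
        assert round(100 * p, 3) == 0.075  # as a percentage

    @pytest.mark.parametrize("q,m,expected", [(0.5, 3, 0.125), (1.0, 4, 0.0)])
    def test_closed_form(self, q, m, expected):
        assert pattern_probability(q, m) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 1))
    def test_single_comparison_is_complement(self, q):
        assert pattern_probability(q, 1) == pytest.approx(1.0 - q)


class TestStratification:
    def _stratified(self, counts):
        """counts: habitat -> (k positive, n)."""
        comps, summaries = [], []
        i = 0
        for habitat, (k, n) in counts.items():
            for j in range(n):
                cid = f"c{i:04d}"
                comp = IndependentComparison(
                    comparison_id=cid, group=f"G{i}",
                    gut_tips=frozenset({f"g{i}"}), nongut_tips=frozenset({f"o{i}"}),
                    nongut_habitats=frozenset({Habitat(habitat)}),
                    polarity=Polarity.UNPOLARIZED, level=Level.CONGENERIC,
                )
                size = 2_100_000 if j < k else 1_900_000
                summaries.append(
                    summarize_comparison(comp, _records({f"g{i}": size, f"o{i}": 2_000_000}))
                )
                comps.append(comp)
                i += 1
        return comps, summaries

    def test_oral_and_urogenital_strata(self):
        comps, summaries = self._stratified({"oral": (22, 25), "urogenital": (19, 29)})
        strata = stratify_by_habitat(comps, summaries)
        assert set(strata) == {"oral", "urogenital"}
        assert strata["oral"].sign.k == 22
        assert strata["oral"].sign.p_one_sided == pytest.approx(7.826e-5, rel=1e-3)
        assert strata["urogenital"].sign.p_one_sided == pytest.approx(0.068, abs=5e-4)

    def test_empty_strata_omitted(self):
        comps, summaries = self._stratified({"skin": (2, 3)})
        assert set(stratify_by_habitat(comps, summaries)) == {"skin"}


class TestPairedFeature:
    def _setup(self):
        atree = annotate(
            "((g1:1,o1:1):1,(g2:1,o2:1):1);",
            {"g1": "gut", "o1": "oral", "g2": "gut", "o2": "oral"},
            genera={"g1": "A", "o1": "A", "g2": "B", "o2": "B"},
            sizes={"g1": 3_100_000, "o1": 3_000_000, "g2": 2_000_000, "o2": 2_100_000},
        )
        return atree, find_independent_comparisons(atree)

    def test_identical_feature_everywhere_is_na(self):
        atree, comps = self._setup()
        res = paired_feature_sign_test(comps, {t: 0.5 for t in atree.records})
        assert res.sign.n == 0 and math.isnan(res.sign.p_one_sided)
        assert res.n_ties == len(comps)

    def test_genome_size_feature_reproduces_main_sign_test(self):
        atree, comps = self._setup()
        feature = {t: float(r.assembly_size) for t, r in atree.records.items()}
        res = paired_feature_sign_test(comps, feature)
        main = sign_test_from_summaries([summarize_comparison(c, atree.records) for c in comps])
        assert (res.sign.k, res.sign.n, res.sign.p_one_sided) == (main.k, main.n, main.p_one_sided)

    def test_negating_feature_swaps_counts(self):
        atree, comps = self._setup()
        feature = {t: float(r.assembly_size) for t, r in atree.records.items()}
        res = paired_feature_sign_test(comps, feature)
        neg = paired_feature_sign_test(comps, {t: -v for t, v in feature.items()})
        assert neg.sign.k == res.sign.n - res.sign.k
        assert neg.mean_paired_diff == pytest.approx(-res.mean_paired_diff)


class TestPhylogeneticAnova:
    def test_constant_trait_gives_f_zero_p_one(self):
        atree = annotate(
            "((a:1,b:1):1,(c:1,d:1):1);", {"a": "gut", "b": "gut", "c": "oral", "d": "oral"}
        )
        groups = {t: r.habitat.value for t, r in atree.records.items()}
        res = phylogenetic_anova(atree, {t: 1.0 for t in groups}, groups, n_sim=200, seed=1)
        assert res.f_obs == 0.0 and res.p_phylo == 1.0

    def test_star_tree_matches_ordinary_anova(self):
        # with no shared ancestry the BM null is iid normal, so the
        # simulation p-value should approximate the parametric F p-value
        rng = np.random.default_rng(5)
        n = 40
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        trait = {f"t{i}": float(rng.standard_normal() + (0.8 if i < n // 2 else 0.0))
                 for i in range(n)}
        groups = {f"t{i}": "A" if i < n // 2 else "B" for i in range(n)}
        from gexpand.phylo_io import tree_from_string

        tree = tree_from_string(newick)
        res = phylogenetic_anova(tree, trait, groups, n_sim=4000, seed=11)
        x = [trait[t] for t in groups if groups[t] == "A"]
        y = [trait[t] for t in groups if groups[t] == "B"]
        f, p_param = stats.f_oneway(x, y)
        assert res.f_obs == pytest.approx(f)
        assert res.p_phylo == pytest.approx(p_param, abs=0.03)

    def test_small_group_rejected(self):
        atree = annotate(
            "((a:1,b:1):1,(c:1,d:1):1);", {"a": "gut", "b": "gut", "c": "gut", "d": "oral"}
        )
        groups = {t: r.habitat.value for t, r in atree.records.items()}
        with pytest.raises(ValueError, match="fewer than 2"):
            phylogenetic_anova(atree, {t: 1.0 for t in groups}, groups, n_sim=200, seed=1)

    def test_low_n_sim_warns(self):
        atree = annotate(
            "((a:1,b:1):1,(c:1,d:1):1);", {"a": "gut", "b": "gut", "c": "oral", "d": "oral"}
        )
        groups = {t: r.habitat.value for t, r in atree.records.items()}
        trait = {"a": 1.0, "b": 2.0, "c": 0.5, "d": 1.5}
        with pytest.warns(UserWarning, match="n_sim"):
            phylogenetic_anova(atree, trait, groups, n_sim=50, seed=1)
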