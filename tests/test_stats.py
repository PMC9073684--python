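import math

import numpy as np
import pytest
import scipy.stats

from sirescan import (combine_pvalues, compare_age_distributions,
                      heterogeneity_test, heterogeneity_total,
                      spearman_trend, vnvs_curve)
from sirescan.spectrum import FrequencyBin, default_bins

from ._oracles import (oracle_chi_square, oracle_mannwhitney_exact_p,
                       oracle_spearman_exact_p)


def curve_from_ratios(ratios):
    """A curve whose per-bin ratios are exactly the given values
    (vS fixed at 1000 so ratios are rational and defined)."""
    bins = []
    for b, r in zip(default_bins(), ratios):
        if r is None:
            bins.append(FrequencyBin(b.lower, b.upper, b.label, 5, 0))
        else:
            bins.append(FrequencyBin(b.lower, b.upper, b.label,
                                     int(round(r * 1000)), 1000))
    return vnvs_curve(bins)


class TestSpearmanTrend:
    def test_strict_decline_gives_exact_minimum_p(self):
        curve = curve_from_ratios([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
        res = spearman_trend(curve)
        assert res.rho == pytest.approx(-1.0)
        assert res.exact
        assert res.p_value == pytest.approx(2 / 720)

    def test_one_distant_swap_matches_published_convention(self):
        # rank pattern with sum of squared rank differences 6 -> rho -0.829,
        # exact two-sided p 42/720 ~ 0.058
        curve = curve_from_ratios([0.9, 0.8, 0.7, 0.4, 0.6, 0.5])
        res = spearman_trend(curve)
        assert res.rho == pytest.approx(-0.8286, abs=1e-3)
        assert res.p_value == pytest.approx(42 / 720)

    def test_constant_ratios_have_no_trend(self):
        res = spearman_trend(curve_from_ratios([0.5] * 6))
        assert res.rho == 0.0
        assert res.p_value == 1.0

    def test_undefined_bins_excluded_from_n(self):
        curve = curve_from_ratios([0.9, 0.5, 0.3, None, 0.2, None])
        res = spearman_trend(curve)
        assert res.n_bins_used == 4

    def test_too_few_usable_bins(self):
        curve = curve_from_ratios([0.9, 0.5, None, None, None, None])
        with pytest.raises(ValueError, match=">= 3"):
            spearman_trend(curve)

    @pytest.mark.parametrize("ratios", [
        [0.31, 0.9, 0.12, 0.77, 0.5],
        [0.2, 0.8, 0.1, 0.6, 0.4, 0.9],
        [0.5, 0.1, 0.5, 0.7, 0.3, 0.2],   # includes a tie
    ])
    def test_exact_p_matches_enumeration_oracle(self, ratios):
        curve = curve_from_ratios(ratios + [None] * (6 - len(ratios)))
        res = spearman_trend(curve)
        assert res.p_value == pytest.approx(oracle_spearman_exact_p(ratios))

    def test_exact_p_equals_two_over_factorial_for_monotone(self):
        for n in (4, 5, 6, 7):
            ratios = [0.9 - 0.1 * i for i in range(n)]
            curve = curve_from_ratios(ratios + [None] * (6 - n)) if n <= 6 \
                else None
            if curve is None:
                continue
            res = spearman_trend(curve)
            assert res.p_value == pytest.approx(2 / math.factorial(n))


class TestCombinePvalues:
    def test_fisher_five_times_005(self):
        # -2 * 5 * ln(0.05) = 29.957; chi-square tail with 10 df
        stat = -2 * 5 * math.log(0.05)
        assert stat == pytest.approx(29.957, abs=1e-3)
        expected = scipy.stats.chi2.sf(stat, 10)
        combined = combine_pvalues([0.05] * 5)
        assert combined == pytest.approx(expected)
        assert combined < 0.001

    def test_single_p_returned_unchanged(self):
        assert combine_pvalues([0.0317]) == pytest.approx(0.0317)

    def test_p_of_one_contributes_nothing(self):
        assert combine_pvalues([0.05, 1.0]) == pytest.approx(
            scipy.stats.chi2.sf(-2 * math.log(0.05), 4))

    def test_stouffer_available(self):
        assert 0 < combine_pvalues([0.05] * 5, method="stouffer") < 0.001

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_pvalues([])
        with pytest.raises(ValueError):
            combine_pvalues([0.0, 0.5])


class TestHeterogeneity:
    def test_identical_groups_give_zero(self):
        res = heterogeneity_test({f"g{i}": (10, 100) for i in range(5)})
        assert res.chi_square == pytest.approx(0.0)
        assert res.df == 4
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_drops_a_degree_of_freedom(self):
        counts = {f"g{i}": (10, 100) for i in range(4)}
        counts["empty"] = (0, 0)
        res = heterogeneity_test(counts)
        assert res.df == 3

    def test_statistic_matches_direct_oracle(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 7))
            table = rng.integers(1, 60, size=(2, k))
            counts = {f"g{j}": (int(table[0, j]), int(table[1, j]))
                      for j in range(k)}
            res = heterogeneity_test(counts)
            assert res.chi_square == pytest.approx(
                oracle_chi_square(table.tolist()))
            assert res.df == k - 1

    def test_group_order_invariance(self):
        counts = {"a": (5, 50), "b": (9, 30), "c": (2, 70)}
        res1 = heterogeneity_test(counts)
        res2 = heterogeneity_test(dict(reversed(list(counts.items()))))
        assert res1.chi_square == pytest.approx(res2.chi_square)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_test({"a": (1, 2), "empty": (0, 0)})

    def test_total_sums_statistics_and_df(self):
        parts = [heterogeneity_test({"a": (5, 50), "b": (9, 30)}, "c1"),
                 heterogeneity_test({"a": (7, 40), "b": (2, 60)}, "c2")]
        tot = heterogeneity_total(parts)
        assert tot.chi_square == pytest.approx(sum(p.chi_square
                                                   for p in parts))
        assert tot.df == 2
        assert tot.p_value == pytest.approx(
            scipy.stats.chi2.sf(tot.chi_square, 2))


class TestAgeComparisons:
    def test_separated_distributions_detected(self, rng):
        a = rng.normal(0.01, 0.002, size=50).tolist()
        b = (np.array(a) + 1.0).tolist()
        res = compare_age_distributions({"a": a, "b": b})
        assert res["kruskal"]["p_value"] < 0.001
        assert res["pairwise"].iloc[0]["p_value"] < 0.001

    def test_identical_groups_have_no_signal(self):
        vals = [0.01, 0.02, 0.03, 0.04]
        res = compare_age_distributions({"a": vals, "b": list(vals)})
        assert res["kruskal"]["statistic"] == pytest.approx(0.0, abs=1e-9)

    def test_small_sample_p_matches_exact_enumeration(self, rng):
        for _ in range(5):
            xs = rng.normal(size=5).round(3).tolist()
            ys = rng.normal(0.5, 1, size=6).round(3).tolist()
            res = compare_age_distributions({"x": xs, "y": ys})
            p = res["pairwise"].iloc[0]["p_value"]
            assert p == pytest.approx(oracle_mannwhitney_exact_p(xs, ys))

    def test_degenerate_all_tied_warns(self):
        with pytest.warns(UserWarning):
            res = compare_age_distributions({"a": [0.1, 0.1],
                                             "b": [0.1, 0.1]})
        assert res["kruskal"]["p_value"] == 1.0

    def test_medians_reported(self):
        res = compare_age_distributions({"a": [1.0, 2.0, 3.0],
                                         "b": [4.0, 5.0, 9.0]})
        assert res["medians"] == {"a": 2.0, "b": 5.0}

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_age_distributions({"a": [1.0, 2.0]})
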