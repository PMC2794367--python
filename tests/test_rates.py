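"""Direct standardisation, Wilson intervals, moving averages, rate contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import embermap as em
from embermap.errors import IncompleteStrataError, InvalidArgumentError
from embermap.standards import StandardPopulation


class TestDirectStandardisedRate:
    def test_single_stratum_identity(self):
        std = StandardPopulation({"40-44": 1.0})
        r = em.direct_standardised_rate({"40-44": 10}, {"40-44": 100_000}, std)
        assert r.rate == pytest.approx(10.0)

    def test_zero_deaths_zero_rate_zero_variance(self):
        std = StandardPopulation({"a": 0.5, "b": 0.5})
        r = em.direct_standardised_rate({"a": 0, "b": 0}, {"a": 1000, "b": 2000}, std)
        assert r.rate == 0.0
        assert r.variance == 0.0

    def test_two_band_weighted_sum(self):
        # hand expansion: 0.4 * (5/50000) + 0.6 * (40/200000) = 16 per 1e5
        std = StandardPopulation({"a": 0.4, "b": 0.6})
        d = {"a": 5, "b": 40}
        n = {"a": 50_000, "b": 200_000}
        r = em.direct_standardised_rate(d, n, std)
        brute = 1e5 * sum(std.weights[k] * d[k] / n[k] for k in d)
        brute_var = 1e10 * sum(std.weights[k] ** 2 * d[k] / n[k] ** 2 for k in d)
        assert r.rate == pytest.approx(16.0)
        assert r.rate == pytest.approx(brute)
        assert r.variance == pytest.approx(brute_var)

    def test_missing_band_with_weight_errors(self):
        std = StandardPopulation({"a": 0.5, "b": 0.5})
        with pytest.raises(IncompleteStrataError):
            em.direct_standardised_rate({"a": 1}, {"a": 1000}, std)

    def test_zero_weight_band_may_be_absent(self):
        std = StandardPopulation({"a": 1.0, "b": 0.0})
        r = em.direct_standardised_rate({"a": 3}, {"a": 30_000}, std)
        assert r.rate == pytest.approx(10.0)

    def test_split_aggregation_invariance(self):
        """Splitting one band's deaths/person-years over two areas and
        re-aggregating leaves the standardised rate unchanged."""
        std = StandardPopulation({"a": 0.3, "b": 0.7})
        whole = em.direct_standardised_rate({"a": 12, "b": 30}, {"a": 60_000, "b": 90_000}, std)
        d = {"a": 7 + 5, "b": 18 + 12}
        n = {"a": 25_000 + 35_000, "b": 50_000 + 40_000}
        split = em.direct_standardised_rate(d, n, std)
        assert split.rate == pytest.approx(whole.rate)

    def test_variance_scales_inversely_with_person_years(self):
        std = StandardPopulation({"a": 0.4, "b": 0.6})
        base = em.direct_standardised_rate({"a": 5, "b": 40}, {"a": 5e4, "b": 2e5}, std)
        m = 4
        scaled = em.direct_standardised_rate(
            {"a": 5 * m, "b": 40 * m}, {"a": 5e4 * m, "b": 2e5 * m}, std
        )
        assert scaled.rate == pytest.approx(base.rate)
        assert scaled.variance == pytest.approx(base.variance / m)


class TestProportionCI:
    def test_zero_successes_lower_bound_zero(self):
        p, lo, hi = em.proportion_ci(0, 100)
        assert p == 0.0
        assert lo == 0.0
        assert hi > 0

    def test_all_successes_upper_bound_one(self):
        p, lo, hi = em.proportion_ci(100, 100)
        assert p == 1.0
        assert hi == 1.0

    def test_matches_wilson_closed_form(self):
        # independent evaluation of the Wilson score interval
        k, n, z = 30, 100, stats.norm.ppf(0.975)
        phat = k / n
        centre = (phat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        p, lo, hi = em.proportion_ci(k, n)
        assert (p, lo, hi) == pytest.approx((phat, centre - half, centre + half))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            em.proportion_ci(1, 0)
        with pytest.raises(InvalidArgumentError):
            em.proportion_ci(5, 3)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = pd.Series([4.0] * 6, index=range(1991, 1997))
        out = em.moving_average(s, window=3)
        np.testing.assert_allclose(out["value"], 4.0)

    def test_window_three_hand_values(self):
        s = pd.Series([1, 2, 3, 4, 5], index=range(2000, 2005), dtype=float)
        out = em.moving_average(s, window=3)
        np.testing.assert_allclose(out["value"], [1.5, 2, 3, 4, 4.5])
        assert list(out["partial"]) == [True, False, False, False, True]

    def test_window_one_is_identity(self):
        s = pd.Series([3.0, 1.0, 2.0], index=range(2000, 2003))
        out = em.moving_average(s, window=1)
        np.testing.assert_allclose(out["value"], s.to_numpy())
        assert not out["partial"].any()

    def test_window_longer_than_series_errors(self):
        s = pd.Series([1.0, 2.0], index=[2000, 2001])
        with pytest.raises(InvalidArgumentError):
            em.moving_average(s, window=3)

    def test_nonconsecutive_years_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=[2000, 2002, 2003])
        with pytest.raises(InvalidArgumentError):
            em.moving_average(s, window=3)


class TestRateDifference:
    def test_equal_rates_symmetric_interval(self):
        d, lo, hi = em.rate_difference_ci(10.0, 1.0, 10.0, 1.0)
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_zero_variance_degenerate(self):
        d, lo, hi = em.rate_difference_ci(12.0, 0.0, 10.0, 0.0)
        assert (d, lo, hi) == (2.0, 2.0, 2.0)

    def test_closed_form(self):
        z = stats.norm.ppf(0.975)
        d, lo, hi = em.rate_difference_ci(26.7, 0.64, 20.0, 0.36)
        half = z * np.sqrt(0.64 + 0.36)
        assert d == pytest.approx(6.7)
        assert (lo, hi) == pytest.approx((6.7 - half, 6.7 + half))

    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            em.rate_difference_ci(1.0, -0.1, 1.0, 0.1)


class TestTable1:
    def test_single_area_matches_direct_rate(self, toy_counts, pair_graph):
        std = StandardPopulation({"40-44": 1.0})
        one = toy_counts[toy_counts["area_id"] == "a"]
        tab = em.table1(one, pair_graph, [(2000, 2000)], std)
        male = tab[(tab["sex"] == "male") & (tab["level"] == 1)].iloc[0]
        ref = em.direct_standardised_rate({"40-44": 7}, {"40-44": 50_000}, std)
        assert male["rate_all"] == pytest.approx(ref.rate)
        assert male["deaths_charcoal"] == 2
        assert male["prop_charcoal"] == pytest.approx(2 / 7)

    def test_zero_new_method_cell_has_wilson_ci(self, toy_counts, pair_graph):
        std = StandardPopulation({"40-44": 1.0})
        counts = toy_counts.copy()
        counts.loc[counts["method"] == "charcoal", "deaths"] = 0
        tab = em.table1(counts, pair_graph, [(2000, 2000)], std)
        assert (tab["prop_charcoal"] == 0).all()
        assert (tab["prop_lo"] == 0).all()
        assert (tab["prop_hi"] > 0).all()

    def test_missing_level_assignment_errors(self, toy_counts):
        g = em.AreaGraph(["a", "b"], {"a": ["b"], "b": ["a"]})
        with pytest.raises(InvalidArgumentError):
            em.table1(toy_counts, g, [(2000, 2000)], StandardPopulation({"40-44": 1.0}))

    def test_pooled_proportion_independent_of_grouping(self, small_scenario, grid10):
        _, counts, _ = small_scenario
        std = em.get_standard("segi", min_age_band="15-19")
        tab = em.table1(counts, grid10, [(2005, 2007)], std)
        male = tab[tab["sex"] == "male"]
        pooled = male["deaths_charcoal"].sum() / male["deaths_all"].sum()
        sub = counts[(counts["sex"] == "male") & counts["year"].between(2005, 2007)]
        direct = (
            sub[sub["method"] == "charcoal"]["deaths"].sum() / sub["deaths"].sum()
        )
        assert pooled == pytest.approx(direct)
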