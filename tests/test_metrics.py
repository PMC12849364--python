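"""Accessibility metrics: weighted quantiles, summaries, tests, deltas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import careloc as cl
from careloc.errors import ValidationError

from conftest import make_demand


class TestWeightedQuantile:
    def test_uniform_weights_lower_median(self):
        assert cl.weighted_quantile([5, 5, 10], [1, 1, 1], 0.5) == 5

    def test_toy_population_weighted_median(self):
        assert cl.weighted_quantile([10, 5, 5], [1, 2, 1], 0.5) == 5

    def test_q_one_is_maximum(self):
        assert cl.weighted_quantile([3, 9, 1], [1, 1, 1], 1.0) == 9

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            cl.weighted_quantile([1, 2], [0, 0], 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20),
        q=st.floats(0, 1),
        seed=st.integers(0, 1000),
    )
    def test_result_is_an_observed_value_and_monotone(self, values, q, seed):
        rng = np.random.default_rng(seed)
        weights = rng.uniform(0.1, 5.0, len(values))
        v = cl.weighted_quantile(values, weights, q)
        assert v in values
        if q < 1:
            assert v <= cl.weighted_quantile(values, weights, 1.0)


class TestSummarize:
    def test_toy_all_open(self, toy1):
        _, minutes = cl.nearest_assignment(toy1["T"], ["H1", "H2", "H3"])
        m = cl.summarize(minutes, toy1["demand"], threshold=8.0)
        assert m.weighted_mean == pytest.approx(6.25)
        assert m.unweighted_mean == pytest.approx(20 / 3)
        assert m.weighted_median == 5.0
        assert m.prop_above_threshold == pytest.approx(0.25)
        assert m.population_above_threshold == pytest.approx(1.0)

    def test_constant_times_degenerate_distribution(self, toy1):
        minutes = np.full(3, 12.0)
        m = cl.summarize(minutes, toy1["demand"], threshold=40.0)
        assert m.weighted_mean == m.weighted_median == 12.0
        assert (m.weighted_iqr_low, m.weighted_iqr_high) == (12.0, 12.0)
        assert m.prop_above_threshold == 0.0
        m2 = cl.summarize(minutes, toy1["demand"], threshold=11.0)
        assert m2.prop_above_threshold == 1.0

    def test_uniform_density_weighted_equals_unweighted(self):
        demand = make_demand(xy=np.zeros((5, 2)), density=[3.0] * 5)
        minutes = np.array([1.0, 7.0, 3.0, 9.0, 5.0])
        m = cl.summarize(minutes, demand)
        assert m.weighted_mean == pytest.approx(m.unweighted_mean)
        assert m.weighted_median == m.unweighted_median
        assert m.weighted_iqr_low == m.unweighted_iqr_low
        assert m.weighted_iqr_high == m.unweighted_iqr_high

    def test_threshold_strictly_exceeding(self):
        demand = make_demand(xy=np.zeros((2, 2)), density=[1.0, 1.0])
        m = cl.summarize(np.array([40.0, 41.0]), demand, threshold=40.0)
        assert m.prop_above_threshold == pytest.approx(0.5)

    def test_weighted_mean_bounded_by_extremes(self):
        rng = np.random.default_rng(3)
        demand = make_demand(xy=np.zeros((10, 2)), density=rng.uniform(1, 50, 10))
        minutes = rng.uniform(5, 80, 10)
        m = cl.summarize(minutes, demand)
        assert minutes.min() <= m.weighted_mean <= minutes.max()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        demand = make_demand(xy=np.zeros((12, 2)), density=rng.uniform(1, 9, 12))
        minutes = rng.uniform(1, 60, 12)
        s = 2.5
        m1 = cl.summarize(minutes, demand, threshold=30.0)
        m2 = cl.summarize(s * minutes, demand, threshold=s * 30.0)
        for f in ("weighted_mean", "weighted_median", "weighted_iqr_low",
                  "weighted_iqr_high", "unweighted_mean", "unweighted_median"):
            assert getattr(m2, f) == pytest.approx(s * getattr(m1, f))
        assert m2.prop_above_threshold == pytest.approx(m1.prop_above_threshold)

    def test_length_mismatch_rejected(self, toy1):
        with pytest.raises(ValidationError):
            cl.summarize([1.0, 2.0], toy1["demand"])


class TestStratified:
    def test_single_class_equals_overall(self):
        demand = make_demand(xy=np.zeros((4, 2)), density=[1, 2, 3, 4],
                             urbanization=["rural"] * 4)
        minutes = np.array([10.0, 20.0, 30.0, 40.0])
        out = cl.stratified_metrics(minutes, demand)
        assert set(out) == {"overall", "rural"}
        assert out["rural"].weighted_mean == out["overall"].weighted_mean
        assert out["rural"].prop_above_threshold == out["overall"].prop_above_threshold

    def test_disjoint_ranges_give_zero_one_proportions(self):
        demand = make_demand(
            xy=np.zeros((4, 2)), density=[1, 1, 1, 1],
            urbanization=["urban", "urban", "rural", "rural"],
        )
        minutes = np.array([5.0, 10.0, 50.0, 60.0])
        out = cl.stratified_metrics(minutes, demand, threshold=40.0)
        assert out["urban"].prop_above_threshold == 0.0
        assert out["rural"].prop_above_threshold == 1.0

    def test_partition_conservation(self, small_country):
        sc = small_country
        _, minutes = cl.nearest_assignment(sc["T"], sc["hospitals"].service_ids)
        out = cl.stratified_metrics(minutes, sc["demand"])
        class_sum = sum(
            out[c].population_above_threshold
            for c in ("urban", "intermediate", "rural") if c in out
        )
        assert class_sum == pytest.approx(
            out["overall"].population_above_threshold, rel=1e-9
        )

    def test_rural_travel_time_exceeds_urban_on_seeded_country(self, small_country):
        # biased site placement concentrates hospitals in dense (urban)
        # cells, so rural weighted means should be the larger ones
        sc = small_country
        _, minutes = cl.nearest_assignment(sc["T"], sc["hospitals"].service_ids)
        out = cl.stratified_metrics(minutes, sc["demand"])
        if "rural" in out and "urban" in out:
            assert out["rural"].weighted_mean >= out["urban"].weighted_mean


class TestCompareDistributions:
    def test_identical_samples_p_near_one(self):
        x = np.arange(30.0)
        res = cl.compare_distributions(x, x)
        assert res.p_value >= 0.99

    def test_complete_separation_u_zero(self):
        res = cl.compare_distributions([1, 2, 3], [101, 102, 103])
        assert res.statistic == 0.0
        assert res.p_value < 0.1

    def test_u_statistic_matches_pair_count_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.integers(0, 20, rng.integers(5, 60)).astype(float)
            b = rng.integers(0, 20, rng.integers(5, 60)).astype(float)
            res = cl.compare_distributions(a, b)
            # brute-force O(n²): U_a = #(a > b) + ties/2
            u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert res.statistic == pytest.approx(u)

    def test_short_samples_rejected(self):
        with pytest.raises(ValidationError):
            cl.compare_distributions([1, 2], [3, 4, 5])

    def test_normality_p_values_reported(self):
        rng = np.random.default_rng(1)
        res = cl.compare_distributions(rng.normal(size=100),
                                       rng.exponential(size=100))
        assert 0 <= res.normality_p_a <= 1
        assert res.normality_p_b < 0.01  # exponential is clearly non-normal


class TestRelativeChange:
    def _metrics(self, wm, med, prop, pop):
        return cl.AccessMetrics(
            weighted_mean=wm, weighted_median=med, weighted_iqr_low=med - 5,
            weighted_iqr_high=med + 5, unweighted_mean=wm, unweighted_median=med,
            unweighted_iqr_low=med - 5, unweighted_iqr_high=med + 5,
            prop_above_threshold=prop, population_above_threshold=pop,
        )

    def test_identical_metrics_zero_deltas(self):
        m = self._metrics(20.0, 18.0, 0.1, 1000.0)
        rep = cl.relative_change(m, m)
        assert (rep["absolute_change"] == 0).all()
        assert (rep["percent_change"].fillna(0) == 0).all()

    def test_threshold_share_reduction_arithmetic(self):
        # 9.17% → 5.86%: −3.31 percentage points, −36.1% relative
        before = self._metrics(23.79, 22.20, 0.0917, 1e6)
        after = self._metrics(22.30, 20.97, 0.0586, 6e5)
        rep = cl.relative_change(before, after).set_index("field")
        pp = rep.loc["prop_above_threshold_percentage_points"]
        assert pp["absolute_change"] == pytest.approx(-3.31, abs=1e-9)
        assert pp["percent_change"] == pytest.approx(-36.1, abs=0.05)

    def test_median_reduction_arithmetic(self):
        # 28.32 → 24.08 minutes is a 14.97% reduction
        before = self._metrics(29.39, 28.32, 0.1, 1.0)
        after = self._metrics(24.56, 24.08, 0.1, 1.0)
        rep = cl.relative_change(before, after).set_index("field")
        assert rep.loc["unweighted_median", "percent_change"] == pytest.approx(
            -14.97, abs=0.005
        )

    def test_zero_baseline_reported_as_undefined(self):
        before = self._metrics(20.0, 18.0, 0.0, 0.0)
        after = self._metrics(19.0, 17.0, 0.05, 10.0)
        rep = cl.relative_change(before, after).set_index("field")
        assert np.isnan(rep.loc["prop_above_threshold", "percent_change"])
        assert rep.loc["prop_above_threshold", "absolute_change"] == pytest.approx(0.05)
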