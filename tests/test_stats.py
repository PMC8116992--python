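"""Statistics layer, checked against independent oracles.

The brute-force oracles deliberately avoid numpy: plain-python sums,
``statistics`` module quantiles (method="inclusive" is the same linear
interpolation convention) and scipy's reference implementations for
percentile-of-score and the rank-sum test.
"""

import math
import random
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, percentileofscore

from ngsqr import (
    SearchFilter,
    StatsError,
    Threshold,
    ThresholdConfig,
    compare_groups,
    dataset_summary,
    make_record,
    metric_distribution,
    percentile_of,
    rank_sum_p_value,
    sample_status,
)

METRIC = "sequencing.pct_q30"


def _records_from_values(values, specimen="ffpe"):
    return [make_record({"record_id": f"R{i}", METRIC: v,
                         "sample_prep.specimen_type": specimen})
            for i, v in enumerate(values)]


ALL = SearchFilter()


class TestMetricDistribution:
    def test_closed_form_small_group(self):
        s = metric_distribution(_records_from_values([1, 2, 3, 4, 5]), ALL, METRIC)
        assert (s.n, s.mean, s.median, s.min, s.max) == (5, 3, 3, 1, 5)
        assert s.q1 == 2 and s.q3 == 4
        assert s.sd == pytest.approx(statistics.stdev([1, 2, 3, 4, 5]))

    def test_empty_group_has_absent_statistics(self):
        s = metric_distribution(_records_from_values([1.0]),
                                SearchFilter(specimen_type="blood"), METRIC)
        assert s.n == 0 and s.mean is None and s.sd is None

    def test_sd_absent_for_single_value(self):
        s = metric_distribution(_records_from_values([7.0]), ALL, METRIC)
        assert s.n == 1 and s.sd is None and s.median == 7.0

    def test_missing_values_excluded_and_counted(self):
        records = _records_from_values([10.0, 20.0])
        records.append(make_record({"record_id": "R9",
                                    "sample_prep.specimen_type": "ffpe"}))
        s = metric_distribution(records, ALL, METRIC)
        assert (s.n, s.n_missing, s.mean) == (2, 1, 15.0)

    def test_unknown_or_non_numeric_metric_rejected(self):
        records = _records_from_values([1.0])
        with pytest.raises(StatsError):
            metric_distribution(records, ALL, "sequencing.no_such_metric")
        with pytest.raises(StatsError):
            metric_distribution(records, ALL, "sequencing.instrument")

    def test_matches_brute_force_on_many_random_small_groups(self):
        rng = random.Random(99)
        for trial in range(120):
            n = rng.randint(2, 25)
            values = [round(rng.uniform(0, 100), 2) for _ in range(n)]
            if rng.random() < 0.3:  # force ties
                values[: n // 2] = [values[0]] * (n // 2)
            threshold = Threshold(METRIC, "ge", rng.uniform(0, 100))
            s = metric_distribution(_records_from_values(values), ALL,
                                    METRIC, threshold)
            assert s.mean == pytest.approx(sum(values) / n)
            assert s.sd == pytest.approx(statistics.stdev(values))
            assert s.median == pytest.approx(statistics.median(values))
            q = statistics.quantiles(values, n=4, method="inclusive")
            assert s.q1 == pytest.approx(q[0])
            assert s.q3 == pytest.approx(q[2])
            assert s.min == min(values) and s.max == max(values)
            assert s.pass_fraction == pytest.approx(
                sum(v >= threshold.value for v in values) / n)
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


class TestPercentile:
    def test_all_tied_gives_50(self):
        values = np.full(10, 3.3)
        assert percentile_of(3.3, values) == 50.0

    def test_max_of_100_distinct_values_gives_99_5(self):
        values = np.arange(100, dtype=float)
        assert percentile_of(99.0, values) == 99.5

    def test_matches_scipy_mean_kind(self):
        rng = random.Random(5)
        for _ in range(100):
            values = [rng.choice([1.0, 2.0, 5.5, 9.0, rng.random() * 10])
                      for _ in range(rng.randint(1, 30))]
            v = rng.choice(values + [rng.random() * 10])
            assert percentile_of(v, np.array(values)) == pytest.approx(
                percentileofscore(values, v, kind="mean"))

    def test_monotone_and_bounded(self):
        values = np.array([1.0, 2.0, 2.0, 3.0, 10.0])
        pcts = [percentile_of(v, values) for v in np.linspace(0, 11, 50)]
        assert pcts == sorted(pcts)
        assert all(0 <= p <= 100 for p in pcts)

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=30),
           st.floats(0, 100, allow_nan=False))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_midrank_formula_property(self, values, v):
        p = percentile_of(v, np.array(values))
        brute = 100.0 * (sum(x < v for x in values)
                         + 0.5 * sum(x == v for x in values)) / len(values)
        assert 0.0 <= p <= 100.0
        assert p == pytest.approx(brute)
        # reflection: percentile of v plus percentile of v from above is 100
        above = 100.0 * (sum(x > v for x in values)
                         + 0.5 * sum(x == v for x in values)) / len(values)
        assert p + above == pytest.approx(100.0)


class TestSampleStatus:
    def test_percentile_z_and_flags(self):
        records = _records_from_values([70, 80, 90, 100.0])
        thresholds = ThresholdConfig([Threshold(METRIC, "ge", 75)])
        status = sample_status(records[0], records, ALL, thresholds)
        entry = status.metric_status[METRIC]
        assert entry["value"] == 70.0
        assert entry["percentile"] == percentile_of(70.0, np.array([70, 80, 90, 100.0]))
        mean, sd = 85.0, statistics.stdev([70, 80, 90, 100.0])
        assert entry["z_score"] == pytest.approx((70 - mean) / sd)
        assert entry["threshold_pass"] is False
        assert status.overall_flags == [METRIC]

    def test_le_threshold_direction(self):
        records = _records_from_values([0.4, 0.9], specimen="fresh_cell")
        thresholds = ThresholdConfig([Threshold("sequencing.error_rate", "le", 1.0)])
        r = make_record({"record_id": "X", "sequencing.error_rate": 2.0,
                         METRIC: 90.0})
        status = sample_status(r, records, ALL, thresholds)
        assert status.metric_status["sequencing.error_rate"]["threshold_pass"] is False
        assert status.overall_flags == ["sequencing.error_rate"]

    def test_z_score_absent_when_sd_zero(self):
        records = _records_from_values([5.0, 5.0, 5.0])
        status = sample_status(records[0], records, ALL)
        assert "z_score" not in status.metric_status[METRIC]

    def test_empty_group_is_an_error(self):
        records = _records_from_values([1.0])
        with pytest.raises(StatsError, match="widen"):
            sample_status(records[0], records, SearchFilter(specimen_type="blood"))


class TestDatasetSummary:
    def test_counts_match_generator_tallies(self, dataset):
        s = dataset_summary(dataset.records)
        assert s.total == dataset.tallies["total"]
        assert s.by_specimen == dataset.tallies["specimen_type"]
        assert s.by_sequencing_type == dataset.tallies["sequencing_type"]
        assert s.by_year == dataset.tallies["year"]

    def test_empty_list(self):
        s = dataset_summary([])
        assert s.total == 0 and s.by_year == {} and s.by_specimen == {}

    def test_missing_facets_counted_as_unknown_and_conserve_total(self):
        records = _records_from_values([1.0, 2.0])
        records.append(make_record({"record_id": "R9"}))
        s = dataset_summary(records)
        assert s.by_specimen == {"ffpe": 2, "unknown": 1}
        assert sum(s.by_specimen.values()) == s.total == 3
        assert s.by_year == {"unknown": 3}

    def test_permutation_invariant(self, small_dataset):
        records = list(small_dataset.records)
        forward = dataset_summary(records)
        records.reverse()
        assert dataset_summary(records) == forward


class TestCompareGroups:
    def test_identical_groups_have_zero_median_difference(self):
        records = _records_from_values([60, 70, 80.0])
        cmp = compare_groups(records, METRIC, ALL, ALL)
        assert cmp.median_difference == 0.0

    def test_antisymmetric_under_group_swap(self, dataset):
        a = SearchFilter(specimen_type="fresh_cell")
        b = SearchFilter(specimen_type="ffpe")
        fwd = compare_groups(dataset.records, METRIC, a, b)
        rev = compare_groups(dataset.records, METRIC, b, a)
        assert fwd.median_difference == -rev.median_difference

    def test_order_invariance(self, small_dataset):
        a = SearchFilter(specimen_type="ffpe")
        records = list(small_dataset.records)
        fwd = compare_groups(records, METRIC, a, a)
        random.Random(3).shuffle(records)
        shuffled = compare_groups(records, METRIC, a, a)
        assert fwd.summary_a.to_dict() == shuffled.summary_a.to_dict()

    def test_empty_group_error_names_the_group(self):
        records = _records_from_values([1.0, 2.0])
        with pytest.raises(StatsError, match="group_b"):
            compare_groups(records, METRIC, ALL, SearchFilter(specimen_type="blood"))

    def test_p_value_absent_below_eight_per_group(self):
        records = (_records_from_values([1, 2, 3, 4.0], "ffpe")
                   + _records_from_values([5, 6, 7, 8.0], "fresh_cell"))
        cmp = compare_groups(records, METRIC,
                             SearchFilter(specimen_type="ffpe"),
                             SearchFilter(specimen_type="fresh_cell"),
                             rank_sum=True)
        assert cmp.rank_sum_p is None

    def test_rank_sum_p_matches_scipy_asymptotic(self):
        rng = random.Random(17)
        for _ in range(50):
            n1, n2 = rng.randint(8, 30), rng.randint(8, 30)
            a = [round(rng.gauss(50, 10), 1) for _ in range(n1)]
            b = [round(rng.gauss(55, 10), 1) for _ in range(n2)]
            expected = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=False).pvalue
            assert rank_sum_p_value(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_fresh_cell_beats_ffpe_on_coverage(self, dataset):
        cmp = compare_groups(dataset.records, "processing.mean_coverage",
                             SearchFilter(specimen_type="fresh_cell"),
                             SearchFilter(specimen_type="ffpe"))
        assert cmp.summary_a.median > cmp.summary_b.median
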