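"""Behavioral-characterization arithmetic, inter-pig tests, illness rule."""

from datetime import time

import numpy as np
import pytest
from scipy import stats as sps

from penwatch import analytics, datasets
from penwatch.analytics import (
    IllnessRule,
    daily_summary,
    descriptive_stats,
    hourly_from_counts,
    hourly_summary,
    illness_flags,
    kruskal_wallis,
    normality_test,
    one_way_anova,
    power_table,
    stratify_power,
)
from penwatch.io import DrinkingEvent


def ev(hour, minute, duration_s, fps=25.0):
    frames = int(round(duration_s * fps))
    return DrinkingEvent(0, frames, fps, 0, start_clock=time(hour, minute))


class TestHourlySummary:
    def test_single_event_binned_by_start_hour(self):
        table = hourly_summary([ev(7, 30, 10.0)])
        assert table.loc[7, "events"] == 1
        assert table.loc[7, "mean_duration_s"] == pytest.approx(10.0)
        assert table.drop(7)["events"].sum() == 0

    def test_no_events_gives_all_zero_table(self):
        table = hourly_summary([])
        assert (table["events"] == 0).all() and len(table) == 24

    def test_counts_sum_to_total_events(self):
        events = [ev(8, 5, 20), ev(8, 40, 30), ev(14, 0, 10), ev(16, 59, 5)]
        assert hourly_summary(events)["events"].sum() == 4

    def test_event_outside_lights_on_warns(self):
        with pytest.warns(UserWarning, match="lights-on"):
            hourly_summary([ev(3, 0, 10.0)])


class TestPowerTable:
    def test_hour_power_is_count_times_mean(self):
        pt = power_table(datasets.load_hourly_reference())
        assert pt.per_hour.loc[15, "power_s"] == pytest.approx(93 * 38.6)
        assert pt.per_hour.loc[15, "power_s"] == pytest.approx(3589.8)

    def test_reference_totals(self):
        pt = power_table(datasets.load_hourly_reference())
        assert pt.total_events == 612
        assert pt.total_power_s == pytest.approx(25359.9, abs=0.05)
        assert pt.overall_mean_s == pytest.approx(41.44, abs=0.005)

    def test_power_consistent_with_total_duration(self):
        hourly = hourly_from_counts({8: 3, 9: 2}, {8: 10.0, 9: 20.0})
        pt = power_table(hourly)
        assert pt.total_power_s == pytest.approx(hourly["total_duration_s"].sum())

    def test_pct_sums_to_hundred(self):
        pt = power_table(datasets.load_hourly_reference())
        assert pt.per_hour["pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_single_hour_gets_full_share(self):
        pt = power_table(hourly_from_counts({10: 2}, {10: 10.0}))
        assert pt.per_hour.loc[10, "power_s"] == pytest.approx(20.0)
        assert pt.per_hour.loc[10, "pct"] == pytest.approx(100.0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            power_table(hourly_summary([]))


class TestStratifiedPower:
    def test_reference_feeding_and_non_feeding_means(self):
        strat = stratify_power(power_table(datasets.load_hourly_reference()))
        assert strat.feeding_mean_pct == pytest.approx(10.90, abs=0.005)
        assert strat.non_feeding_mean_pct == pytest.approx(5.69, abs=0.005)
        assert strat.all_hours_mean_pct == pytest.approx(100 / 13, abs=1e-9)

    def test_uniform_hours_give_equal_strata_at_hundred_percent(self):
        hourly = hourly_from_counts({h: 2 for h in range(6, 19)},
                                    {h: 10.0 for h in range(6, 19)})
        strat = stratify_power(power_table(hourly))
        assert strat.feeding_mean_pct == pytest.approx(strat.non_feeding_mean_pct)
        assert strat.feeding_relative_pct == pytest.approx(100.0)
        assert strat.non_feeding_relative_pct == pytest.approx(100.0)

    def test_overlapping_hour_sets_rejected(self):
        pt = power_table(datasets.load_hourly_reference())
        with pytest.raises(ValueError):
            stratify_power(pt, feeding_hours={8, 9}, other_hours={9, 10})


class TestDailySummary:
    def _pig2_day1(self):
        # 15 events totalling 240.5 s, all in one morning
        durations = [16.0] * 14 + [240.5 - 16.0 * 14]
        return [ev(8, min(5 + i, 59), d) for i, d in enumerate(durations)]

    def test_counts_and_totals(self):
        ds = daily_summary(self._pig2_day1(), "pig2", 1)
        assert ds.events == 15
        assert ds.total_s == pytest.approx(240.5, abs=0.1)
        assert ds.total_min == pytest.approx(4.0, abs=0.05)
        assert ds.mean_s == pytest.approx(16.0, abs=0.05)

    def test_single_event_degenerate_stats(self):
        ds = daily_summary([ev(9, 15, 30.0)])
        assert (ds.events, ds.mean_s, ds.std_s) == (1, 30.0, 0.0)
        assert ds.first_hour == ds.last_hour == pytest.approx(9.25)

    def test_empty_day_is_zero_row(self):
        ds = daily_summary([], "pig", 3)
        assert ds.events == 0 and ds.first_hour is None

    def test_reference_daily_averages(self):
        avg1 = np.mean(datasets.DAILY_EVENT_COUNTS["pig1"])
        avg2 = np.mean(datasets.DAILY_TOTAL_S["pig2"])
        assert avg1 == pytest.approx(47.7, abs=0.05)
        assert avg2 == pytest.approx(212.6, abs=0.05)


class TestDescriptiveStats:
    def test_reference_per_pig_statistics(self):
        table = descriptive_stats(datasets.DAILY_EVENT_COUNTS)
        assert table.loc["pig3", "std"] == pytest.approx(22.0, abs=0.05)
        assert table.loc["pig2", "median"] == pytest.approx(14.5)
        assert table.loc["pig3", "median"] == pytest.approx(26.0)
        assert table.loc["pig1", "std"] == pytest.approx(12.7, abs=0.05)
        assert table.loc["pig2", "std"] == pytest.approx(3.1, abs=0.05)

    def test_population_denominator(self):
        counts = {"p": [1.0, 2.0, 3.0, 4.0]}
        assert descriptive_stats(counts).loc["p", "std"] == pytest.approx(
            np.std([1, 2, 3, 4], ddof=0))

    def test_constant_counts(self):
        row = descriptive_stats({"p": [5, 5, 5]}).loc["p"]
        assert row["std"] == 0 and row["min"] == row["max"] == 5


def kruskal_oracle(groups):
    """Independent midrank computation of H with tie correction."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    n = flat.size
    ranks = sps.rankdata(flat)
    idx, h = 0, 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / tie


class TestKruskalWallis:
    def test_reference_daily_counts(self):
        h, p = kruskal_wallis(list(datasets.DAILY_EVENT_COUNTS.values()))
        assert h == pytest.approx(11.80, abs=0.005)
        assert p < 0.01

    def test_hand_ranked_two_groups(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_identical_groups_score_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_midrank_oracle_small_n(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            sizes = rng.integers(1, 5, size=rng.integers(2, 4))
            if sizes.sum() > 10:
                continue
            groups = [rng.integers(0, 5, size=s).astype(float).tolist()
                      for s in sizes]
            flat = np.concatenate(groups)
            if np.ptp(flat) == 0:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-10)


class TestOneWayAnova:
    def test_reference_daily_counts(self):
        f, p = one_way_anova(list(datasets.DAILY_EVENT_COUNTS.values()))
        assert f == pytest.approx(6.97, abs=0.005)
        assert p == pytest.approx(0.007, abs=0.0005)

    def test_hand_computed_two_groups(self):
        f, _ = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)

    def test_two_identical_groups_give_zero(self):
        f, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        f, pf = one_way_anova([a, b])
        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_zero_within_variance_flagged(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 1], [2, 2]])


class TestNormality:
    def test_pig3_departs_from_normality(self):
        assert normality_test(datasets.DAILY_EVENT_COUNTS["pig3"]) < 0.01

    def test_uniform_grid_not_rejected(self):
        assert normality_test(list(range(1, 21))) > 0.05

    @pytest.mark.parametrize("sample", [[1, 2], list(range(60)), [5, 5, 5, 5]])
    def test_unsupported_samples_rejected(self, sample):
        with pytest.raises(ValueError):
            normality_test(sample)


class TestIllnessFlags:
    def test_absolute_mode_flags_large_deviation(self):
        # baseline median 49.5, population std ~12.7 -> 2 sigma band ~25.4
        base = datasets.DAILY_EVENT_COUNTS["pig1"]
        counts = base + [80]
        flags = illness_flags(counts, baseline_days=range(6), mode="absolute")
        assert flags[-1]
        assert not flags[:6].any()

    def test_count_at_baseline_median_never_flagged(self):
        counts = [20, 22, 18, 20]
        for mode in ("absolute", "relative"):
            assert not illness_flags(counts, [0, 1, 2], mode=mode)[3]

    def test_relative_mode_hand_case(self):
        # median 20, r = 0.4 -> band is 8; a 27-count day stays inside
        counts = [20, 20, 20, 27, 29]
        flags = illness_flags(counts, [0, 1, 2], mode="relative")
        assert not flags[3]
        assert flags[4]  # |29 - 20| = 9 > 8

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError):
            illness_flags([1, 2, 3, 4], [0, 1])

    def test_rule_parameter_validation(self):
        with pytest.raises(ValueError):
            IllnessRule(k=0)
        with pytest.raises(ValueError):
            IllnessRule(r=1.0)

    def test_false_alarm_rate_bounded_on_stationary_baseline(self):
        # Chebyshev at k = 2: per-day false-flag rate must stay under ~10 %
        rng = np.random.default_rng(5)
        flagged = total = 0
        for _ in range(300):
            counts = rng.poisson(40, size=10).astype(float)
            flags = illness_flags(counts, range(10), mode="absolute")
            flagged += flags.sum()
            total += flags.size
        assert flagged / total < 0.10
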