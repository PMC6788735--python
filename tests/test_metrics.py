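import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cgmkit import (
    MetricsConfig,
    auc_trapezoid,
    basic_stats,
    daynight_stats,
    estimated_a1c,
    excursions,
    gmi,
    j_index,
    percent_cgm_wear,
    summarize,
    summary_columns,
    time_in_band,
    time_metrics,
)

from .conftest import build_trace
from .oracles import excursion_count_oracle


class TestFormulae:
    @pytest.mark.parametrize("mean", [54.0, 70.0, 100.0, 126.87, 154.0, 200.0])
    def test_estimated_a1c(self, mean):
        assert estimated_a1c(mean) == pytest.approx((46.7 + mean) / 28.7, rel=1e-14)

    def test_a1c_linearity(self):
        # adding 28.7 mg/dL to the mean raises estimated A1c by exactly 1%
        assert estimated_a1c(128.7) - estimated_a1c(100.0) == pytest.approx(1.0)

    def test_gmi_value_and_slope(self):
        assert gmi(100.0) == pytest.approx(5.702, rel=1e-12)
        assert gmi(200.0) - gmi(100.0) == pytest.approx(2.392, rel=1e-12)

    def test_j_index(self):
        assert j_index(100.0, 0.0) == pytest.approx(0.324 * 100**2, rel=1e-14)
        assert j_index(100.0, 100.0) == pytest.approx(4 * j_index(50.0, 50.0))

    @pytest.mark.parametrize("fn", [estimated_a1c, gmi])
    def test_nonpositive_mean_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            j_index(100.0, -1.0)


class TestWearAndStats:
    def test_gapless_wear_is_100(self):
        assert percent_cgm_wear(build_trace(np.full(288, 100.0))) == 100.0

    def test_one_missing_of_289(self):
        # 24-h span at 5 min = 289 potential readings
        trace = build_trace(np.full(289, 100.0)).take(
            np.arange(289) != 144
        )
        assert percent_cgm_wear(trace) == pytest.approx(100 * 288 / 289)

    def test_half_deleted_is_half_wear(self, rng):
        n = 2 * 288
        keep = np.zeros(n, dtype=bool)
        keep[rng.choice(n, n // 2, replace=False)] = True
        keep[0] = keep[-1] = True
        trace = build_trace(rng.uniform(80, 200, n)).take(keep)
        expected = 100 * keep.sum() / (math.floor(trace.span_minutes / 5) + 1)
        assert percent_cgm_wear(trace) == pytest.approx(expected)
        assert percent_cgm_wear(trace) == pytest.approx(50, abs=2)

    def test_constant_trace(self):
        stats = basic_stats(build_trace(np.full(10, 100.0)))
        assert stats["average_sensor"] == 100
        assert stats["standard_deviation"] == 0 and stats["cv"] == 0

    def test_two_samples_hand_arithmetic(self):
        stats = basic_stats(build_trace([90.0, 110.0]))
        assert stats["average_sensor"] == 100
        assert stats["standard_deviation"] == pytest.approx(math.sqrt(200), rel=1e-12)

    @given(st.lists(st.floats(41, 400), min_size=2, max_size=40))
    def test_order_statistics_bracket(self, values):
        s = basic_stats(build_trace(values))
        assert (s["min_sensor"] <= s["q1_sensor"] <= s["median_sensor"]
                <= s["q3_sensor"] <= s["max_sensor"])
        assert s["min_sensor"] <= s["average_sensor"] <= s["max_sensor"]
        assert s["cv"] * s["average_sensor"] == pytest.approx(
            s["standard_deviation"], rel=1e-12, abs=1e-12)


class TestTimeMetrics:
    def test_constant_in_range_day(self):
        tm = time_metrics(build_trace(np.full(288, 100.0)))
        assert tm["min_spent_70_180"] == 1440
        assert tm["percent_time_70_180"] == 100
        assert tm["min_spent_over_180"] == 0 and tm["min_spent_under_70"] == 0

    def test_half_high(self):
        values = np.where(np.arange(288) % 2 == 0, 250.0, 100.0)
        tm = time_metrics(build_trace(values))
        assert tm["percent_time_over_200"] == 50

    def test_boundary_sample_counts_in_both_bands(self):
        """A reading exactly at 180 is both 'at or above 180' and inside
        the inclusive 70-180 range, per the printed definitions."""
        tm = time_metrics(build_trace([180.0, 180.0, 180.0]))
        assert tm["percent_time_over_180"] == 100
        assert tm["percent_time_70_180"] == 100

    @given(st.lists(st.floats(41, 400), min_size=2, max_size=60))
    def test_strict_bands_partition_wear_time(self, values):
        trace = build_trace(values)
        total = len(values) * 5.0
        over = time_in_band(trace, lower=180, interval=5, lower_inclusive=False)
        under = time_in_band(trace, upper=70, interval=5, upper_inclusive=False)
        mid = time_in_band(trace, lower=70, upper=180, interval=5)
        assert over + under + mid == pytest.approx(total)


class TestExcursions:
    def test_constant_trace_has_none(self):
        ex = excursions(build_trace(np.full(288, 100.0)))
        assert all(v == 0 for k, v in ex.items() if k.startswith("excursions"))

    @pytest.mark.parametrize("n_high,expected", [(7, 1), (6, 0)])
    def test_35_minute_gate_boundary(self, n_high, expected):
        """7 consecutive 5-min readings >= 180 last 35 min and count; 6
        last 30 min and do not."""
        values = [100.0] * 5 + [190.0] * n_high + [100.0] * 5
        ex = excursions(build_trace(values))
        assert ex["excursions_over_180"] == expected

    def test_under_gate_10_minutes(self):
        values = [100.0] * 4 + [50.0] * 2 + [100.0] * 4  # 10 min below 54
        ex = excursions(build_trace(values))
        assert ex["excursions_under_54"] == 1
        values = [100.0] * 4 + [50.0] + [100.0] * 4  # only 5 min
        assert excursions(build_trace(values))["excursions_under_54"] == 0

    def test_per_day_average(self):
        values = ([100.0] * 20 + [200.0] * 7 + [100.0] * 20) * 6
        trace = build_trace(values)
        ex = excursions(trace)
        days = len(values) * 5 / 1440
        assert ex["avg_excur_over_180_per_day"] == pytest.approx(6 / days)

    @given(st.lists(st.floats(41, 400), min_size=4, max_size=60))
    def test_matches_run_length_oracle(self, values):
        ex = excursions(build_trace(values))
        for t in (120, 140, 180, 200, 250):
            assert ex[f"excursions_over_{t}"] == excursion_count_oracle(
                values, 5, t, 35, "over")
        for u in (54, 60, 70):
            assert ex[f"excursions_under_{u}"] == excursion_count_oracle(
                values, 5, u, 10, "under")


class TestAUC:
    def test_constant_equals_value_times_span(self):
        trace = build_trace(np.full(288, 137.0))
        assert auc_trapezoid(trace)["auc"] == pytest.approx(137.0 * trace.span_minutes)

    def test_two_sample_hand_value(self):
        trace = build_trace([100.0, 200.0], times_min=[0, 10])
        assert auc_trapezoid(trace)["auc"] == pytest.approx(1500.0)

    def test_day_night_partition(self, rng):
        trace = build_trace(rng.uniform(70, 250, 2 * 288))
        aucs = auc_trapezoid(trace)
        assert aucs["daytime_auc"] + aucs["nighttime_auc"] == pytest.approx(aucs["auc"])


class TestDayNight:
    @staticmethod
    def _day_night_trace():
        clock = (np.arange(288) * 5) % 1440
        values = np.where((clock >= 360) & (clock < 1320), 100.0, 80.0)
        return build_trace(values)

    def test_window_means(self):
        dn = daynight_stats(self._day_night_trace())
        assert dn["daytime_mean"] == 100 and dn["nighttime_mean"] == 80

    def test_custom_window_reassigns_samples(self):
        """With daystart=8 the 06:00-08:00 block moves to nighttime."""
        dn = daynight_stats(self._day_night_trace(), MetricsConfig(daystart=8, dayend=23))
        assert dn["nighttime_max"] == 100  # 6:00-8:00 block (value 100) now night
        assert dn["daytime_min"] == 80  # 22:00-23:00 block (value 80) now day

    def test_degenerate_full_day_window_warns(self):
        with pytest.warns(UserWarning, match="no nighttime samples"):
            dn = daynight_stats(self._day_night_trace(), MetricsConfig(daystart=0, dayend=24))
        assert math.isnan(dn["nighttime_mean"])


class TestSummarize:
    def test_row_has_all_columns_in_order(self, rng):
        trace = build_trace(rng.uniform(60, 250, 3 * 288))
        row = summarize(trace)
        assert list(row) == summary_columns()
        assert row["subject_id"] == "T001"

    def test_custom_config_row(self, rng):
        trace = build_trace(rng.uniform(60, 250, 3 * 288))
        cfg = MetricsConfig(daystart=8, dayend=23, magedef="2sd")
        row = summarize(trace, cfg)
        assert set(summary_columns(cfg)) == set(row)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            summarize(build_trace([100.0]))

    def test_shift_invariance_of_difference_metrics(self, rng):
        values = rng.uniform(80, 200, 2 * 288)
        row0 = summarize(build_trace(values))
        row1 = summarize(build_trace(values + 50.0))
        assert row1["average_sensor"] == pytest.approx(row0["average_sensor"] + 50)
        for key in ("standard_deviation", "r_mage", "conga", "modd"):
            assert row1[key] == pytest.approx(row0[key], rel=1e-9)
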