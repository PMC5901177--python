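"""Monthly microclimate summaries, thawing degree days, PAR shading."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import tundraphys as tp


def hourly_frame(values_by_treatment, start="2016-07-01", days=3):
    idx = pd.date_range(start, periods=24 * days, freq="h")
    rows = []
    for trt, vals in values_by_treatment.items():
        vals = np.broadcast_to(np.asarray(vals, dtype=float), (len(idx),))
        rows.append(pd.DataFrame({
            "timestamp": idx, "value": vals, "garden": "TL",
            "treatment": trt, "sensor": f"{trt}-1"}))
    return pd.concat(rows, ignore_index=True)


class TestMonthlyStats:
    def test_constant_series_both_treatments(self):
        df = hourly_frame({"ambient": 10.0, "OTC": 10.0})
        (s,) = tp.monthly_stats(df)
        assert s.tmean["ambient"] == 10.0
        assert s.tmean["OTC"] == 10.0
        assert s.tmean_se["ambient"] == pytest.approx(0.0)
        assert s.difference == 0.0
        assert s.tmin["ambient"] <= s.tmean["ambient"] <= s.tmax["ambient"]

    def test_hand_computed_three_day_series(self):
        # day d: ambient = d, d+2 alternating -> daily means 1..3 etc.
        idx = pd.date_range("2016-07-01", periods=72, freq="h")
        amb = np.repeat([1.0, 2.0, 3.0], 24)
        otc = amb + 1.5
        df = pd.concat([
            pd.DataFrame({"timestamp": idx, "value": amb, "garden": "TL",
                          "treatment": "ambient", "sensor": "a1"}),
            pd.DataFrame({"timestamp": idx, "value": otc, "garden": "TL",
                          "treatment": "OTC", "sensor": "o1"}),
        ], ignore_index=True)
        (s,) = tp.monthly_stats(df)
        assert s.tmean["ambient"] == pytest.approx(2.0)
        # SE over daily means {1,2,3}: sd=1, n=3
        assert s.tmean_se["ambient"] == pytest.approx(1.0 / np.sqrt(3))
        assert s.difference == pytest.approx(1.5)

    def test_difference_equals_reported_means(self):
        rng = np.random.default_rng(3)
        df = hourly_frame({"ambient": rng.normal(12.1, 2, 72),
                           "OTC": rng.normal(14.0, 2, 72)})
        (s,) = tp.monthly_stats(df)
        assert s.difference == s.tmean["OTC"] - s.tmean["ambient"]

    def test_single_treatment_month_has_no_difference(self):
        df = hourly_frame({"ambient": 9.0})
        (s,) = tp.monthly_stats(df)
        assert s.difference is None

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        df = hourly_frame({"ambient": rng.normal(10, 3, 72),
                           "OTC": rng.normal(11, 3, 72)})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        (a,), (b,) = tp.monthly_stats(df), tp.monthly_stats(shuffled)
        assert a.tmean == b.tmean
        assert a.difference == pytest.approx(b.difference)

    def test_sensors_averaged_before_daily_means(self):
        idx = pd.date_range("2016-07-01", periods=24, freq="h")
        df = pd.concat([
            pd.DataFrame({"timestamp": idx, "value": 8.0, "garden": "TL",
                          "treatment": "ambient", "sensor": "a1"}),
            pd.DataFrame({"timestamp": idx, "value": 12.0, "garden": "TL",
                          "treatment": "ambient", "sensor": "a2"}),
        ], ignore_index=True)
        (s,) = tp.monthly_stats(df)
        assert s.tmean["ambient"] == pytest.approx(10.0)


class TestThawingDegreeDays:
    def frame(self, dates, vals):
        return pd.DataFrame({"date": pd.to_datetime(dates), "tair": vals})

    def test_all_below_zero_gives_zero(self):
        df = self.frame(["2016-06-01", "2016-06-02"], [-3.0, -0.1])
        assert tp.thawing_degree_days(df) == 0.0

    def test_hand_sum_positive_days_only(self):
        df = self.frame(["2016-06-01", "2016-06-02", "2016-06-03"],
                        [5.0, -2.0, 10.0])
        assert tp.thawing_degree_days(df) == 15.0

    def test_window_excludes_april(self):
        df = self.frame(["2016-04-20", "2016-05-02"], [7.0, 3.0])
        assert tp.thawing_degree_days(df) == 3.0

    def test_additive_over_disjoint_ranges_and_monotone(self):
        rng = np.random.default_rng(12)
        dates = pd.date_range("2016-05-01", "2016-09-30", freq="D")
        vals = rng.normal(4, 5, len(dates))
        df = pd.DataFrame({"date": dates, "tair": vals})
        june = df[df["date"].dt.month == 6]
        july = df[df["date"].dt.month == 7]
        both = pd.concat([june, july])
        assert tp.thawing_degree_days(both) == pytest.approx(
            tp.thawing_degree_days(june) + tp.thawing_degree_days(july))
        # growing the window never decreases TDD
        assert tp.thawing_degree_days(df) >= tp.thawing_degree_days(both)

    def test_empty_input(self):
        assert tp.thawing_degree_days(pd.DataFrame(
            {"date": [], "tair": []})) == 0.0


class TestParPercentDifference:
    def series(self, vals, start="2016-06-01"):
        idx = pd.date_range(start, periods=len(vals), freq="h")
        return pd.Series(vals, index=idx)

    def test_identical_series_zero_percent(self):
        a = self.series([800.0] * 48)
        out = tp.par_percent_difference(a, a.copy())
        assert out.iloc[0] == pytest.approx(0.0)

    def test_constant_attenuation_hand_value(self):
        a = self.series([1000.0] * 48)
        o = self.series([750.0] * 48)
        out = tp.par_percent_difference(a, o)
        assert out.iloc[0] == pytest.approx(25.0)

    def test_dim_hours_are_ignored(self):
        # half the hours are below threshold in both series
        a = self.series([1000.0, 100.0] * 24)
        o = self.series([750.0, 90.0] * 24)
        out = tp.par_percent_difference(a, o)
        assert out.iloc[0] == pytest.approx(25.0)

    def test_all_dim_month_is_missing(self):
        a = self.series([100.0] * 48)
        o = self.series([90.0] * 48)
        out = tp.par_percent_difference(a, o)
        assert np.isnan(out.iloc[0])


class TestGeneratedMetRoundTrip:
    def test_noise_free_offsets_recovered_exactly(self):
        cfg = replace(tp.default_garden_configs()["TL"], noise_sd=0.0)
        m = tp.generate_met_series(cfg, seed=3)
        summaries = {str(s.month): s for s in tp.monthly_stats(m["tair"])}
        assert summaries["2016-06"].difference == pytest.approx(1.8)
        assert summaries["2016-07"].difference == pytest.approx(1.9)
        assert summaries["2016-08"].difference == pytest.approx(1.0)

    def test_noise_free_par_attenuation_recovered(self):
        cfg = replace(tp.default_garden_configs()["TL"], noise_sd=0.0)
        m = tp.generate_met_series(cfg, seed=3)
        wide = (m["par"].groupby(["treatment", "timestamp"])["value"]
                .mean().unstack("treatment"))
        out = tp.par_percent_difference(wide["ambient"], wide["OTC"])
        assert out[pd.Period("2016-06")] == pytest.approx(25.0)
        assert out[pd.Period("2016-07")] == pytest.approx(16.0)
        assert out[pd.Period("2016-08")] == pytest.approx(9.0)

    def test_same_seed_identical_series(self):
        cfg = tp.default_garden_configs()["SAG"]
        a = tp.generate_met_series(cfg, seed=9)["tair"]
        b = tp.generate_met_series(cfg, seed=9)["tair"]
        pd.testing.assert_frame_equal(a, b)
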