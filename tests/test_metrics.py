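"""Daily/condition metrics: forced arithmetic, invariants, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from bottlechoice.io import DrinkLog, MouseRecord, Schedule, ScheduleDay, standard_schedule
from bottlechoice.metrics import (
    MINUTES_PER_DAY,
    condition_summaries,
    daily_metrics,
    habituation_side_preference,
    intake_deltas,
    titration_response,
)
from bottlechoice.simulate import archetype_presets, simulate_mouse

from conftest import make_daily


def _log_from_daily_volumes(left_per_day, right_per_day, mouse_id="m"):
    """A log drinking each day's volume in one mid-day step."""
    minutes, vl, vr = [0], [0.0], [0.0]
    cl = cr = 0.0
    for d, (l, r) in enumerate(zip(left_per_day, right_per_day), start=1):
        cl += l
        cr += r
        minutes.append((d - 1) * MINUTES_PER_DAY + 720)
        vl.append(cl)
        vr.append(cr)
    return DrinkLog(mouse_id, minutes, vl, vr)


class TestDailyMetrics:
    def test_intake_arithmetic(self):
        # 25 g mouse drinking 2.5 ml of 100 µg/ml -> 10 mg/kg/day
        sched = Schedule([ScheduleDay(1, 100.0, "left")])
        log = _log_from_daily_volumes([2.5], [1.0])
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        assert daily["intake_mg_per_kg"].iloc[0] == pytest.approx(10.0)

    def test_percent_consumption(self):
        sched = Schedule([ScheduleDay(1, 100.0, "left")])
        log = _log_from_daily_volumes([2.0], [2.0])
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        assert daily["pct_drug"].iloc[0] == pytest.approx(50.0)

    def test_habituation_day_zero_intake_with_virtual_side(self):
        sched = Schedule([ScheduleDay(1, 0.0, "none"), ScheduleDay(2, 100.0, "left")])
        log = _log_from_daily_volumes([1.0, 2.0], [3.0, 2.0])
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        hab = daily.iloc[0]
        assert hab["intake_mg_per_kg"] == 0.0
        assert hab["pct_drug"] == pytest.approx(25.0)  # left virtual side: 1/(1+3)
        flagged = daily_metrics(
            log, sched, MouseRecord("m", {1: 25.0}), habituation_virtual_sides=False
        )
        assert np.isnan(flagged["pct_drug"].iloc[0])

    def test_zero_total_volume_gives_nan_pct_not_zero(self):
        sched = Schedule([ScheduleDay(1, 100.0, "left")])
        log = DrinkLog("m", [0, 100], [0.0, 0.0], [0.0, 0.0])
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        assert np.isnan(daily["pct_drug"].iloc[0])
        assert daily["intake_mg_per_kg"].iloc[0] == 0.0

    def test_uncovered_day_flagged_missing_not_zero(self):
        sched = Schedule([ScheduleDay(1, 100.0, "left"), ScheduleDay(2, 100.0, "left")])
        log = DrinkLog("m", [0, 100], [0.0, 1.0], [0.0, 0.5])  # day 2 has no samples
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        assert not daily["missing"].iloc[0]
        assert daily["missing"].iloc[1]
        assert np.isnan(daily["intake_mg_per_kg"].iloc[1])

    def test_conservation_drug_plus_vehicle_is_total(self):
        sched = standard_schedule()
        log, rec, _ = simulate_mouse(
            archetype_presets()["tracker"], sched, np.random.default_rng(3)
        )
        daily = daily_metrics(log, sched, rec)
        ok = daily[~daily["missing"] & daily["vol_drug_ml"].notna()]
        np.testing.assert_allclose(
            ok["vol_drug_ml"] + ok["vol_vehicle_ml"], ok["vol_total_ml"], atol=1e-9
        )

    def test_brute_force_per_minute_oracle(self):
        # independent path: assign each minute's increment to its calendar day
        rng = np.random.default_rng(11)
        n_days = 3
        inc_l = rng.gamma(0.5, 0.01, size=n_days * MINUTES_PER_DAY)
        inc_r = rng.gamma(0.5, 0.01, size=n_days * MINUTES_PER_DAY)
        log = DrinkLog("m", np.arange(n_days * MINUTES_PER_DAY),
                       np.cumsum(inc_l), np.cumsum(inc_r))
        sched = Schedule([ScheduleDay(d, 100.0, "left") for d in range(1, n_days + 1)])
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        for d in range(1, n_days + 1):
            sl = slice((d - 1) * MINUTES_PER_DAY, d * MINUTES_PER_DAY)
            assert daily["vol_left_ml"].iloc[d - 1] == pytest.approx(inc_l[sl].sum())
            assert daily["vol_right_ml"].iloc[d - 1] == pytest.approx(inc_r[sl].sum())
            expect_intake = inc_l[sl].sum() * 100.0 / 25.0
            assert daily["intake_mg_per_kg"].iloc[d - 1] == pytest.approx(expect_intake)

    def test_intake_linear_in_concentration_and_inverse_in_weight(self):
        log = _log_from_daily_volumes([2.0], [2.0])
        for conc, weight, expected in [(100.0, 25.0, 8.0), (200.0, 25.0, 16.0),
                                       (100.0, 50.0, 4.0)]:
            sched = Schedule([ScheduleDay(1, conc, "left")])
            daily = daily_metrics(log, sched, MouseRecord("m", {1: weight}))
            assert daily["intake_mg_per_kg"].iloc[0] == pytest.approx(expected)


class TestRelabelSymmetry:
    def test_side_swap_preserves_metrics_and_swaps_side_components(self):
        sched = standard_schedule()
        log, rec, _ = simulate_mouse(
            archetype_presets()["side_biased"], sched, np.random.default_rng(5)
        )
        daily = daily_metrics(log, sched, rec)
        daily_sw = daily_metrics(log.swapped(), sched.swapped(), rec)
        np.testing.assert_allclose(
            daily["intake_mg_per_kg"], daily_sw["intake_mg_per_kg"], atol=1e-9
        )
        np.testing.assert_allclose(daily["pct_drug"], daily_sw["pct_drug"], atol=1e-9)
        s, s_sw = condition_summaries(daily), condition_summaries(daily_sw)
        np.testing.assert_allclose(s["mean_pct"], s_sw["mean_pct"], atol=1e-9)
        np.testing.assert_allclose(s["pct_c1"], s_sw["pct_c2"], atol=1e-9)
        np.testing.assert_allclose(s["pct_c2"], s_sw["pct_c1"], atol=1e-9)
        d, d_sw = intake_deltas(daily), intake_deltas(daily_sw)
        np.testing.assert_allclose(d.deltas, d_sw.deltas, atol=1e-9)


class TestConditionSummaries:
    def test_condition_mean(self):
        daily = make_daily([8, 10, 12, 10], [100] * 4)
        s = condition_summaries(daily)
        assert s["mean_intake"].iloc[0] == pytest.approx(10.0)

    def test_pct_by_side_definition(self):
        daily = make_daily([5] * 4, [100] * 4, pcts=[90, 92, 10, 8])
        daily["pct_side"] = ["left", "left", "right", "right"]
        s = condition_summaries(daily)
        assert s["pct_c1"].iloc[0] == pytest.approx(91.0)
        assert s["pct_c2"].iloc[0] == pytest.approx(9.0)
        # mean over days lies within the daily range
        assert 8.0 <= s["mean_pct"].iloc[0] <= 92.0

    def test_missing_days_reduce_coverage_not_mean(self):
        daily = make_daily([8, 10, 12, 10], [100] * 4)
        daily.loc[daily.index[2:], "missing"] = True
        daily.loc[daily.index[2:], "intake_mg_per_kg"] = np.nan
        s = condition_summaries(daily)
        assert s["n_days_used"].iloc[0] == 2
        assert s["mean_intake"].iloc[0] == pytest.approx(9.0)

    def test_habituation_preference(self):
        daily = make_daily([1], [10], hab_days=4, hab_left_frac=0.75)
        assert habituation_side_preference(daily) == pytest.approx(75.0)


class TestIntakeDeltas:
    def test_simple_series(self):
        daily = make_daily([2, 4, 3], [10, 10, 10])
        d = intake_deltas(daily)
        np.testing.assert_allclose(d.deltas, [2.0, -1.0])
        assert d.min_delta == -1.0 and d.max_delta == 2.0

    def test_monotone_series_has_positive_min_delta(self):
        daily = make_daily([1, 2, 3, 4], [10, 10, 50, 50])
        assert intake_deltas(daily).min_delta > 0

    def test_constant_low_series_has_near_zero_extremes(self):
        daily = make_daily([0.5, 0.5, 0.5], [10, 10, 10])
        d = intake_deltas(daily)
        assert abs(d.min_delta) < 1e-12 and abs(d.max_delta) < 1e-12

    def test_habituation_excluded_and_too_few_days_error(self):
        daily = make_daily([3.0], [10], hab_days=4)
        with pytest.raises(ValueError, match="2 drug days"):
            intake_deltas(daily)

    def test_transition_deltas_labeled(self):
        daily = make_daily([1, 2, 5, 6], [10, 10, 50, 50])
        d = intake_deltas(daily)
        # day2->day3 crosses the step; day3->day4 is within one day of it
        assert list(d.after_increase) == [True, True, True]
        daily5 = make_daily([1, 2, 3, 5, 6], [10, 10, 10, 50, 50])
        d5 = intake_deltas(daily5)
        assert list(d5.after_increase) == [True, False, True, True]


class TestTitration:
    def test_perfect_titrator_flagged_rapid(self):
        # volume halves when concentration doubles -> intake unchanged
        sched = Schedule(
            [ScheduleDay(d, 50.0, "left") for d in (1, 2)]
            + [ScheduleDay(d, 100.0, "left") for d in (3, 4)]
        )
        log = _log_from_daily_volumes([2.0, 2.0, 1.0, 1.0], [1.0] * 4)
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        t = titration_response(daily, sched)
        assert len(t) == 1 and bool(t["rapid"].iloc[0])

    def test_constant_volume_drinker_not_rapid(self):
        sched = Schedule(
            [ScheduleDay(d, 50.0, "left") for d in (1, 2)]
            + [ScheduleDay(d, 100.0, "left") for d in (3, 4)]
        )
        log = _log_from_daily_volumes([2.0] * 4, [1.0] * 4)
        daily = daily_metrics(log, sched, MouseRecord("m", {1: 25.0}))
        t = titration_response(daily, sched)
        assert not bool(t["rapid"].iloc[0])  # intake doubled across the step

    def test_titrating_archetype_majority_rapid_above_knee(self):
        # plateau titrators re-establish their dose within a day of the
        # 100->200 step (above their knee concentration)
        sched = standard_schedule()
        rng = np.random.default_rng(21)
        rapid = []
        for _ in range(12):
            log, rec, _ = simulate_mouse(archetype_presets()["plateau"], sched, rng)
            daily = daily_metrics(log, sched, rec)
            t = titration_response(daily, sched)
            row = t[(t["conc_from"] == 100.0) & (t["conc_to"] == 200.0)]
            rapid.append(bool(row["rapid"].iloc[0]))
        assert sum(rapid) > len(rapid) / 2
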