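"""Epoch classification, non-wear/sleep detection, daily summaries, weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timeuse24.accelerometry import (AccelConfig, classify_epoch, day_type_of,
                                     detect_non_wear, detect_sleep_period,
                                     filter_valid_participants, is_valid_day,
                                     process_day, summarize_day,
                                     weighted_time_use, DailySummary)

CFG = AccelConfig()


def quiet_night_day(onset=1380, spt=480, waking_level=60.0):
    """1440-epoch day: quiescent circular sleep window, steady waking signal."""
    m = np.full(1440, waking_level)
    idx = (onset + np.arange(spt)) % 1440
    m[idx] = 20.0
    return m


class TestClassifyEpoch:
    @pytest.mark.parametrize("magnitude,expected", [
        (0.0, 0),        # below the lowest cutpoint: sedentary
        (117.9, 0),
        (118.0, 1),      # cutpoints inclusive on the left
        (402.9, 1),
        (403.0, 2),
        (500.0, 2),      # bracketed by 403 and 1131: moderate
        (1130.9, 2),
        (1131.0, 3),
        (5000.0, 3),
    ])
    def test_boundaries(self, magnitude, expected):
        assert classify_epoch(magnitude) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=5000.0))
    def test_matches_counting_oracle(self, m):
        # class index = number of cutpoints at or below the magnitude
        oracle = sum(1 for c in CFG.cutpoints if c <= m)
        assert classify_epoch(m) == oracle

    def test_monotone_in_magnitude(self):
        mags = np.linspace(0.0, 2000.0, 4001)
        classes = classify_epoch(mags)
        assert np.all(np.diff(classes) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(-1.0)


class TestNonWear:
    def test_planted_90min_block_flagged(self):
        m = np.full(1440, 80.0)
        m[600:690] = 1.0
        mask = detect_non_wear(m, CFG)
        assert mask[600:690].all()
        assert mask.sum() == 90

    def test_fully_active_day_empty(self):
        m = np.full(1440, 200.0)
        assert detect_non_wear(m, CFG).sum() == 0

    def test_short_block_not_flagged(self):
        m = np.full(1440, 80.0)
        m[600:645] = 0.0  # 45 min, below the 60-min minimum
        assert detect_non_wear(m, CFG).sum() == 0

    def test_flat_block_survives_borderline_flank(self):
        # one epoch below the floor but off-level should not erase the block
        m = np.full(1440, 80.0)
        m[599] = 8.0
        m[600:690] = 1.0
        mask = detect_non_wear(m, CFG)
        assert mask[600:690].sum() >= 60

    def test_drifting_low_signal_not_flagged(self):
        # below the floor but with too much range: wear, not non-wear
        m = np.full(1440, 80.0)
        m[600:700] = np.linspace(0.0, 9.9, 100)
        assert detect_non_wear(m, CFG).sum() == 0

    def test_diary_extension(self):
        m = np.full(1440, 80.0)
        diary = np.zeros(1440, bool)
        diary[100:130] = True
        assert detect_non_wear(m, CFG, diary_nonwear=diary).sum() == 30


class TestSleepDetection:
    def test_perfect_night_with_diary(self):
        m = quiet_night_day(onset=1380, spt=480)
        sp = detect_sleep_period(m, 1380, 420, CFG)
        assert sp.onset == 1380
        assert sp.duration_min == 480
        assert sp.efficiency_pct == pytest.approx(100.0)

    def test_efficiency_75_percent(self):
        # 480-min period with 120 min of above-threshold epochs inside
        m = quiet_night_day(onset=1380, spt=480)
        interior = (1380 + 20 + np.arange(120)) % 1440
        m[interior] = 90.0
        sp = detect_sleep_period(m, 1380, 420, CFG)
        assert sp.duration_min == 480
        assert sp.efficiency_pct == pytest.approx(75.0)

    def test_window_not_crossing_midnight(self):
        m = quiet_night_day(onset=60, spt=400)
        sp = detect_sleep_period(m, 60, 460, CFG)
        assert (sp.onset, sp.duration_min) == (60, 400)

    def test_fallback_without_diary(self):
        m = quiet_night_day(onset=1380, spt=480)
        sp = detect_sleep_period(m, None, None, CFG)
        assert sp.duration_min >= 480
        assert abs(sp.onset - 1380) <= 5

    def test_no_candidate_window_returns_none(self):
        m = np.full(1440, 200.0)  # never quiescent
        assert detect_sleep_period(m, None, None, CFG) is None

    def test_diary_misreport_still_recovers_window(self):
        m = quiet_night_day(onset=1380, spt=480)
        sp = detect_sleep_period(m, 1380 + 35, 420 - 40, CFG)
        assert abs(sp.onset - 1380) <= 10
        assert abs(sp.duration_min - 480) <= 10


class TestSummarizeDay:
    def test_quiescent_night_sedentary_waking(self):
        m = quiet_night_day(onset=1380, spt=480, waking_level=60.0)
        nonwear = detect_non_wear(m, CFG)
        sp = detect_sleep_period(m, 1380, 420, CFG)
        s = summarize_day(m, nonwear, sp, "P1", "2023-01-02", "weekday", CFG)
        assert s.sleep_min == 480
        assert s.sedentary_min == 960
        assert s.lpa_min == s.mvpa_min == s.nonwear_min == 0

    def test_five_parts_sum_to_1440(self, default_cohort):
        epochs = default_cohort.epochs
        one = epochs[epochs["participant_id"] == "P001"]
        date = one["timestamp"].str[:10].iloc[0]
        mags = one.iloc[:1440]["magnitude_gmin"].to_numpy()
        s = process_day(mags, {"diary_sleep_onset": "23:00",
                               "diary_wake": "07:00"}, "P001", date, CFG)
        total = (s.sleep_min + s.sedentary_min + s.lpa_min + s.mvpa_min
                 + s.nonwear_min)
        assert total == 1440


def _summary(wear_waking, sleep):
    return DailySummary("P1", "2023-01-02", "weekday", sleep, 0.0, 0.0, 0.0,
                        0.0, 90.0, wear_waking, False)


class TestValidity:
    @pytest.mark.parametrize("wear,sleep,expected", [
        (599, 480, False),
        (600, 200, True),    # thresholds are inclusive
        (700, 199, False),
        (960, 480, True),
    ])
    def test_thresholds(self, wear, sleep, expected):
        assert is_valid_day(_summary(wear, sleep), CFG) is expected


def _daily_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "day_type",
                                       "is_valid"])


class TestInclusion:
    def test_five_weekdays_no_weekend_excluded(self):
        daily = _daily_frame([("P1", "weekday", True)] * 5)
        assert filter_valid_participants(daily, CFG) == []

    def test_three_weekdays_one_saturday_included(self):
        daily = _daily_frame([("P1", "weekday", True)] * 3
                             + [("P1", "weekend", True)])
        assert filter_valid_participants(daily, CFG) == ["P1"]

    def test_invalid_days_do_not_count(self):
        daily = _daily_frame([("P1", "weekday", True)] * 3
                             + [("P1", "weekend", False)] * 5)
        assert filter_valid_participants(daily, CFG) == []

    def test_day_type_weekend_is_sat_sun(self):
        assert day_type_of("2023-01-07") == "weekend"   # Saturday
        assert day_type_of("2023-01-08") == "weekend"   # Sunday
        assert day_type_of("2023-01-09") == "weekday"   # Monday


def _valid_days(pid, weekday_sed, weekend_sed, n_wd=5, n_we=2):
    rows = []
    for sed, dtype, n in [(weekday_sed, "weekday", n_wd),
                          (weekend_sed, "weekend", n_we)]:
        for _ in range(n):
            rows.append({"participant_id": pid, "day_type": dtype,
                         "sleep_min": 480.0, "sedentary_min": sed,
                         "lpa_min": 1440.0 - 480.0 - sed - 20.0,
                         "mvpa_min": 20.0, "nonwear_min": 0.0,
                         "sleep_efficiency_pct": 80.0, "is_valid": True})
    return pd.DataFrame(rows)


class TestWeighting:
    def test_equal_means_identity(self):
        ptu = weighted_time_use(_valid_days("P1", 700.0, 700.0), CFG)
        assert ptu.sedentary_min == pytest.approx(700.0)

    def test_five_two_arithmetic(self):
        ptu = weighted_time_use(_valid_days("P1", 700.0, 770.0), CFG)
        assert ptu.sedentary_min == pytest.approx((5 * 700 + 2 * 770) / 7)
        assert ptu.sedentary_min == pytest.approx(720.0)

    def test_weighted_parts_sum_to_1440(self):
        ptu = weighted_time_use(_valid_days("P1", 700.0, 770.0), CFG)
        total = (ptu.sleep_min + ptu.sedentary_min + ptu.lpa_min
                 + ptu.mvpa_min + ptu.nonwear_min)
        assert total == pytest.approx(1440.0, abs=1e-9)

    def test_no_weekend_rejected(self):
        days = _valid_days("P1", 700.0, 770.0, n_wd=5, n_we=0)
        with pytest.raises(ValueError, match="weekend"):
            weighted_time_use(days, CFG)


class TestPipelineIdempotence:
    def test_reprocessing_identical(self, noiseless_cohort):
        from timeuse24.accelerometry import process_cohort
        d1, p1 = process_cohort(noiseless_cohort.epochs, noiseless_cohort.diary)
        d2, p2 = process_cohort(noiseless_cohort.epochs, noiseless_cohort.diary)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(p1, p2)
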