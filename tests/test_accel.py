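"""Accelerometer screening: window, minute aggregation, non-wear, MVPA."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from paqcal import accel, synthetic
from paqcal.accel import (
    CutpointConfig,
    EpochFormatError,
    EpochSeries,
    ScreenConfig,
    classify_mvpa,
    detect_nonwear,
    mvpa_cutpoint_cpm,
    read_epoch_csv,
    restrict_day_window,
    summarize_day,
    summarize_week,
    to_minute_counts,
    write_epoch_csv,
)


def make_series(counts, start="2010-03-01 08:00:00", pid="T01"):
    counts = np.asarray(counts)
    ts = pd.date_range(start, periods=len(counts), freq="30s")
    return EpochSeries(pid, ts, counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_epoch_csv_round_trip(tmp_path, rng):
    series = make_series(rng.integers(0, 3000, 200))
    path = tmp_path / "T01.csv"
    write_epoch_csv(series, path)
    back = read_epoch_csv(path)
    assert back.participant_id == series.participant_id
    assert (back.timestamps == series.timestamps).all()
    assert (back.counts == series.counts).all()


def test_read_rejects_negative_count(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# participant_id: X\n# epoch_seconds: 30\ntimestamp,counts\n"
        "2010-03-01T08:00:00,10\n2010-03-01T08:00:30,-5\n"
    )
    with pytest.raises(EpochFormatError, match=r":5.*negative"):
        read_epoch_csv(path)


def test_read_rejects_wrong_epoch_length(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# participant_id: X\n# epoch_seconds: 60\ntimestamp,counts\n"
        "2010-03-01T08:00:00,10\n2010-03-01T08:01:00,10\n"
    )
    with pytest.raises(EpochFormatError, match="epoch length"):
        read_epoch_csv(path)


def test_read_rejects_bad_spacing(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# participant_id: X\n# epoch_seconds: 30\ntimestamp,counts\n"
        "2010-03-01T08:00:00,10\n2010-03-01T08:01:00,10\n"
    )
    with pytest.raises(EpochFormatError, match="spacing"):
        read_epoch_csv(path)


# ---------------------------------------------------------------------------
# Day window
# ---------------------------------------------------------------------------


def test_full_day_restricts_to_780_minutes():
    series = make_series(np.ones(2880), start="2010-03-01 00:00:00")
    windowed = restrict_day_window(series)
    assert len(windowed) == 1560  # 13 h x 2 epochs/min
    assert windowed.timestamps[0].time() == dt.time(8, 0)
    assert windowed.timestamps[-1].time() == dt.time(20, 59, 30)


def test_window_is_half_open_at_end():
    ts = pd.DatetimeIndex(
        ["2010-03-01 20:59:30", "2010-03-01 21:00:00", "2010-03-01 21:00:30"]
    )
    series = EpochSeries("T01", ts, np.array([1, 1, 1]))
    windowed = restrict_day_window(series)
    assert len(windowed) == 1
    assert windowed.timestamps[0].time() == dt.time(20, 59, 30)


def test_night_series_empties():
    series = make_series(np.ones(100), start="2010-03-01 02:00:00")
    assert len(restrict_day_window(series)) == 0


def test_inverted_window_rejected():
    series = make_series(np.ones(10))
    with pytest.raises(accel.ConfigError):
        restrict_day_window(series, dt.time(21, 0), dt.time(8, 0))


# ---------------------------------------------------------------------------
# Minute aggregation
# ---------------------------------------------------------------------------


def test_minute_counts_sum_epoch_pairs():
    series = make_series([40, 60, 0, 0, 500, 100])
    minutes = to_minute_counts(series)
    assert list(minutes) == [100, 0, 600]


def test_unpaired_trailing_epoch_dropped():
    series = make_series([40, 60, 30])
    minutes = to_minute_counts(series)
    assert list(minutes) == [100]


# ---------------------------------------------------------------------------
# Non-wear detection
# ---------------------------------------------------------------------------


def test_all_zero_day_is_nonwear():
    wear = detect_nonwear(np.zeros(780))
    assert not wear.any()


def test_89_minute_zero_run_is_wear():
    x = np.concatenate([[500], np.zeros(89), [500]])
    assert detect_nonwear(x).all()


def test_allowance_interruption_absorbed():
    # 50 zeros + 2 min at 50 cpm + 48 zeros = 100-min non-wear run
    x = synthetic.interruption_fixture(50, 2, 50, 48, flank_minutes=200, flank_cpm=500)
    wear = detect_nonwear(x)
    assert wear[:200].all() and wear[300:].all()
    assert not wear[200:300].any()


def test_three_minute_interruption_splits_run():
    # 50 + 3 min at 50 cpm + 48 -> two sub-90 runs -> all wear
    x = synthetic.interruption_fixture(50, 3, 50, 48, flank_minutes=200, flank_cpm=500)
    assert detect_nonwear(x).all()


def test_interruption_above_ceiling_splits_run():
    x = synthetic.interruption_fixture(50, 1, 101, 48, flank_minutes=200, flank_cpm=500)
    assert detect_nonwear(x).all()


def nonwear_bruteforce(x, min_bout=90, allow_max=2, ceiling=100.0):
    """Independent per-index expansion scan over maximal candidate runs."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    term = [False] * n
    for i in range(n):
        if x[i] > ceiling:
            term[i] = True
        elif x[i] > 0:
            a = i
            while a > 0 and x[a - 1] > 0:
                a -= 1
            b = i
            while b < n - 1 and x[b + 1] > 0:
                b += 1
            if b - a + 1 > allow_max or (x[a : b + 1] > ceiling).any():
                term[i] = True
    wear = [True] * n
    i = 0
    while i < n:
        if term[i]:
            i += 1
            continue
        j = i
        while j < n and not term[j]:
            j += 1
        if j - i >= min_bout:
            for k in range(i, j):
                wear[k] = False
        i = j
    return np.array(wear)


def test_nonwear_matches_bruteforce_on_random_traces(rng):
    """Detector equals an exhaustive maximal-run scan on 1,000 random days."""
    values = np.array([0, 0, 0, 50, 100, 101, 500])
    for _ in range(1000):
        # run-structured traces so long zero bouts actually occur
        pieces = []
        while sum(len(p) for p in pieces) < 780:
            v = values[rng.integers(len(values))]
            pieces.append(np.full(rng.integers(1, 120), v))
        x = np.concatenate(pieces)[:780]
        expected = nonwear_bruteforce(x)
        got = detect_nonwear(x)
        assert (got == expected).all()


def test_empty_input_empty_mask():
    assert detect_nonwear([]).size == 0


# ---------------------------------------------------------------------------
# Cut points and MVPA classification
# ---------------------------------------------------------------------------


def test_freedson_cutpoint_age10():
    # closed form: solve 4 = 2.757 + 0.0015*cpm - 0.08957*age - 0.000038*cpm*age
    assert mvpa_cutpoint_cpm(10) == pytest.approx(1910, abs=1)


def test_cutpoint_zero_when_threshold_at_rest_value():
    cfg = CutpointConfig(met_threshold=2.757 - 0.08957 * 10)
    assert mvpa_cutpoint_cpm(10, cfg) == 0.0


def test_cutpoint_table_passthrough():
    cfg = CutpointConfig(age_cpm_table={12: 1234.0})
    assert mvpa_cutpoint_cpm(12, cfg) == 1234.0
    with pytest.raises(accel.ConfigError):
        mvpa_cutpoint_cpm(9, cfg)


def test_classify_counts_only_wear_epochs():
    # 20 above-threshold epochs during wear -> 10 min; same counts in
    # non-wear minutes are not counted
    counts = np.concatenate([np.full(20, 2000), np.zeros(20)])
    series = make_series(counts)
    mask = classify_mvpa(series, epoch_threshold=955)
    assert mask.sum() == 20  # 10 minutes
    minutes = to_minute_counts(series)
    wear = pd.Series([False] * 10 + [True] * 10, index=minutes.index)
    mask = classify_mvpa(series, 955, wear)
    assert mask.sum() == 0  # active epochs fell inside non-wear minutes


def test_lower_cutpoint_never_decreases_mvpa(small_cohort):
    for profile in small_cohort[:3]:
        trace = synthetic.generate_epoch_trace(profile)
        windowed = restrict_day_window(trace)
        hi = classify_mvpa(windowed, 955).sum()
        lo = classify_mvpa(windowed, 500).sum()
        assert lo >= hi


# ---------------------------------------------------------------------------
# Day and week summaries
# ---------------------------------------------------------------------------


def _day(date, wear_min, mvpa_min):
    pct = 100 * mvpa_min / wear_min if wear_min else None
    return accel.DaySummary(
        date=date,
        is_weekend=date.weekday() >= 5,
        wear_minutes=wear_min,
        mvpa_minutes=mvpa_min,
        pct_mvpa=pct,
        counts_per_minute_mean=300.0,
        valid=wear_min >= 546,
    )


@pytest.mark.parametrize("wear,valid", [(546, True), (545, False), (780, True)])
def test_valid_day_boundary(wear, valid):
    minutes = pd.Series(
        np.r_[np.full(wear, 300), np.zeros(780 - wear)],
        index=pd.date_range("2010-03-01 08:00", periods=780, freq="min"),
    )
    wear_mask = np.r_[np.ones(wear, bool), np.zeros(780 - wear, bool)]
    mvpa_mask = np.zeros(2 * wear, dtype=bool)
    day = summarize_day(dt.date(2010, 3, 1), wear_mask, mvpa_mask, minutes)
    assert day.valid is valid
    assert day.wear_minutes == wear


def test_day_pct_mvpa_ratio():
    minutes = pd.Series(
        np.full(780, 300),
        index=pd.date_range("2010-03-01 08:00", periods=780, freq="min"),
    )
    wear_mask = np.ones(780, bool)
    mvpa_mask = np.zeros(1560, bool)
    mvpa_mask[:156] = True  # 78 minutes
    day = summarize_day(dt.date(2010, 3, 1), wear_mask, mvpa_mask, minutes)
    assert day.pct_mvpa == pytest.approx(10.0)


def test_week_rule_requires_weekend_day():
    mon = dt.date(2010, 3, 1)
    weekdays = [_day(mon + dt.timedelta(days=i), 700, 50) for i in range(3)]
    saturday = _day(dt.date(2010, 3, 6), 700, 50)
    ok = summarize_week("A", weekdays + [saturday])
    assert ok.week_valid
    bad = summarize_week("B", weekdays + [_day(dt.date(2010, 3, 4), 700, 50)])
    assert not bad.week_valid and bad.valid_days == 4
    assert bad.pct_mvpa_combined is None


def test_combined_weighting():
    mon = dt.date(2010, 3, 1)
    days = [_day(mon + dt.timedelta(days=i), 780, 0.08 * 780) for i in range(5)]
    days += [_day(dt.date(2010, 3, 6), 780, 0.08 * 780),
             _day(dt.date(2010, 3, 7), 780, 0.08 * 780)]
    assert summarize_week("A", days).pct_mvpa_combined == pytest.approx(8.0)
    days = [_day(mon + dt.timedelta(days=i), 780, 0.07 * 780) for i in range(5)]
    days += [_day(dt.date(2010, 3, 6), 780, 0.0),
             _day(dt.date(2010, 3, 7), 780, 0.0)]
    assert summarize_week("A", days).pct_mvpa_combined == pytest.approx(5.0)
    cfg = ScreenConfig(combined_weighting="mean")
    assert summarize_week("A", days, cfg).pct_mvpa_combined == pytest.approx(5.0)


def test_wear_partition_and_mvpa_subset(small_cohort):
    """Wear + non-wear = 780 window minutes; MVPA never exceeds wear."""
    for profile in small_cohort[:4]:
        trace = synthetic.generate_epoch_trace(profile)
        person, days = accel.process_series(trace, profile.age_years)
        for day in days:
            assert day.mvpa_minutes <= day.wear_minutes <= 780
        # full-window traces: every minute is either wear or non-wear
        windowed = restrict_day_window(trace)
        dates = windowed.timestamps.normalize()
        for d in dates.unique():
            sel = np.asarray(dates == d)
            sub = EpochSeries("x", windowed.timestamps[sel], windowed.counts[sel])
            minutes = to_minute_counts(sub)
            assert len(minutes) == 780
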