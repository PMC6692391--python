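"""Unit and property tests for the sleep-window heuristic."""

import numpy as np
import pandas as pd
import pytest

from somnotypes.actigraphy import (
    AccelEpochSeries,
    SleepWindowAnalyzer,
    SptWindow,
    compute_day_metrics,
    detect_inactivity_bouts,
    detect_sleep_episodes,
    detect_spt_window,
    merge_bouts_to_blocks,
    movement_threshold,
    rolling_median_abs_change,
    summarize_person,
    z_angle_from_triaxial,
)
from somnotypes.simulate import AccelSimConfig, gen_accel_trace

EPD = 17280  # epochs per day at 5 s


def make_trace(z, activity=None, epoch_seconds=5.0):
    z = np.asarray(z, float)
    act = np.full(z.size, 10.0) if activity is None else activity
    return AccelEpochSeries("t", epoch_seconds,
                            pd.Timestamp("2015-06-01 12:00:00"), z, act)


# ---------------------------------------------------------------------------
# rolling median of |z-angle change|


def brute_rolling_median(z, w):
    d = np.abs(np.diff(z))
    d = np.concatenate([d[:1], d])
    half = w // 2
    return np.array([
        np.median(d[max(0, i - half):min(d.size, i + half + 1)])
        for i in range(d.size)
    ])


def test_rolling_median_constant_angle_is_zero():
    out = rolling_median_abs_change(np.full(100, 33.0))
    assert np.all(out == 0)


def test_rolling_median_alternating_pattern():
    z = np.tile([0.0, 10.0], 30)
    out = rolling_median_abs_change(z, window_min=0.25, epoch_seconds=5.0)
    assert np.allclose(out, 10.0)


def test_rolling_median_degenerate_window_is_abs_diff():
    z = np.array([0.0, 3.0, -1.0, 5.0])
    out = rolling_median_abs_change(z, window_min=1 / 12, epoch_seconds=5.0)
    assert np.allclose(out, [3.0, 3.0, 4.0, 6.0])


@pytest.mark.parametrize("n,window_min", [(50, 0.25), (300, 5.0), (77, 1.0)])
def test_rolling_median_matches_bruteforce(rng, n, window_min):
    z = rng.uniform(-90, 90, size=n)
    w = int(round(window_min * 60 / 5.0))
    if w % 2 == 0:
        w += 1
    assert np.allclose(
        rolling_median_abs_change(z, window_min, 5.0),
        brute_rolling_median(z, w))


def test_rolling_median_rejects_subepoch_window():
    with pytest.raises(ValueError):
        rolling_median_abs_change(np.zeros(10), window_min=0.01,
                                  epoch_seconds=5.0)


def test_detector_invariant_to_constant_angle_offset():
    trace, _ = gen_accel_trace(AccelSimConfig(n_days=1, seed=5,
                                              daytime_jitter_sd=10.0))
    a = SleepWindowAnalyzer().fit(trace)
    shifted = make_trace(np.clip(trace.z_angle - trace.z_angle.mean(), -90, 90),
                         trace.activity)
    b = SleepWindowAnalyzer().fit(shifted)
    # only changes matter, apart from rare clipping at +/-90
    assert a.spt_windows_[0].onset_epoch == b.spt_windows_[0].onset_epoch
    assert a.spt_windows_[0].wake_epoch == b.spt_windows_[0].wake_epoch


# ---------------------------------------------------------------------------
# threshold, bouts, blocks, SPT


def manual_quantile(values, q):
    """Independent sort-and-linear-interpolate quantile."""
    v = np.sort(np.asarray(values, float))
    h = (v.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_movement_threshold_closed_cases():
    assert movement_threshold(np.zeros(50)) == 0.0
    assert movement_threshold(np.full(50, 3.0), multiplier=1.0) == 3.0
    vals = np.arange(1.0, 101.0)
    assert movement_threshold(vals, 10.0, multiplier=1.0) == pytest.approx(
        manual_quantile(vals, 0.1), abs=1e-12)
    with pytest.raises(ValueError):
        movement_threshold([])


def test_inactivity_bouts_duration_rule():
    mask = np.zeros(3000, bool)
    mask[100:100 + 1440] = True  # 2 h at 5 s epochs
    assert detect_inactivity_bouts(mask) == [(100, 1540)]
    mask = np.zeros(600, bool)
    mask[10:10 + 348] = True  # 29 min: below the strict 30-min minimum
    assert detect_inactivity_bouts(mask) == []


def test_inactivity_bouts_match_bruteforce_scan(rng):
    for _ in range(100):
        mask = rng.random(400) < 0.7
        got = detect_inactivity_bouts(mask, min_duration_min=1.0,
                                      epoch_seconds=5.0)
        runs, start = [], None
        for i, v in enumerate(mask):
            if v and start is None:
                start = i
            if not v and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, mask.size))
        assert got == [(s, e) for s, e in runs if e - s >= 12]


def test_merge_bouts_strict_gap_rule():
    b1 = (0, 360)              # 30 min
    gap59 = (360 + 707, 360 + 707 + 360)
    assert merge_bouts_to_blocks([b1, gap59]) == [(0, gap59[1])]
    gap60 = (360 + 720, 360 + 720 + 360)
    assert merge_bouts_to_blocks([b1, gap60]) == [b1, gap60]


def test_merge_bouts_transitive_chaining():
    bouts = [(0, 360), (720, 1080), (1440, 1800)]  # 30-min gaps
    assert merge_bouts_to_blocks(bouts) == [(0, 1800)]
    with pytest.raises(ValueError):
        merge_bouts_to_blocks([(720, 1080), (0, 360)])


def test_spt_window_longest_block_with_earliest_tiebreak():
    assert detect_spt_window([(0, 2160), (5000, 10040)]).onset_epoch == 5000
    single = detect_spt_window([(7, 1000)])
    assert (single.onset_epoch, single.wake_epoch) == (7, 1000)
    tie = detect_spt_window([(100, 200), (300, 400)])
    assert tie.onset_epoch == 100
    assert detect_spt_window([]) is None
    with pytest.raises(ValueError):
        SptWindow(0, 10, 10)


# ---------------------------------------------------------------------------
# sleep episodes


def test_sleep_episodes_constant_angle_spans_spt():
    z = np.concatenate([np.repeat([0, 20, -15, 40.0], 500), np.full(4000, 10.0)])
    spt = SptWindow(0, 2200, 5800)
    eps = detect_sleep_episodes(z, spt)
    assert eps == [(2200, 5800)]


def test_sleep_episodes_below_minimum_duration():
    # stable 4-min runs separated by sustained 6-min movement; every stable
    # stretch of the rolled metric falls below the 5-min episode minimum
    rng = np.random.default_rng(0)
    seg = []
    for _ in range(8):
        seg.append(np.full(48, 10.0))                # 4 min still
        seg.append(rng.uniform(-60, 60, size=72))    # 6 min movement
    z = np.concatenate(seg)
    spt = SptWindow(0, 0, z.size)
    assert detect_sleep_episodes(z, spt) == []


def test_sleep_episodes_match_runlength_oracle():
    # plant sustained movement bursts at known epochs inside the window
    rng = np.random.default_rng(1)
    z = np.full(6000, 5.0)
    bursts = [(1000, 1100), (2500, 2620), (4000, 4090)]
    for s, e in bursts:
        z[s:e] = rng.uniform(-80, 80, size=e - s)
    spt = SptWindow(0, 0, 6000)
    eps = detect_sleep_episodes(z, spt)
    rolled = rolling_median_abs_change(z)
    stable = rolled < 5.0
    runs, start = [], None
    for i in range(6000):
        if stable[i] and start is None:
            start = i
        if not stable[i] and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, 6000))
    assert eps == [(s, e) for s, e in runs if e - s >= 60]
    with pytest.raises(ValueError):
        detect_sleep_episodes(z, SptWindow(0, 0, 9000))


# ---------------------------------------------------------------------------
# day metrics and person summary


def flat_day_trace():
    z = np.zeros(EPD)
    act = np.full(EPD, 20.0)
    return make_trace(z, act)


def test_sleep_efficiency_closed_forms():
    trace = flat_day_trace()
    spt = SptWindow(0, 8000, 8000 + 5760)  # 480 min
    full = compute_day_metrics(trace, spt, [(8000, 13760)], [])
    assert full.sleep_efficiency == pytest.approx(1.0)
    assert full.sleep_duration_min == pytest.approx(480.0)
    part = compute_day_metrics(trace, spt, [(8000, 10000), (11000, 13320)], [])
    assert part.sleep_efficiency == pytest.approx((2000 + 2320) / 5760)
    assert part.n_sleep_bouts == 2
    assert part.sleep_midpoint_min == pytest.approx((8000 + 5760 / 2) * 5 / 60)


def test_l5_timing_planted_trough():
    # activity trough 02:00-07:00 -> L5 midpoint 4.5 h after midnight
    act = np.full(EPD, 50.0)
    lo = int(14 * 3600 / 5)  # 02:00 is 14 h after the noon day-start
    act[lo:lo + int(5 * 3600 / 5)] = 1.0
    trace = make_trace(np.zeros(EPD), act)
    m = compute_day_metrics(trace, SptWindow(0, lo, lo + 3600), [], [])
    assert m.l5_timing_hours == pytest.approx(4.5)


def test_m10_timing_planted_peak():
    act = np.full(EPD, 1.0)
    lo = int(2 * 3600 / 5)  # peak 14:00-24:00 -> midpoint 19:00 = 7 h past noon
    act[lo:lo + int(10 * 3600 / 5)] = 80.0
    trace = make_trace(np.zeros(EPD), act)
    m = compute_day_metrics(trace, SptWindow(0, 100, 4000), [], [])
    assert m.m10_timing_hours == pytest.approx(7.0)


def test_l5_moving_average_equals_exhaustive_scan(rng):
    act = rng.uniform(0, 60, size=EPD)
    trace = make_trace(np.zeros(EPD), act)
    m = compute_day_metrics(trace, SptWindow(0, 100, 4000), [], [])
    win = int(5 * 3600 / 5)
    sums = np.array([act[s:s + win].sum() for s in range(EPD - win + 1)])
    expect = (int(np.argmin(sums)) + win / 2) * 5 / 3600
    assert m.l5_timing_hours == pytest.approx((expect + 12) % 24)


def test_diurnal_inactivity_excludes_spt():
    trace = flat_day_trace()
    spt = SptWindow(0, 8000, 13760)
    bouts = [(8000, 13760), (2000, 2720), (13500, 14220)]  # nap + overlap
    m = compute_day_metrics(trace, spt, [(8000, 13760)], bouts)
    # 2000-2720 fully outside (60 min); 13500-14220 overlaps SPT by 260 epochs
    assert m.diurnal_inactivity_min == pytest.approx((720 + 460) * 5 / 60)


def test_person_summary_sample_sd():
    def day(dur):
        return compute_day_metrics(
            flat_day_trace(), SptWindow(0, 8000, 8000 + 5760),
            [(8000, 8000 + int(dur * 12))], [])
    s = summarize_person([day(400), day(420), day(440)])
    assert s.sleep_duration_mean_min == pytest.approx(420.0)
    assert s.sleep_duration_sd_min == pytest.approx(20.0)
    same = summarize_person([day(410), day(410)])
    assert same.sleep_duration_sd_min == pytest.approx(0.0)
    single = summarize_person([day(400), None])
    assert single.n_days == 1
    assert np.isnan(single.sleep_duration_sd_min)
    with pytest.raises(ValueError):
        summarize_person([None])


# ---------------------------------------------------------------------------
# end-to-end invariants


def test_analyzer_invariants_on_simulated_week():
    trace, truth = gen_accel_trace(AccelSimConfig(n_days=3, seed=11))
    an = SleepWindowAnalyzer().fit(trace)
    assert len(an.spt_windows_) == 3
    for day, spt in enumerate(an.spt_windows_):
        eps = an.episodes_[day]
        assert all(spt.onset_epoch <= s < e <= spt.wake_epoch for s, e in eps)
        assert all(e0 <= s1 for (_, e0), (s1, _) in zip(eps, eps[1:]))
    m = an.day_metrics_
    assert ((m.sleep_efficiency > 0) & (m.sleep_efficiency <= 1)).all()
    assert (m.sleep_duration_min <= m.spt_duration_min + 1e-9).all()


def test_nap_contributes_diurnal_inactivity_not_spt():
    cfg = AccelSimConfig(n_days=1, daytime_nap=(180.0, 240.0), seed=3)
    trace, truth = gen_accel_trace(cfg)
    an = SleepWindowAnalyzer().fit(trace)
    spt = an.spt_windows_[0]
    a, b = truth["windows"][0]
    assert abs(spt.onset_epoch - a) <= 120 and abs(spt.wake_epoch - b) <= 120
    assert an.day_metrics_.diurnal_inactivity_min.iloc[0] >= 50.0


def test_z_angle_from_triaxial_reference_directions():
    assert z_angle_from_triaxial(0, 0, 1) == pytest.approx(90.0)
    assert z_angle_from_triaxial(1, 0, 0) == pytest.approx(0.0)
    assert z_angle_from_triaxial(0, 1, -1) == pytest.approx(-45.0)
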