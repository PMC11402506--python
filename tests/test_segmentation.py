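"""Life-stage detectors and their composition."""

import numpy as np
import pandas as pd
import pytest

import vultrack as vt
from vultrack.segmentation import KM_PER_DEG_LAT

from conftest import hourly_times, make_traj

NEST = vt.GeoPoint(-6.2, 41.2)


def lat_off(km):
    return km / KM_PER_DEG_LAT


class TestNestDeparture:
    def test_first_fix_beyond_200m(self):
        lats = NEST.lat + lat_off(np.array([0.05, 0.15, 0.25]))
        traj = make_traj(hourly_times("2021-07-10", 3), [NEST.lon] * 3, lats,
                         nest=(NEST.lon, NEST.lat))
        t = vt.detect_nest_departure(traj, NEST)
        assert t == traj.fixes["timestamp"].iloc[2]

    def test_never_beyond_200m_gives_none(self):
        lats = NEST.lat + lat_off(np.array([0.05, 0.1, 0.19]))
        traj = make_traj(hourly_times("2021-07-10", 3), [NEST.lon] * 3, lats,
                         nest=(NEST.lon, NEST.lat))
        assert vt.detect_nest_departure(traj, NEST) is None

    def test_exactly_200m_is_inclusive(self):
        lats = [NEST.lat, NEST.lat + lat_off(0.2)]
        traj = make_traj(hourly_times("2021-07-10", 2), [NEST.lon] * 2, lats,
                         nest=(NEST.lon, NEST.lat))
        assert vt.detect_nest_departure(traj, NEST) == traj.fixes["timestamp"].iloc[1]


def _looping_then_south(n_loop_days=6, leg_km=300.0):
    """Daily fixes: loops out to 5 km and back (twice), then a directed
    southward leg of leg_km over four days."""
    lats, times = [], []
    t0 = pd.Timestamp("2021-07-10")
    day = 0
    for _ in range(2):
        for d_km in (0.0, 5.0, 0.5):
            lats.append(NEST.lat - lat_off(d_km))
            times.append(t0 + pd.Timedelta(days=day))
            day += 1
    for frac in (0.25, 0.5, 0.75, 1.0):
        lats.append(NEST.lat - lat_off(leg_km * frac))
        times.append(t0 + pd.Timedelta(days=day))
        day += 1
    for _ in range(5):   # linger at the endpoint so the confirm window closes
        lats.append(lats[-1])
        times.append(t0 + pd.Timedelta(days=day))
        day += 1
    return make_traj(times, [NEST.lon] * len(lats), lats,
                     nest=(NEST.lon, NEST.lat))


class TestNatalDeparture:
    def test_loops_then_long_leg(self):
        traj = _looping_then_south()
        t, confirmed = vt.detect_natal_departure(traj, NEST)
        # last fix inside 2 km is the 0.5-km return of the second loop
        assert t == traj.fixes["timestamp"].iloc[5]
        assert confirmed

    def test_never_leaves_radius(self):
        lats = NEST.lat + lat_off(np.array([0.0, 1.0, 0.5, 1.5, 0.2]))
        traj = make_traj(hourly_times("2021-07-10", 5, 24), [NEST.lon] * 5, lats,
                         nest=(NEST.lon, NEST.lat))
        t, _ = vt.detect_natal_departure(traj, NEST)
        assert t is None

    def test_small_drift_fails_confirmation(self):
        traj = _looping_then_south(leg_km=10.0)
        t, _ = vt.detect_natal_departure(traj, NEST)
        assert t is None

    def test_short_track_flags_unconfirmed(self):
        times = hourly_times("2021-07-10", 3, 24)
        lats = [NEST.lat, NEST.lat - lat_off(30), NEST.lat - lat_off(45)]
        traj = make_traj(times, [NEST.lon] * 3, lats, nest=(NEST.lon, NEST.lat))
        t, confirmed = vt.detect_natal_departure(traj, NEST)
        assert t == times[0] and not confirmed


class TestGibraltarCrossing:
    def test_southbound_pair_in_window(self):
        traj = make_traj(hourly_times("2021-09-01", 2), [-5.6, -5.5], [36.2, 35.8])
        assert vt.detect_gibraltar_crossing(traj) == traj.fixes["timestamp"].iloc[1]

    def test_crossing_outside_window_ignored(self):
        traj = make_traj(hourly_times("2021-09-01", 2), [-2.0, -2.0], [36.2, 35.8])
        assert vt.detect_gibraltar_crossing(traj) is None

    def test_northbound_only_ignored(self):
        traj = make_traj(hourly_times("2021-09-01", 2), [-5.6, -5.5], [35.8, 36.2])
        assert vt.detect_gibraltar_crossing(traj) is None

    def test_interpolated_crossing_longitude_counts(self):
        # endpoints straddle the window but the segment crosses inside it
        traj = make_traj(hourly_times("2021-09-01", 2), [-6.3, -5.0], [36.4, 35.6])
        assert vt.detect_gibraltar_crossing(traj) is not None


class TestSaharaSpan:
    def test_monotone_southbound_duration(self):
        times = hourly_times("2021-09-01", 10, 24)
        lats = np.linspace(31.0, 20.0, 10)   # crosses 30 then 22.5
        traj = make_traj(times, [-7.0] * 10, lats)
        span = vt.detect_sahara_span(traj)
        assert span is not None
        start, end = span
        days = (end - start).total_seconds() / 86400
        # 30 -> 22.5 degrees at ~1.22 deg/day is ~6 days, within grid slack
        assert days == pytest.approx((30.0 - 22.5) / (11.0 / 9.0), abs=1.5)

    def test_turnback_gives_none(self):
        lats = [31.0, 28.0, 25.0, 27.0, 30.0, 32.0]
        traj = make_traj(hourly_times("2021-09-01", 6, 24), [-7.0] * 6, lats)
        assert vt.detect_sahara_span(traj) is None

    def test_two_attempts_anchor_to_successful(self):
        lats = [31.0, 26.0, 31.0, 31.0, 29.0, 24.0, 22.0]
        times = hourly_times("2021-09-01", 7, 24)
        traj = make_traj(times, [-7.0] * 7, lats)
        start, end = vt.detect_sahara_span(traj)
        assert start == times[3]     # last fix at/above 30 before the drop
        assert end == times[6]


def _sahel_with_return(foray_km=0.0, climb_to=31.0, end_early=False):
    """Half-hourly Sahel track at 16N with an optional mid-stay northward
    foray, then a 100 km/day climb starting day 200."""
    rng = np.random.default_rng(5)
    dt = 0.5 / 24
    n_stay = int(200 / dt)
    lat = 16.0 + np.cumsum(rng.normal(0, 0.002, n_stay))
    lat -= np.linspace(0, lat[-1] - 16.0, n_stay)   # pin endpoints near 16
    if foray_km:
        k = n_stay // 2
        bump = np.zeros(n_stay)
        width = int(6 / dt)
        bump[k:k + width] = np.sin(np.linspace(0, np.pi, width)) * foray_km / KM_PER_DEG_LAT
        lat = lat + bump
    climb = np.arange(16.0, climb_to, 100.0 / KM_PER_DEG_LAT * dt)
    lat = np.concatenate([lat, climb])
    if end_early:
        lat = lat[lat <= 24.0]
    times = hourly_times("2021-10-01", len(lat), 0.5)
    return make_traj(times, [-8.0] * len(lat), lat), times[n_stay]


class TestReturnStart:
    def test_detected_within_a_day_of_climb_onset(self):
        traj, t_true = _sahel_with_return()
        t = vt.detect_return_start(traj)
        assert t is not None
        assert abs((t - t_true).total_seconds()) / 86400 <= 1.0

    def test_short_foray_rejected(self):
        traj, _ = _sahel_with_return(foray_km=80.0, climb_to=16.5)
        assert vt.detect_return_start(traj) is None

    def test_aborted_return_still_detected(self):
        # reaches 31N (north of the desert line) then turns back south
        traj, t_true = _sahel_with_return()
        f = traj.fixes
        lat = f["lat"].to_numpy().copy()
        n = len(lat)
        back = np.arange(lat[-1], 18.0, -100.0 / KM_PER_DEG_LAT * (0.5 / 24))
        lat2 = np.concatenate([lat, back])
        times = hourly_times("2021-10-01", len(lat2), 0.5)
        traj2 = make_traj(times, [-8.0] * len(lat2), lat2)
        t = vt.detect_return_start(traj2)
        assert t is not None
        assert abs((t - t_true).total_seconds()) / 86400 <= 1.0

    def test_truncated_climb_counts_as_return(self):
        # transmitter lost at 24N, before the desert line
        traj, t_true = _sahel_with_return(end_early=True)
        t = vt.detect_return_start(traj)
        assert t is not None
        assert abs((t - t_true).total_seconds()) / 86400 <= 1.5


class TestSegmentComposition:
    def test_full_migrant_cycle_six_intervals(self, small_cohort_clean):
        _, clean, segs, truths = small_cohort_clean
        found = False
        for traj, seg in zip(clean, segs):
            tr = truths[traj.individual_id]
            if tr.strategy != "migrant" or tr.iberia_return is None:
                continue
            found = True
            assert [iv.stage for iv in seg.intervals] == [
                "dependence", "iberia_premigration", "sahara_crossing",
                "sahel_stay", "return_migration", "iberia_postreturn"]
            for boundary, truth_t in [
                    (seg.intervals[1].start, tr.natal_departure),
                    (seg.intervals[2].start, tr.gibraltar_crossing),
                    (seg.intervals[3].start, tr.sahel_arrival),
                    (seg.intervals[4].start, tr.return_start),
                    (seg.intervals[5].start, tr.iberia_return)]:
                assert abs((boundary - truth_t).total_seconds()) / 86400 <= 1.0
        assert found

    def test_resident_two_intervals(self, small_cohort_clean):
        _, clean, segs, truths = small_cohort_clean
        residents = [s for t, s in zip(clean, segs)
                     if truths[t.individual_id].strategy == "non_migrant"
                     and truths[t.individual_id].death_time is None]
        assert residents
        for seg in residents:
            assert [iv.stage for iv in seg.intervals] == ["dependence", "residency"]
            assert seg.strategy == "non_migrant"

    def test_empty_track_undetermined(self):
        traj = make_traj([], [], [], nest=(NEST.lon, NEST.lat),
                         tagging_date="2021-07-10")
        seg = vt.segment(traj)
        assert seg.intervals == [] and seg.strategy == "undetermined"

    def test_intervals_contiguous_and_monotone(self, small_cohort_clean):
        _, clean, segs, _ = small_cohort_clean
        for seg in segs:
            for a, b in zip(seg.intervals, seg.intervals[1:]):
                assert a.end == b.start
                assert a.start <= a.end

    def test_pre_tagging_fixes_ignored(self, small_cohort_clean):
        _, clean, segs, _ = small_cohort_clean
        traj = clean[0]
        early = traj.fixes.iloc[:3].copy()
        early["timestamp"] = early["timestamp"] - pd.Timedelta(days=400)
        padded = vt.Trajectory(traj.deployment,
                               pd.concat([early, traj.fixes], ignore_index=True))
        seg1, seg2 = vt.segment(traj), vt.segment(padded)
        assert [(iv.stage, iv.start, iv.end) for iv in seg1.intervals] == \
               [(iv.stage, iv.start, iv.end) for iv in seg2.intervals]


class TestStageDurations:
    def test_exact_48h_interval(self):
        seg = vt.StageSegmentation("x", [vt.segmentation.StageInterval(
            "dependence", pd.Timestamp("2021-07-28"), pd.Timestamp("2021-07-30"))])
        assert vt.stage_durations_days(seg)["dependence"] == 2.0

    def test_date_arithmetic(self):
        seg = vt.StageSegmentation("x", [vt.segmentation.StageInterval(
            "dependence", pd.Timestamp("2021-07-28"), pd.Timestamp("2021-08-17"))])
        assert vt.stage_durations_days(seg)["dependence"] == 20.0

    def test_durations_sum_to_observed_span(self, small_cohort_clean):
        _, clean, segs, _ = small_cohort_clean
        for traj, seg in zip(clean, segs):
            if not seg.intervals:
                continue
            total = sum(vt.stage_durations_days(seg).values())
            span = (seg.intervals[-1].end - seg.intervals[0].start
                    ).total_seconds() / 86400
            assert total == pytest.approx(span, abs=1e-9)

    def test_truncation_clips_at_instant(self):
        iv = vt.segmentation.StageInterval
        seg = vt.StageSegmentation("x", [
            iv("dependence", pd.Timestamp("2021-07-01"), pd.Timestamp("2021-07-20")),
            iv("residency", pd.Timestamp("2021-07-20"), pd.Timestamp("2021-09-01"))])
        cut = vt.truncate_segmentation(seg, pd.Timestamp("2021-08-01"))
        assert len(cut.intervals) == 2
        assert cut.intervals[-1].end == pd.Timestamp("2021-08-01")
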