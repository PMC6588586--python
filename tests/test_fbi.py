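import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fbindex import (BaselineProfile, DegenerateBaselineError, FBIMonitor,
                     HEALTHY, MinuteRecord, categorize, compute_baseline,
                     fbi_score, minute_records, score_records, simulate,
                     zone_sequence)
from fbindex.fbi import CATEGORIES
from fbindex.trajectory_io import INVALID

from conftest import make_traj

CONST = BaselineProfile(a0={w: 50.0 for w in (1, 10, 20, 30)},
                        d0={w: 40.0 * w for w in (1, 10, 20, 30)})


def const_record(minute, activity=50.0, distance=40.0, low=False):
    return MinuteRecord(minute=minute, zones=frozenset(), activity_pct=activity,
                        distance_cm=distance, valid_fraction=0.0 if low else 1.0,
                        low_coverage=low)


class TestZones:
    def test_corner_cell_is_zone_one(self):
        traj = make_traj([[5, 0.1, 0.1]] * 3)
        assert zone_sequence(traj)[0] == 1

    def test_boundary_goes_to_higher_section(self):
        traj = make_traj([[5, 10.0, 0.1]] * 3)  # y exactly on the first third edge
        assert zone_sequence(traj)[0] == 2

    def test_sweep_covers_all_nine(self):
        ys = np.tile([5, 15, 25], 3).astype(float)
        zs = np.repeat([3, 10, 17], 3).astype(float)
        traj = make_traj(np.column_stack([np.full(9, 5.0), ys, zs]))
        assert set(zone_sequence(traj)) == set(range(1, 10))

    def test_invalid_maps_to_none(self):
        traj = make_traj([[5, 5, 5]] * 3, valid=[1, 0, 1])
        assert zone_sequence(traj)[1] == 0

    def test_2d_uses_width_axis(self):
        traj = make_traj([[19.0, 19.0]] * 3)  # top-right of the 20 x 20 side plane
        assert zone_sequence(traj)[0] == 9


class TestMinuteRecords:
    def test_single_zone_minute_with_30cm(self):
        # 61 samples at 1 Hz oscillating 0.5 cm inside zone 5 (centre cell)
        n = 61
        x = 10.0 + 0.25 * np.where(np.arange(n) % 2 == 0, -1, 1)
        pos = np.column_stack([x, np.full(n, 15.0), np.full(n, 10.0)])
        recs = minute_records(make_traj(pos, dt=1.0))
        assert len(recs) == 1
        assert recs[0].zones == frozenset({5})
        assert recs[0].activity_pct == pytest.approx(100.0 / 9)
        assert recs[0].distance_cm == pytest.approx(30.0)

    def test_full_occupancy_minute(self):
        ys = np.resize([5.0, 15.0, 25.0], 61)
        zs = np.resize([3.0, 10.0, 17.0, 3.0, 10.0], 61)
        pos = np.column_stack([np.full(61, 5.0), ys, zs])
        recs = minute_records(make_traj(pos, dt=1.0))
        assert recs[0].activity_pct == 100.0

    def test_fully_invalid_minute_flagged(self):
        pos = np.tile([[5.0, 5.0, 5.0]], (121, 1))
        valid = np.ones(121, dtype=np.uint8)
        valid[60:120] = INVALID
        recs = minute_records(make_traj(pos, dt=1.0, valid=valid))
        assert recs[1].low_coverage and recs[1].distance_cm == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="minute"):
            minute_records(make_traj(np.tile([[5.0, 5, 5]], (30, 1)), dt=1.0))

    def test_activity_quantized_in_ninths(self):
        traj = simulate(HEALTHY, 300, 25, seed=4)
        for rec in minute_records(traj):
            steps = rec.activity_pct / (100.0 / 9)
            assert steps == pytest.approx(round(steps), abs=1e-9)


class TestBaseline:
    def test_constant_baseline_means(self):
        recs = [const_record(m, 55.6, 40.0) for m in range(25)]
        base = compute_baseline(recs, windows=(1, 10))
        assert base.a0[10] == pytest.approx(55.6)
        assert base.d0[10] == pytest.approx(400.0)

    def test_short_baseline_falls_back_with_warning(self):
        recs = [const_record(m, 55.6, 40.0) for m in range(25)]
        with pytest.warns(UserWarning, match="shorter than"):
            base = compute_baseline(recs, windows=(1, 30))
        assert base.fallback[30] == 25
        assert base.d0[30] == pytest.approx(40.0 * 30)  # scaled to 30-min equivalent

    def test_never_moving_fish_rejected(self):
        recs = [const_record(m, 0.0, 0.0) for m in range(10)]
        with pytest.raises(DegenerateBaselineError):
            compute_baseline(recs, windows=(1, 10))


class TestScore:
    def test_matching_baseline_scores_six(self):
        assert fbi_score(50.0, 400.0, 50.0, 400.0)[2] == 6.0

    def test_half_activity(self):
        sub_a, sub_d, score = fbi_score(25.0, 400.0, 50.0, 400.0, dev_max=1.0)
        assert (sub_a, sub_d, score) == pytest.approx((1.5, 3.0, 4.5))

    def test_zero_everything(self):
        assert fbi_score(0.0, 0.0, 50.0, 400.0)[2] == 0.0

    def test_hyperactivity_also_penalised(self):
        _, sub_d, score = fbi_score(50.0, 800.0, 50.0, 400.0, dev_max=1.0)
        assert sub_d == 0.0 and score == pytest.approx(3.0)

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            fbi_score(50.0, 400.0, 0.0, 400.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(0, 200), d=st.floats(0, 2000), worse=st.floats(0.01, 2.0))
    def test_monotone_in_deviation(self, a, d, worse):
        base_a, base_d = 50.0, 400.0
        s1 = fbi_score(a, d, base_a, base_d)[2]
        # push activity strictly farther from baseline, keep distance fixed
        a2 = a + worse * (1 if a >= base_a else -1)
        s2 = fbi_score(max(a2, -1e9), d, base_a, base_d)[2]
        assert s2 <= s1 + 1e-12
        assert 0.0 <= s1 <= 6.0


class TestCategorize:
    @pytest.mark.parametrize("score,normalized,category", [
        (6.0, 1.00, "Healthy"),
        (5.0, 0.83, "Ok"),
        (4.5, 0.75, "Ok"),
        (4.0, 0.67, "Unhealthy"),
        (2.0, 0.33, "Abnormal"),
        (0.0, 0.00, "Abnormal"),
    ])
    def test_category_table(self, score, normalized, category):
        norm, cat = categorize(score)
        assert norm == pytest.approx(normalized, abs=1e-12)
        assert cat == category

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 6.1):
            with pytest.raises(ValueError):
                categorize(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(s1=st.floats(0, 6), s2=st.floats(0, 6))
    def test_category_monotone_and_consistent(self, s1, s2):
        n1, c1 = categorize(s1)
        n2, c2 = categorize(s2)
        if s1 <= s2:
            assert CATEGORIES.index(c1) <= CATEGORIES.index(c2)
        assert n1 == pytest.approx(round(s1 / 6.0 + 1e-12, 2), abs=5e-3)


class TestStreaming:
    def test_steady_state_all_healthy(self):
        monitor = FBIMonitor(CONST)
        for m in range(30):
            readings = monitor.update(const_record(m))
        assert all(r.score == 6.0 and r.category == "Healthy" for r in readings)

    def test_single_bad_minute_recovers_over_ten(self):
        monitor = FBIMonitor(CONST)
        first = monitor.update(const_record(0, activity=0.0, distance=0.0))
        one_min = {r.window_min: r for r in first}[1]
        assert one_min.category == "Abnormal" and one_min.score == 0.0
        for m in range(1, 10):
            readings = monitor.update(const_record(m))
        ten = {r.window_min: r for r in readings}[10]
        # window mean: 9 normal minutes + 1 silent minute -> 10% deviation
        assert ten.score == pytest.approx(5.4)
        assert ten.category == "Healthy" and not ten.partial

    def test_ten_zero_minutes_fire_alert(self):
        monitor = FBIMonitor(CONST)
        for m in range(10):
            readings = monitor.update(const_record(m, activity=0.0, distance=0.0))
        ten = {r.window_min: r for r in readings}[10]
        assert ten.alert and ten.category == "Abnormal"
        # partial windows never alert
        monitor2 = FBIMonitor(CONST)
        partial = monitor2.update(const_record(0, activity=0.0, distance=0.0))
        assert not any(r.alert for r in partial)

    def test_update_requires_baseline_windows(self):
        with pytest.raises(ValueError, match="lacks windows"):
            FBIMonitor(BaselineProfile(a0={1: 50.0}, d0={1: 40.0}))

    def test_streaming_equals_batch(self):
        traj = simulate(HEALTHY, 3600, 25, seed=21)
        records = list(minute_records(traj))
        # inject artificial low-coverage minutes to exercise exclusion
        for i in (5, 6, 7, 8, 9, 10, 40):
            r = records[i]
            records[i] = MinuteRecord(r.minute, r.zones, r.activity_pct,
                                      r.distance_cm, 0.2, True)
        base = compute_baseline(records[:25])
        monitor = FBIMonitor(base)
        streamed = [monitor.update(r) for r in records]
        batched = score_records(records, base)
        for row_s, row_b in zip(streamed, batched):
            for rs, rb in zip(row_s, row_b):
                assert rs == rb

    def test_mostly_missing_window_gives_no_reading(self):
        monitor = FBIMonitor(CONST)
        for m in range(10):
            readings = monitor.update(const_record(m, low=True))
        assert all(r.no_data for r in readings)


class TestBaselineSelfConsistency:
    def test_constant_series_scores_exactly_six(self):
        recs = [const_record(m) for m in range(40)]
        base = compute_baseline(recs)
        for row in score_records(recs, base):
            for r in row:
                if not r.partial:
                    assert r.score == 6.0

    def test_normalized_times_six_is_score(self):
        traj = simulate(HEALTHY, 1500, 25, seed=2)
        recs = minute_records(traj)
        base = compute_baseline(recs)
        for row in score_records(recs, base):
            for r in row:
                if not r.no_data:
                    assert 0.0 <= r.score <= 6.0
                    assert r.score == r.sub_score_activity + r.sub_score_distance
                    assert abs(r.normalized - r.score / 6.0) <= 5e-3 + 1e-12
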