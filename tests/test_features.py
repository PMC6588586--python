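import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fbindex import (FEATURE_NAMES, FeatureConfig, InsufficientDataError,
                     TankGeometry, extract_features, kinematics)
from fbindex.trajectory_io import INVALID, OBSERVED

from conftest import make_traj, random_segment
from naive_features import naive_features

RELAXED = FeatureConfig(min_valid_s=1.0)


class TestKinematics:
    def test_uniform_straight_motion(self):
        # 1 cm per 0.2 s step along x at mid-height
        pos = np.column_stack([np.arange(15.0), np.full(15, 15.0), np.full(15, 10.0)])
        kin = kinematics(make_traj(pos, dt=0.2))
        np.testing.assert_allclose(kin.speed, 5.0)
        np.testing.assert_allclose(kin.accel, 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.turn_deg, 0.0, atol=1e-6)

    def test_right_angle_corner(self):
        pos = [[1, 1, 10], [2, 1, 10], [2, 2, 10]]
        kin = kinematics(make_traj(pos))
        assert kin.turn_deg[0] == pytest.approx(90.0)

    def test_finite_difference_accel(self):
        # step lengths 2, 4, 6 cm at dt = 1 s -> speeds (2, 4, 6), accels (2, 2)
        pos = np.array([[0, 1, 10], [2, 1, 10], [6, 1, 10], [12, 1, 10]], dtype=float)
        kin = kinematics(make_traj(pos, dt=1.0, geometry=TankGeometry(20, 30, 20)))
        np.testing.assert_allclose(kin.speed, [2, 4, 6])
        np.testing.assert_allclose(kin.accel, [2, 2])

    def test_intervals_touching_invalid_excluded(self):
        pos = np.tile([[5.0, 5.0, 5.0]], (6, 1))
        valid = np.array([1, 1, 1, 0, 1, 1], dtype=np.uint8)
        kin = kinematics(make_traj(pos, valid=valid))
        assert not kin.step_valid[2] and not kin.step_valid[3]
        assert not kin.accel_valid[1] and not kin.accel_valid[2] and not kin.accel_valid[3]

    def test_needs_three_consecutive_valid(self):
        pos = np.tile([[5.0, 5.0, 5.0]], (6, 1))
        valid = np.array([1, 1, 0, 1, 1, 0], dtype=np.uint8)
        with pytest.raises(InsufficientDataError):
            kinematics(make_traj(pos, valid=valid))


class TestExtractFeatures:
    def test_stationary_fish(self):
        pos = np.tile([[10.0, 15.0, 10.0]], (3001, 1))  # 10 min at 5 Hz
        fv = extract_features(make_traj(pos, dt=0.2))
        assert fv.total_distance == 0.0
        assert fv.pct_active == 0.0
        assert fv.avg_turns_per_min == 0.0
        assert fv.pct_tank_explored == pytest.approx(100.0 / 1000)

    def test_bottom_dweller_one_sided(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform([1, 1, 1], [19, 29, 8], size=(400, 3))  # always below z=10
        fv = extract_features(make_traj(pos, dt=0.2), RELAXED)
        assert fv.pct_time_bottom == 100.0
        assert fv.distance_top == 0.0
        assert fv.avg_speed_top == 0.0
        assert "empty-half:top" in fv.flags

    def test_total_distance_brute_force(self):
        rng = np.random.default_rng(11)
        pos = np.cumsum(rng.normal(0, 0.3, size=(600, 3)), axis=0) + 10.0
        traj = make_traj(np.clip(pos, 0, 19.9), dt=0.2)
        fv = extract_features(traj, RELAXED)
        brute = sum(float(np.linalg.norm(traj.positions[i + 1] - traj.positions[i]))
                    for i in range(599))
        assert fv.total_distance == pytest.approx(brute, rel=1e-9)

    def test_insufficient_data_is_explicit(self):
        pos = np.tile([[5.0, 5.0, 5.0]], (30, 1))
        with pytest.raises(InsufficientDataError, match="valid data"):
            extract_features(make_traj(pos, dt=0.2))  # only ~6 s

    def test_twenty_named_characteristics(self):
        assert len(FEATURE_NAMES) == 20
        rng = np.random.default_rng(0)
        fv = extract_features(random_segment(rng, min_samples=800), RELAXED)
        assert set(fv.to_dict()) == set(FEATURE_NAMES)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            traj = random_segment(rng)
            fv = extract_features(traj, RELAXED).to_dict()
            expected = naive_features(traj, RELAXED)
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(expected[name], rel=1e-9, abs=1e-9), name


class TestProperties:
    def test_distance_additive_over_partition(self):
        rng = np.random.default_rng(5)
        traj = random_segment(rng, min_samples=600)
        full = extract_features(traj, RELAXED)
        b = len(traj) // 2
        parts = []
        for sl in (slice(0, b + 1), slice(b, None)):  # share the boundary sample
            parts.append(extract_features(type(traj)(
                t=traj.t[sl] - traj.t[sl][0], x=traj.x[sl],
                y=traj.y[sl] if traj.y is not None else None, z=traj.z[sl],
                valid=traj.valid[sl], geometry=traj.geometry), RELAXED))
        assert full.total_distance == pytest.approx(
            parts[0].total_distance + parts[1].total_distance, rel=1e-9)
        # duration-weighted mean of window averages
        w_avg = (sum(p.avg_speed * p.valid_time_s for p in parts)
                 / sum(p.valid_time_s for p in parts))
        assert full.avg_speed == pytest.approx(w_avg, rel=1e-9)
        # turn counts additive up to the two boundary intervals
        count = lambda p: p.avg_turns_per_min * p.valid_time_s / 60.0
        assert abs(count(full) - count(parts[0]) - count(parts[1])) <= 2 + 1e-6

    @pytest.mark.parametrize("k", [0.37, 2.5])
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(8)
        traj = random_segment(rng, min_samples=500)
        g = traj.geometry
        scaled = type(traj)(
            t=traj.t, x=traj.x * k, y=traj.y * k if traj.y is not None else None,
            z=traj.z * k, valid=traj.valid,
            geometry=TankGeometry(g.width_cm * k, g.depth_cm * k, g.height_cm * k))
        cfg_k = FeatureConfig(min_valid_s=1.0,
                              active_speed_cms=RELAXED.active_speed_cms * k,
                              fast_speed_cms=RELAXED.fast_speed_cms * k)
        a = extract_features(traj, RELAXED).to_dict()
        b = extract_features(scaled, cfg_k).to_dict()
        scaling = {"total_distance": k, "distance_top": k, "distance_bottom": k,
                   "avg_speed": k, "avg_speed_top": k, "avg_speed_bottom": k,
                   "max_speed_top": k, "max_speed_bottom": k, "avg_accel": k,
                   "avg_decel": k, "avg_accel_top": k, "avg_accel_bottom": k,
                   "max_accel_top": k, "max_accel_bottom": k}
        for name in FEATURE_NAMES:
            assert b[name] == pytest.approx(a[name] * scaling.get(name, 1.0),
                                            rel=1e-9, abs=1e-9), name

    def test_time_reversal(self):
        rng = np.random.default_rng(9)
        traj = random_segment(rng, min_samples=400)
        rev = type(traj)(t=traj.t, x=traj.x[::-1].copy(),
                         y=traj.y[::-1].copy() if traj.y is not None else None,
                         z=traj.z[::-1].copy(), valid=traj.valid[::-1].copy(),
                         geometry=traj.geometry)
        a = extract_features(traj, RELAXED)
        b = extract_features(rev, RELAXED)
        assert a.total_distance == pytest.approx(b.total_distance, rel=1e-9)
        assert a.avg_turns_per_min == pytest.approx(b.avg_turns_per_min, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariants_hold_on_random_segments(self, seed):
        rng = np.random.default_rng(seed)
        fv = extract_features(random_segment(rng, max_samples=400), RELAXED)
        d = fv.to_dict()
        for name in ("pct_active", "pct_fast_sharp_moves", "pct_time_bottom",
                     "pct_tank_explored", "pct_time_near_walls"):
            assert 0.0 <= d[name] <= 100.0
        assert d["total_distance"] == pytest.approx(
            d["distance_top"] + d["distance_bottom"], rel=1e-12, abs=1e-12)
        assert d["max_speed_top"] >= d["avg_speed_top"] or "empty-half:top" in fv.flags
        assert d["max_speed_bottom"] >= d["avg_speed_bottom"] or "empty-half:bottom" in fv.flags
        assert d["avg_decel"] >= 0.0
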