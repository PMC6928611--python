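"""Projection and movement-metric geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grazetrack as gt
from grazetrack.geo import CrossZoneError, UnsupportedLatitudeError
from tests.conftest import straight_trajectory


class TestUtm:
    def test_central_meridian_equator_is_false_easting(self):
        p = gt.to_utm(0.0, 3.0)  # central meridian of zone 31
        assert p.zone == 31
        assert p.easting == pytest.approx(500_000.0, abs=1e-6)
        assert p.northing == pytest.approx(0.0, abs=1e-6)

    def test_study_site_zone(self):
        # 42°55'N 120°42'E falls in zone 51 (floor(lon/6)+31)
        assert gt.utm_zone(120.7) == 51
        assert gt.to_utm(42.9167, 120.7).zone == 51

    @given(
        lat=st.floats(-80, 80),
        lon=st.floats(-179.9, 179.9),
    )
    def test_round_trip(self, lat, lon):
        p = gt.to_utm(lat, lon)
        lat2, lon2 = gt.from_utm(p.easting, p.northing, p.zone, p.hemisphere)
        assert abs(lat2 - lat) < 1e-6
        assert abs(lon2 - lon) < 1e-6

    def test_polar_latitudes_rejected(self):
        with pytest.raises(UnsupportedLatitudeError):
            gt.to_utm(86.0, 10.0)

    def test_projected_distance_matches_meridian_arc(self):
        # 0.01 deg of latitude at 45N is ~1111.3 m of meridian arc;
        # on the central meridian the projection scales it by 0.9996
        a = gt.to_utm(45.0, 3.0)
        b = gt.to_utm(45.01, 3.0)
        assert gt.linear_distance(a, b) == pytest.approx(1111.3 * 0.9996, rel=2e-4)


class TestLinearDistance:
    def test_identity_and_pythagoras(self):
        p = gt.UtmPoint(500_000.0, 4_000_000.0, 51, "N")
        q = gt.UtmPoint(500_003.0, 4_000_004.0, 51, "N")
        assert gt.linear_distance(p, p) == 0.0
        assert gt.linear_distance(p, q) == pytest.approx(5.0)
        assert gt.linear_distance(q, p) == pytest.approx(5.0)

    def test_cross_zone_rejected(self):
        p = gt.UtmPoint(500_000.0, 0.0, 31, "N")
        q = gt.UtmPoint(500_000.0, 0.0, 32, "N")
        with pytest.raises(CrossZoneError):
            gt.linear_distance(p, q)

    def test_matches_hypot_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            e1, e2 = rng.uniform(1e5, 9e5, 2)
            n1, n2 = rng.uniform(0, 9e6, 2)
            p = gt.UtmPoint(e1, n1, 51, "N")
            q = gt.UtmPoint(e2, n2, 51, "N")
            expected = math.hypot(e2 - e1, n2 - n1)
            assert gt.linear_distance(p, q) == pytest.approx(expected, rel=1e-9)


def random_trajectory(seed, n=60):
    rng = np.random.default_rng(seed)
    ts = pd.date_range("2018-09-23 09:00:00", periods=n, freq="50s", tz="UTC")
    return gt.Trajectory(
        animal_id="r",
        timestamps=ts,
        easting=500_000.0 + np.cumsum(rng.normal(0, 12, n)),
        northing=4_000_000.0 + np.cumsum(rng.normal(0, 12, n)),
        zone=51,
        hemisphere="N",
        segment_ids=np.zeros(n, dtype=int),
    )


class TestAccumulativeDistance:
    def test_lag_one_equals_linear(self, straight_traj):
        assert gt.accumulative_distance(straight_traj, 5, 1, "backward") == pytest.approx(
            gt.focal_lag_distance(straight_traj, 5, 1, "backward")
        )

    def test_collinear_equals_linear(self, straight_traj):
        # equal 10-m collinear steps: path length = straight-line length
        assert gt.accumulative_distance(straight_traj, 10, 3, "backward") == pytest.approx(30.0)
        assert gt.focal_lag_distance(straight_traj, 10, 3, "backward") == pytest.approx(30.0)

    def test_brute_force_oracle(self):
        traj = random_trajectory(3)
        for i in range(2, 17):
            focal = 30
            expected = sum(
                math.hypot(
                    traj.easting[k + 1] - traj.easting[k],
                    traj.northing[k + 1] - traj.northing[k],
                )
                for k in range(focal - i, focal)
            )
            got = gt.accumulative_distance(traj, focal, i, "backward")
            assert got == pytest.approx(expected, rel=1e-9)
            expected_f = sum(
                math.hypot(
                    traj.easting[k + 1] - traj.easting[k],
                    traj.northing[k + 1] - traj.northing[k],
                )
                for k in range(focal, focal + i)
            )
            assert gt.accumulative_distance(traj, focal, i, "forward") == pytest.approx(
                expected_f, rel=1e-9
            )

    def test_window_outside_segment_is_missing(self, straight_traj):
        assert math.isnan(gt.accumulative_distance(straight_traj, 2, 5, "backward"))


class TestTurningAngle:
    def test_straight_continuation_is_zero(self, straight_traj):
        assert gt.turning_angle(straight_traj, 10, 1) == pytest.approx(0.0, abs=1e-9)

    def test_reversal_is_180(self):
        ts = pd.date_range("2018-09-23", periods=3, freq="50s", tz="UTC")
        traj = gt.Trajectory(
            animal_id="x", timestamps=ts,
            easting=np.array([0.0, 10.0, 0.0]) + 5e5,
            northing=np.full(3, 4e6),
            zone=51, hemisphere="N", segment_ids=np.zeros(3, dtype=int),
        )
        assert gt.turning_angle(traj, 1, 1) == pytest.approx(180.0)

    def test_right_angle_corner(self):
        ts = pd.date_range("2018-09-23", periods=3, freq="50s", tz="UTC")
        traj = gt.Trajectory(
            animal_id="x", timestamps=ts,
            easting=np.array([0.0, 10.0, 10.0]) + 5e5,
            northing=np.array([0.0, 0.0, 10.0]) + 4e6,
            zone=51, hemisphere="N", segment_ids=np.zeros(3, dtype=int),
        )
        assert gt.turning_angle(traj, 1, 1) == pytest.approx(90.0)

    def test_zero_length_vector_is_missing(self):
        ts = pd.date_range("2018-09-23", periods=3, freq="50s", tz="UTC")
        traj = gt.Trajectory(
            animal_id="x", timestamps=ts,
            easting=np.array([0.0, 0.0, 10.0]) + 5e5,
            northing=np.full(3, 4e6),
            zone=51, hemisphere="N", segment_ids=np.zeros(3, dtype=int),
        )
        assert math.isnan(gt.turning_angle(traj, 1, 1))


class TestFeatureTable:
    def test_distance_census_at_full_window(self):
        # 32 focal-lag linear + 30 one-step segment = 62 linear distances,
        # plus 30 accumulative = 92 distance metrics at the 800-s window
        assert gt.distance_metric_census(16) == 92

    def test_straight_segment_fully_populated(self):
        traj = straight_trajectory(n=33)
        feats = gt.build_gps_features(traj)
        mid = feats.iloc[16]
        metric_cols = gt.gps_feature_columns(16)
        assert not mid[metric_cols].isna().any()
        angles = [mid[f"angle_{i}"] for i in range(1, 17)]
        assert np.allclose(angles, 0.0, atol=1e-9)

    def test_stationary_track_zero_distances_missing_angles(self):
        ts = pd.date_range("2018-09-23", periods=40, freq="50s", tz="UTC")
        traj = gt.Trajectory(
            animal_id="s", timestamps=ts,
            easting=np.full(40, 5e5), northing=np.full(40, 4e6),
            zone=51, hemisphere="N", segment_ids=np.zeros(40, dtype=int),
        )
        feats = gt.build_gps_features(traj)
        mid = feats.iloc[20]
        assert mid[[f"blin_{i}" for i in range(1, 17)]].eq(0).all()
        assert mid[[f"bacc_{i}" for i in range(2, 17)]].eq(0).all()
        assert mid[[f"angle_{i}" for i in range(1, 17)]].isna().all()

    def test_matches_scalar_operations(self):
        traj = random_trajectory(9)
        feats = gt.build_gps_features(traj)
        focal = 25
        for i in (1, 4, 16):
            assert feats.loc[focal, f"blin_{i}"] == pytest.approx(
                gt.focal_lag_distance(traj, focal, i, "backward"), rel=1e-12
            )
            assert feats.loc[focal, f"flin_{i}"] == pytest.approx(
                gt.focal_lag_distance(traj, focal, i, "forward"), rel=1e-12
            )
            assert feats.loc[focal, f"angle_{i}"] == pytest.approx(
                gt.turning_angle(traj, focal, i), rel=1e-12
            )
        for i in (2, 7, 16):
            assert feats.loc[focal, f"bacc_{i}"] == pytest.approx(
                gt.accumulative_distance(traj, focal, i, "backward"), rel=1e-12
            )

    @given(seed=st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        feats = gt.build_gps_features(random_trajectory(seed, n=40))
        for i in (2, 6, 16):
            both = feats[[f"bacc_{i}", f"blin_{i}"]].dropna()
            assert (both[f"bacc_{i}"] >= both[f"blin_{i}"] - 1e-9).all()
            both = feats[[f"facc_{i}", f"flin_{i}"]].dropna()
            assert (both[f"facc_{i}"] >= both[f"flin_{i}"] - 1e-9).all()

    def test_accumulative_is_sum_of_segments(self):
        feats = gt.build_gps_features(random_trajectory(4, n=50))
        row = feats.iloc[25]
        for i in (2, 5, 16):
            assert row[f"bacc_{i}"] == pytest.approx(
                sum(row[f"seg_b_{j}"] for j in range(1, i + 1)), rel=1e-12
            )
        assert row["blin_1"] == pytest.approx(row["seg_b_1"])
        assert row["flin_1"] == pytest.approx(row["seg_f_1"])

    def test_time_reversal_swaps_directions(self):
        traj = random_trajectory(11, n=41)
        rev = gt.Trajectory(
            animal_id="r", timestamps=traj.timestamps,
            easting=traj.easting[::-1].copy(), northing=traj.northing[::-1].copy(),
            zone=51, hemisphere="N", segment_ids=np.zeros(41, dtype=int),
        )
        f = gt.build_gps_features(traj)
        g = gt.build_gps_features(rev)
        focal, rfocal = 20, 20  # center maps to itself
        for i in (1, 3, 16):
            assert f.loc[focal, f"blin_{i}"] == pytest.approx(g.loc[rfocal, f"flin_{i}"])
            assert f.loc[focal, f"seg_b_{i}"] == pytest.approx(g.loc[rfocal, f"seg_f_{i}"])
            assert f.loc[focal, f"angle_{i}"] == pytest.approx(g.loc[rfocal, f"angle_{i}"])
        for i in (2, 16):
            assert f.loc[focal, f"bacc_{i}"] == pytest.approx(g.loc[rfocal, f"facc_{i}"])

    def test_rigid_motion_invariance(self):
        traj = random_trajectory(17, n=40)
        theta = 0.7
        c, s = math.cos(theta), math.sin(theta)
        e = traj.easting - 5e5
        n = traj.northing - 4e6
        moved = gt.Trajectory(
            animal_id="m", timestamps=traj.timestamps,
            easting=5e5 + 120.0 + c * e - s * n,
            northing=4e6 - 40.0 + s * e + c * n,
            zone=51, hemisphere="N", segment_ids=traj.segment_ids,
        )
        f = gt.build_gps_features(traj)
        g = gt.build_gps_features(moved)
        cols = gt.gps_feature_columns(16)
        pd.testing.assert_frame_equal(f[cols], g[cols], atol=1e-7, rtol=1e-9)

    def test_metrics_never_span_segments(self):
        traj = random_trajectory(5, n=30)
        traj.segment_ids[15:] = 1
        feats = gt.build_gps_features(traj)
        # last fix of segment 0: no forward metrics at any lag
        assert feats.loc[14, [f"flin_{i}" for i in range(1, 17)]].isna().all()
        # first fix of segment 1: no backward metrics
        assert feats.loc[15, [f"blin_{i}" for i in range(1, 17)]].isna().all()

    def test_model_column_counts_per_interval(self):
        # T=800 has the 92 distance metrics + 16 angles
        assert len(gt.model_columns_for_interval(800)) == 108
        assert len(gt.model_columns_for_interval(800, include_angles=False)) == 92
        # T=100 (lag 2): blin/flin 1-2, seg 2, bacc/facc 2, angle 1-2
        assert len(gt.model_columns_for_interval(100)) == 10

    def test_d_index_lookup(self):
        assert gt.D_INDEX_TABLE["d19"] == "blin_6"
        assert gt.D_INDEX_TABLE["d43"] == "blin_7"
        assert gt.D_INDEX_TABLE["d20"] == "bacc_4"
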