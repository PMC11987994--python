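from datetime import datetime, timedelta

import numpy as np
import pytest

import fishtrack3d as ft

T0 = datetime(2024, 6, 1, 9, 0, 0)


def track_from_positions(pos, dt=1.0, sources=None):
    pos = np.asarray(pos, dtype=float)
    return [ft.TrackPoint3D(timestamp=T0 + timedelta(seconds=i * dt),
                            t_s=i * dt, x_mm=p[0], y_mm=p[1], z_mm=p[2],
                            x_delta_mm=0.0,
                            source=(sources[i] if sources else "fused"))
            for i, p in enumerate(pos)]


class TestStepSpeeds:
    def test_stationary_track_all_zero(self):
        track = track_from_positions([[10, 10, 10]] * 5)
        s = ft.step_speeds(track)
        assert np.all(s.speed_mm_s == 0)
        assert len(s.speed_mm_s) == 5

    def test_345_displacement_gives_5(self):
        track = track_from_positions([[0, 0, 0], [3, 4, 0]])
        s = ft.step_speeds(track)
        assert s.speed_mm_s[0] == 0.0
        assert s.speed_mm_s[1] == pytest.approx(5.0)

    def test_constant_velocity_track(self):
        pos = [[10 * i, 0, 0] for i in range(20)]
        s = ft.step_speeds(track_from_positions(pos))
        assert s.speed_mm_s[0] == 0.0
        assert np.allclose(s.speed_mm_s[1:], 10.0)

    def test_non_monotone_time_rejected(self):
        track = track_from_positions([[0, 0, 0], [1, 1, 1]])
        track[1] = ft.TrackPoint3D(timestamp=T0, t_s=0.0, x_mm=1, y_mm=1,
                                   z_mm=1, x_delta_mm=0, source="fused")
        with pytest.raises(ValueError):
            ft.step_speeds(track)


class TestTotalDistance:
    def test_zero_series(self):
        s = ft.step_speeds(track_from_positions([[0, 0, 0]] * 10))
        assert ft.total_distance(s) == 0.0

    def test_ten_hour_experiment_at_table_speed(self):
        # 36,000 samples at a constant 92.13 mm/s integrate to 3,316.68 m,
        # the scale of the reported control-group swim distance
        s = ft.SpeedSeries(t_s=np.arange(36000, dtype=float),
                           speed_mm_s=np.full(36000, 92.13))
        s.speed_mm_s[0] = 0.0
        assert ft.total_distance(s) == pytest.approx(92.13 * 35999)
        assert ft.total_distance(s) / 1000.0 == pytest.approx(3316.68,
                                                              abs=0.2)

    def test_concatenation_additivity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 50, 30)
        b = rng.uniform(0, 50, 40)
        a[0] = b[0] = 0

        def series(v, t0=0.0):
            return ft.SpeedSeries(t_s=t0 + np.arange(len(v), dtype=float),
                                  speed_mm_s=v)

        da = ft.total_distance(series(a))
        db = ft.total_distance(series(b))
        joint = ft.SpeedSeries(
            t_s=np.arange(len(a) + len(b), dtype=float),
            speed_mm_s=np.concatenate([a, b]))
        # joining adds one connecting step of speed b[0] = 0
        assert da + db == pytest.approx(ft.total_distance(joint))


class TestWindowMeans:
    def test_ten_hour_series_gives_3600_windows(self):
        s = ft.SpeedSeries(t_s=np.arange(36000, dtype=float),
                           speed_mm_s=np.zeros(36000))
        w = ft.window_means(s, 10.0)
        assert len(w.means) == 3600

    def test_trailing_partial_window_dropped(self):
        s = ft.SpeedSeries(t_s=np.arange(25, dtype=float),
                           speed_mm_s=np.arange(25, dtype=float))
        w = ft.window_means(s, 10.0)
        assert len(w.means) == 2
        assert w.means[0] == pytest.approx(np.mean(np.arange(10)))

    def test_constant_series_gives_constant_means(self):
        s = ft.SpeedSeries(t_s=np.arange(40, dtype=float),
                           speed_mm_s=np.full(40, 7.5))
        assert np.allclose(ft.window_means(s, 10.0).means, 7.5)

    def test_window_must_be_multiple_of_dt(self):
        s = ft.SpeedSeries(t_s=np.arange(10, dtype=float),
                           speed_mm_s=np.zeros(10))
        with pytest.raises(ValueError):
            ft.window_means(s, 2.5)
        with pytest.raises(ValueError):
            ft.window_means(ft.SpeedSeries(t_s=s.t_s, speed_mm_s=s.speed_mm_s,
                                           dt_s=3.0), 10.0)

    def test_mean_of_window_means_equals_series_mean(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 100, 500)
        s = ft.SpeedSeries(t_s=np.arange(500, dtype=float), speed_mm_s=v)
        w = ft.window_means(s, 10.0)
        assert np.mean(w.means) == pytest.approx(np.mean(v), abs=1e-9)


class TestOccupancy:
    def test_single_corner_occupies_one_bin(self, geom):
        track = track_from_positions([[5, 5, 5]] * 20)
        grid = ft.occupancy(track, geom)
        assert (grid.counts > 0).sum() == 1
        assert grid.counts[0, 0, 0] == 20

    def test_counts_conserved_over_full_track(self, geom):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 1, (500, 3)) * np.array(geom.extents_xyz)
        grid = ft.occupancy(track_from_positions(pos), geom)
        assert grid.counts.sum() == 500

    def test_uniform_positions_have_low_count_variation(self, geom):
        rng = np.random.default_rng(3)
        n = 100_000
        pos = rng.uniform(0, 1, (n, 3)) * np.array(geom.extents_xyz)
        grid = ft.occupancy(track_from_positions(pos), geom,
                            bins_per_axis=(4, 4, 4))
        cv = grid.counts.std() / grid.counts.mean()
        assert cv < 0.1

    def test_time_slice_selects_half_open_interval(self, geom):
        pos = [[100, 100, 100]] * 7300
        track = track_from_positions(pos)
        grid = ft.occupancy(track, geom, slice_hours=(0, 2))
        assert grid.counts.sum() == 7200
        assert grid.slice_label == "0-2h"

    def test_empty_slice_gives_empty_grid(self, geom):
        track = track_from_positions([[1, 1, 1]] * 10)
        grid = ft.occupancy(track, geom, slice_hours=(5, 7))
        assert grid.counts.sum() == 0


class TestRecoveryFromRendering:
    def test_total_distance_recovered_within_5pct(self, tracked_scene, geom):
        cal_f, cal_t = tracked_scene["cals"]
        match = ft.match_by_timestamp(tracked_scene["front_dets"],
                                      tracked_scene["top_dets"])
        track = ft.fuse_tracks(match, cal_f, cal_t, geom)
        recovered = ft.total_distance(ft.step_speeds(track))
        truth = tracked_scene["gt"].total_distance_mm
        assert recovered == pytest.approx(truth, rel=0.05)

    def test_subthreshold_motion_never_inflates_distance(self, geom,
                                                         small_scene,
                                                         small_params):
        # at ~1 px/frame displacement the motion gate suppresses detections;
        # recovered distance must then UNDER-estimate, never invent motion
        motion = ft.MotionConfig(duration_s=30, mean_speed_mm_s=1.0,
                                 speed_sd=0.3, seed=9)
        gt = ft.simulate_trajectory(motion, geom)
        front, top, ref_f, ref_t = ft.render_views(gt, small_scene, geom)
        cal_f, cal_t = small_scene.calibrations(geom)
        det_f = ft.process_sequence(front, ref_f, cal_f, small_params)
        det_t = ft.process_sequence(top, ref_t, cal_t, small_params)
        track = ft.fuse_tracks(ft.match_by_timestamp(det_f, det_t),
                               cal_f, cal_t, geom)
        recovered = ft.total_distance(ft.step_speeds(track))
        assert recovered <= gt.total_distance_mm + 1e-9
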