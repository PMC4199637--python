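"""Generators: deterministic limits, stationary occupancy, determinism."""

import io

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from embryoquant import synthetic as sy
from embryoquant.trafficking import step_displacements


class TestSimulateTrajectory:
    def test_never_pauses_limit(self):
        p = sy.MotionParams(pause_dwell_mean=0.0, run_speed=0.24,
                            frame_interval=5.0, pause_jitter_sd=0.0, n_frames=12)
        traj, states = sy.simulate_trajectory(p, 0)
        assert np.all(states == "run")
        assert step_displacements(traj).displacement_um == pytest.approx([1.2] * 11)

    def test_always_paused_limit(self):
        p = sy.MotionParams(run_dwell_mean=0.0, pause_jitter_sd=0.0, n_frames=12)
        traj, states = sy.simulate_trajectory(p, 0)
        assert np.all(states == "pause")
        assert step_displacements(traj).displacement_um == pytest.approx([0.0] * 11)

    def test_stationary_occupancy_monte_carlo(self):
        """Empirical pause occupancy matches pause/(pause+run) within ±0.05."""
        p = sy.MotionParams(run_dwell_mean=35.0, pause_dwell_mean=15.0, n_frames=200)
        assert sy.pause_occupancy(p) == pytest.approx(0.3)
        frac = np.mean([
            np.mean(sy.simulate_trajectory(p, seed)[1] == "pause")
            for seed in range(50)
        ])
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sy.MotionParams(run_speed=-1.0)
        with pytest.raises(ValueError):
            sy.MotionParams(frame_interval=0.0)
        with pytest.raises(ValueError):
            sy.MotionParams(n_frames=1)
        with pytest.raises(ValueError):
            sy.MotionParams(anterior_bias=1.5)

    def test_pure_function_of_seed(self):
        p = sy.MotionParams(n_frames=50)
        t1, s1 = sy.simulate_trajectory(p, 9)
        t2, s2 = sy.simulate_trajectory(p, 9)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(s1, s2)


class TestRenderTimelapse:
    def test_empty_scene_contains_only_background(self):
        scene = sy.SceneParams(n_puncta=0, noise_sd=0.0, seed=0)
        stack, truth = sy.render_timelapse([], scene)
        assert truth.empty
        assert stack.shape[0] == 1 and stack.max() > 0  # fiducials + axon

    def test_drift_translates_everything(self):
        from embryoquant.tracking import Trajectory
        still = Trajectory(0, np.arange(4), np.full(4, 100.0), np.full(4, 100.0),
                           0.2, 5.0)
        scene = sy.SceneParams(n_puncta=1, drift_per_frame=(1.0, 2.0),
                               noise_sd=0.0, seed=0, fiducial_positions=(),
                               axon_amplitude=0.0)
        stack, _ = sy.render_timelapse([still], scene)
        for k in range(4):
            py, px = np.unravel_index(np.argmax(stack[k]), stack[k].shape)
            assert (px, py) == (100 + k, 100 + 2 * k)

    def test_seed_determinism(self):
        motion = sy.MotionParams(n_frames=8)
        scene = sy.SceneParams(n_puncta=3, noise_sd=5.0, seed=21)
        s1, t1, _ = sy.simulate_timelapse(motion, scene, seed=2)
        s2, t2, _ = sy.simulate_timelapse(motion, scene, seed=2)
        assert np.array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)


class TestRenderCells:
    def test_zero_filopodia_iq_approaches_one_with_vertices(self):
        iqs = []
        for n_vertices in (8, 16, 64, 256):
            v = sy.star_polygon((0, 0), 30.0, 0, 0.0, n_body_vertices=n_vertices)
            poly = Polygon(v)
            iqs.append(4 * np.pi * poly.area / poly.length ** 2)
        assert all(b > a for a, b in zip(iqs, iqs[1:]))
        assert iqs[-1] == pytest.approx(1.0, abs=1e-3)

    def test_more_filopodia_lower_analytic_iq(self):
        iqs = []
        for nf in (0, 2, 4, 8, 12):
            _, truth, _ = sy.render_cells(sy.CellShapeParams(
                n_cells=1, n_filopodia=nf, seed=1))
            iqs.append(truth["iq"].iloc[0])
        assert all(b < a for a, b in zip(iqs, iqs[1:]))

    def test_truth_matches_shapely_polygon(self):
        _, truth, polys = sy.render_cells(sy.CellShapeParams(n_cells=2, seed=3))
        for (_, row), verts in zip(truth.iterrows(), polys):
            poly = Polygon(verts)
            assert row["area"] == pytest.approx(poly.area)
            assert row["perimeter"] == pytest.approx(poly.length)

    def test_no_cells_blank_image(self):
        image, truth, polys = sy.render_cells(sy.CellShapeParams(n_cells=0))
        assert image.max() == 0 and truth.empty and polys == []

    def test_infeasible_packing_reported(self):
        with pytest.raises(ValueError, match="place|small"):
            sy.render_cells(sy.CellShapeParams(n_cells=40, image_size=(200, 200),
                                               seed=0))

    def test_seed_determinism(self):
        i1, t1, _ = sy.render_cells(sy.CellShapeParams(seed=5))
        i2, t2, _ = sy.render_cells(sy.CellShapeParams(seed=5))
        assert np.array_equal(i1, i2)
        pd.testing.assert_frame_equal(t1, t2)


class TestRenderSpots:
    def test_truth_counts_respect_roi(self):
        p = sy.SpotSceneParams(n_spots_in_roi=7, n_spots_outside=3, seed=2)
        _, truth = sy.render_spots(p)
        inside = truth[truth["in_roi"]]
        assert len(inside) == 7 and len(truth) == 10
        assert all(p.roi_mask[y, x] for x, y in zip(inside["x"], inside["y"]))

    def test_noise_free_spots_are_local_maxima(self):
        p = sy.SpotSceneParams(n_spots_in_roi=4, n_spots_outside=2,
                               noise_sd=0.0, seed=8)
        image, truth = sy.render_spots(p)
        for x, y in zip(truth["x"], truth["y"]):
            patch = image[y - 1:y + 2, x - 1:x + 2]
            assert image[y, x] == patch.max()
            assert np.count_nonzero(patch == patch.max()) == 1

    def test_seed_determinism(self):
        p = sy.SpotSceneParams(noise_sd=4.0, seed=13)
        i1, t1 = sy.render_spots(p)
        i2, t2 = sy.render_spots(p)
        assert np.array_equal(i1, i2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_mask_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sy.SpotSceneParams(image_size=(64, 64), roi_mask=np.ones((32, 32), bool))


class TestGroundTruthRoundTrip:
    def test_truth_table_survives_csv(self):
        motion = sy.MotionParams(n_frames=6)
        scene = sy.SceneParams(n_puncta=2, seed=4)
        _, truth, _ = sy.simulate_timelapse(motion, scene, seed=4)
        buf = io.StringIO()
        truth.to_csv(buf, index=False)
        buf.seek(0)
        back = pd.read_csv(buf)
        pd.testing.assert_frame_equal(back, truth)

    def test_trajectory_csv_round_trip(self, tmp_path):
        from embryoquant.tracking import read_trajectories, write_trajectories
        p = sy.MotionParams(n_frames=10)
        trajs = [sy.simulate_trajectory(p, s, punctum_id=s)[0] for s in range(3)]
        path = tmp_path / "t.csv"
        write_trajectories(trajs, path)
        back = read_trajectories(path)
        assert len(back) == 3
        for a, b in zip(trajs, back):
            assert np.array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.x, b.x)
            np.testing.assert_allclose(a.y, b.y)
            assert a.scale == b.scale and a.frame_interval == b.frame_interval
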