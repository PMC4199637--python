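"""Detection, drift compensation, linking and exclusion filtering."""

import numpy as np
import pandas as pd
import pytest

from embryoquant import synthetic as sy
from embryoquant import tracking as tr
from conftest import match_track_to_truth


def spot_frame(positions, shape=(128, 128), amplitude=100.0, sigma=1.5):
    frame = np.zeros(shape)
    for x, y in positions:
        sy._add_gaussian_spot(frame, x, y, amplitude, sigma)
    return frame


class TestDetectPuncta:
    def test_recovers_rendered_spots_subpixel(self):
        truth = [(30.3, 40.7), (80.0, 50.5), (60.6, 100.2)]
        det = tr.detect_puncta(spot_frame(truth), 20, 5)
        assert len(det) == 3
        for x, y in truth:
            d = np.hypot(det["x"] - x, det["y"] - y)
            assert d.min() < 0.5

    def test_blank_frame_empty(self):
        assert tr.detect_puncta(np.zeros((64, 64)), 10, 3).empty

    def test_close_pair_keeps_brighter(self):
        frame = spot_frame([(40.0, 40.0)], amplitude=100.0)
        frame += spot_frame([(43.0, 40.0)], amplitude=60.0)
        det = tr.detect_puncta(frame, 20, 6)
        assert len(det) == 1
        assert abs(det["x"].iloc[0] - 40.0) < 1.0  # the brighter survives

    def test_rejects_non_grayscale(self):
        with pytest.raises(ValueError):
            tr.detect_puncta(np.zeros((8, 8, 3)), 1, 1)


class TestEstimateDrift:
    def test_recovers_rendered_drift(self, drifting_scene):
        _, scene, stack, _, _ = drifting_scene
        drift = tr.estimate_drift(stack, scene.fiducial_positions)
        expected = np.outer(np.arange(stack.shape[0]), [1.0, 2.0])
        assert np.abs(drift - expected).max() < 0.5

    def test_zero_drift(self):
        scene = sy.SceneParams(n_puncta=0, noise_sd=0.0, seed=0)
        stack, _ = sy.render_timelapse([], scene)
        stack = np.repeat(stack, 5, axis=0)
        drift = tr.estimate_drift(stack, scene.fiducial_positions)
        assert np.abs(drift).max() < 0.05

    def test_two_identical_fiducials_equal_one(self, drifting_scene):
        _, scene, stack, _, _ = drifting_scene
        both = tr.estimate_drift(stack, scene.fiducial_positions)
        one = tr.estimate_drift(stack, scene.fiducial_positions[:1])
        assert np.abs(both - one).max() < 0.2

    def test_lost_fiducial_names_frame(self):
        stack = np.zeros((6, 64, 64))
        for k in range(3):  # fiducial visible only in frames 0-2
            sy._add_gaussian_spot(stack[k], 30.0, 30.0, 150.0, 1.5)
        with pytest.raises(tr.DriftEstimationError, match="frame 3"):
            tr.estimate_drift(stack, [(30.0, 30.0)], min_intensity=50.0)


class TestLinkTrajectories:
    def _detections(self, tracks_positions):
        rows = []
        for frame, pts in enumerate(tracks_positions):
            for x, y in pts:
                rows.append((frame, x, y, 100.0))
        return pd.DataFrame(rows, columns=["frame", "x", "y", "intensity"])

    def test_two_stationary_spots(self):
        det = self._detections([[(10, 10), (40, 10)]] * 10)
        trajs = tr.link_trajectories(det, max_step_px=5, scale=0.2, frame_interval=5.0)
        assert len(trajs) == 2
        assert all(len(t) == 10 for t in trajs)

    def test_single_moving_spot(self):
        det = self._detections([[(10 + 2 * k, 20)] for k in range(10)])
        trajs = tr.link_trajectories(det, max_step_px=5, scale=0.2, frame_interval=5.0)
        assert len(trajs) == 1 and len(trajs[0]) == 10

    def test_gap_bridged_and_flagged(self):
        pts = [[(10 + 2 * k, 20)] for k in range(8)]
        pts[4] = []  # dropped detection
        det = self._detections(pts)
        trajs = tr.link_trajectories(det, max_step_px=5, scale=0.2,
                                     frame_interval=5.0, max_gap=1)
        assert len(trajs) == 1
        t = trajs[0]
        assert np.array_equal(t.frames, np.arange(8))
        assert list(t.imputed) == [False] * 4 + [True] + [False] * 3
        assert t.x[4] == pytest.approx(18.0)  # linear interpolation

    def test_no_gap_bridging_splits_track(self):
        pts = [[(10 + 2 * k, 20)] for k in range(8)]
        pts[4] = []
        det = self._detections(pts)
        trajs = tr.link_trajectories(det, max_step_px=5, scale=0.2,
                                     frame_interval=5.0, max_gap=0)
        assert sorted(len(t) for t in trajs) == [3, 4]

    def test_recovers_ground_truth_assignments(self, drifting_scene):
        """≥90% of (punctum, frame) ground-truth assignments recovered."""
        _, scene, stack, truth, _ = drifting_scene
        drift = tr.estimate_drift(stack, scene.fiducial_positions)
        det = pd.concat(
            [tr.detect_puncta(stack[k], 30, 5, frame=k) for k in range(stack.shape[0])],
            ignore_index=True)
        corrected = tr.apply_drift(det, drift)
        trajs = tr.link_trajectories(corrected, max_step_px=9, scale=0.2,
                                     frame_interval=5.0)
        recovered = 0
        for t in trajs:
            pid, err = match_track_to_truth(t, truth)
            if pid is None or err > 1.0:
                continue
            tt = truth[truth["punctum_id"] == pid].set_index("frame")
            sel = np.isin(t.frames, tt.index)
            close = np.hypot(t.x[sel] - tt.loc[t.frames[sel], "x_px"],
                             t.y[sel] - tt.loc[t.frames[sel], "y_px"]) < 1.0
            recovered += int(close.sum())
        assert recovered >= 0.9 * len(truth)


class TestFilterTrajectories:
    def _traj(self, xs, ys, pid=0, scale=1.0):
        return tr.Trajectory(pid, np.arange(len(xs)), np.asarray(xs, float),
                             np.asarray(ys, float), scale, 5.0)

    def test_static_excluded(self):
        t = self._traj([10, 10.1, 10, 10.05], [5, 5, 5.1, 5])
        kept, log = tr.filter_trajectories([t])
        assert kept == []
        assert "static" in log["reasons"].iloc[0]

    def test_off_axon_excluded(self):
        axon = np.array([[0.0, 0.0], [100.0, 0.0]])
        t = self._traj([0, 10, 20], [0, 20, 0])  # wanders 20 µm off the axon
        kept, log = tr.filter_trajectories([t], axon, axon_max_dist_um=5.0)
        assert kept == []
        assert "off-axon" in log["reasons"].iloc[0]

    def test_non_anterior_excluded(self):
        t = self._traj([10, 6, 2], [0, 0, 0])  # net −8 µm along +x
        kept, log = tr.filter_trajectories([t])
        assert kept == []
        assert "non-anterior" in log["reasons"].iloc[0]

    def test_anterograde_on_axon_kept(self):
        axon = np.array([[0.0, 0.0], [100.0, 0.0]])
        t = self._traj([0, 5, 10, 15], [0, 0.5, 0, 0.5])
        kept, log = tr.filter_trajectories([t], axon)
        assert len(kept) == 1 and log["reasons"].iloc[0] == ""

    def test_filtering_idempotent(self):
        axon = np.array([[0.0, 0.0], [100.0, 0.0]])
        trajs = [
            self._traj([0, 5, 10], [0, 0, 0], pid=0),
            self._traj([10, 10, 10], [0, 0, 0], pid=1),
            self._traj([0, 10, 20], [0, 30, 0], pid=2),
        ]
        kept1, log1 = tr.filter_trajectories(trajs, axon)
        kept2, log2 = tr.filter_trajectories(kept1, axon)
        assert [t.punctum_id for t in kept1] == [t.punctum_id for t in kept2]
        assert all(r == "" for r in log2["reasons"])

    def test_all_rules_reported_together(self):
        t = self._traj([10, 10], [50, 50])  # static AND non-anterior AND off-axon
        axon = np.array([[0.0, 0.0], [100.0, 0.0]])
        _, log = tr.filter_trajectories([t], axon)
        assert set(log["reasons"].iloc[0].split(";")) == \
            {"static", "off-axon", "non-anterior"}
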