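import numpy as np
import pytest

from embryoquant import synthetic as sy


@pytest.fixture(scope="session")
def drifting_scene():
    """Rendered noise-free trafficking stack with (1, 2) px/frame drift.

    Shared by drift-estimation and end-to-end tracking tests; field and
    fiducials chosen so everything stays inside the image for all frames.
    """
    motion = sy.MotionParams(n_frames=30)
    scene = sy.SceneParams(
        image_size=(448, 448),
        n_puncta=5,
        drift_per_frame=(1.0, 2.0),
        noise_sd=0.0,
        seed=3,
        fiducial_positions=((25.0, 25.0), (60.0, 300.0)),
        axon_path=((10.0, 195.0), (430.0, 195.0)),
    )
    stack, truth, trajectories = sy.simulate_timelapse(motion, scene, seed=7)
    return motion, scene, stack, truth, trajectories


def match_track_to_truth(track, truth, min_common=5):
    """Ground-truth punctum id whose positions best match a linked track."""
    best_err, best_id = np.inf, None
    for pid, tt in truth.groupby("punctum_id"):
        tt = tt.set_index("frame")
        common = [f for f in track.frames if f in tt.index]
        if len(common) < min_common:
            continue
        sel = np.isin(track.frames, common)
        err = np.median(np.hypot(track.x[sel] - tt.loc[common, "x_px"],
                                 track.y[sel] - tt.loc[common, "y_px"]))
        if err < best_err:
            best_err, best_id = err, pid
    return best_id, best_err
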