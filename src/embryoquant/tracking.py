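"""Puncta detection, drift compensation, linking and trajectory filtering.

Coordinate convention (used in every CSV this module writes): pixel-centered,
0-based, ``x`` = column index, ``y`` = row index.  The anterior axis is +x in
scene coordinates; "anterior to the left" in the source movies is a display
convention only.

The pipeline is: detect bright puncta per frame as local maxima with
subpixel centroid refinement, estimate stage drift from stationary embryo
landmarks (fiducials), subtract the drift, link detections into trajectories
by greedy nearest neighbour, and exclude trajectories that are static, leave
the axon, or do not traffic anteriorly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage.feature import peak_local_max

__all__ = [
    "Trajectory",
    "DriftEstimationError",
    "detect_puncta",
    "estimate_drift",
    "apply_drift",
    "link_trajectories",
    "filter_trajectories",
    "write_trajectories",
    "read_trajectories",
]

#: Columns of a detection table.
DETECTION_COLUMNS = ("frame", "x", "y", "intensity")


class DriftEstimationError(RuntimeError):
    """A fiducial landmark could not be followed through the stack."""


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-frame positions of one punctum with physical calibration.

    Positions are in drift-corrected pixel coordinates; ``scale`` (µm/pixel)
    and ``frame_interval`` (s) calibrate them.  ``imputed`` flags frames whose
    position was linearly interpolated across a detection gap.
    """

    punctum_id: int
    frames: np.ndarray       # int, strictly increasing
    x: np.ndarray            # px
    y: np.ndarray            # px
    scale: float             # µm / pixel
    frame_interval: float    # s
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if frames.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if not (frames.size == x.size == y.size):
            raise ValueError("frames, x, y must have equal length")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be a positive µm/pixel value, got {self.scale}")
        if not (np.isfinite(self.frame_interval) and self.frame_interval > 0):
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")
        imputed = self.imputed
        if imputed is None:
            imputed = np.zeros(frames.size, dtype=bool)
        imputed = np.asarray(imputed, dtype=bool)
        if imputed.size != frames.size:
            raise ValueError("imputed flags must match trajectory length")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "imputed", imputed)

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in pixels."""
        return np.column_stack([self.x, self.y])

    def net_displacement_um(self) -> np.ndarray:
        """Start→end displacement vector in µm, (dx, dy)."""
        return (self.positions[-1] - self.positions[0]) * self.scale


def _centroid_refine(image: np.ndarray, y: int, x: int, window: int) -> tuple[float, float]:
    """Intensity-weighted centroid in a window×window box around (y, x)."""
    h = window // 2
    y0, y1 = max(0, y - h), min(image.shape[0], y + h + 1)
    x0, x1 = max(0, x - h), min(image.shape[1], x + h + 1)
    patch = np.asarray(image[y0:y1, x0:x1], dtype=float)
    total = patch.sum()
    if total <= 0:
        return float(y), float(x)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((yy * patch).sum() / total), float((xx * patch).sum() / total)


def detect_puncta(
    image: np.ndarray,
    min_intensity: float,
    min_separation: float,
    *,
    frame: int = 0,
    refine_window: int = 5,
    smooth_sigma: float = 0.0,
) -> pd.DataFrame:
    """Detect bright puncta in one grayscale frame.

    Local maxima with intensity ≥ ``min_intensity`` and pairwise separation of
    at least ``min_separation`` pixels are kept (the brighter of two close
    peaks wins; equal-brightness ties go to the lower ``(y, x)``), then each
    is refined to subpixel precision by the intensity-weighted centroid in a
    ``refine_window`` × ``refine_window`` box.

    ``smooth_sigma`` > 0 applies a Gaussian prefilter (matched roughly to the
    spot size) before peak finding — essential on shot-noisy images; note the
    smoothing lowers peak intensities, so ``min_intensity`` refers to the
    filtered image.

    Returns a DataFrame with columns ``frame, x, y, intensity``; empty if no
    peak qualifies.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if smooth_sigma > 0:
        image = ndimage.gaussian_filter(image.astype(float), smooth_sigma)
    min_dist = max(1, int(math.ceil(min_separation)))
    peaks = peak_local_max(
        image.astype(float),
        min_distance=min_dist,
        threshold_abs=min_intensity,
        exclude_border=False,
    )
    rows = []
    for py, px in peaks:
        cy, cx = _centroid_refine(image, int(py), int(px), refine_window)
        rows.append((frame, cx, cy, float(image[py, px])))
    df = pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))
    return df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)


def estimate_drift(
    stack: np.ndarray,
    fiducial_seeds: Sequence[tuple[float, float]],
    *,
    search_radius: int = 6,
    refine_window: int = 5,
    min_intensity: float | None = None,
) -> np.ndarray:
    """Per-frame stage drift from stationary embryo landmarks.

    Each fiducial is followed frame to frame: the brightest pixel within
    ``search_radius`` of its previous position is centroid-refined.  The
    drift of frame k is the mean displacement of all fiducials relative to
    frame 0; drift[0] is (0, 0) by construction.

    Parameters
    ----------
    fiducial_seeds : sequence of (x, y)
        Approximate fiducial positions in frame 0 (pixels).
    min_intensity : float, optional
        If given, a fiducial whose local peak falls below this value is
        considered lost and a :class:`DriftEstimationError` naming the frame
        is raised.

    Returns
    -------
    (n_frames, 2) array of (dx, dy) in pixels.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, rows, cols) stack, got shape {stack.shape}")
    if len(fiducial_seeds) == 0:
        raise ValueError("at least one fiducial seed is required")
    n_frames = stack.shape[0]
    n_fid = len(fiducial_seeds)
    track = np.zeros((n_frames, n_fid, 2))  # (x, y)

    for j, (sx, sy) in enumerate(fiducial_seeds):
        prev = (float(sx), float(sy))
        for k in range(n_frames):
            cx0, cy0 = int(round(prev[0])), int(round(prev[1]))
            y0 = max(0, cy0 - search_radius)
            y1 = min(stack.shape[1], cy0 + search_radius + 1)
            x0 = max(0, cx0 - search_radius)
            x1 = min(stack.shape[2], cx0 + search_radius + 1)
            patch = stack[k, y0:y1, x0:x1]
            if patch.size == 0:
                raise DriftEstimationError(f"fiducial {j} left the field at frame {k}")
            py, px = np.unravel_index(int(np.argmax(patch)), patch.shape)
            peak_val = float(patch[py, px])
            if min_intensity is not None and peak_val < min_intensity:
                raise DriftEstimationError(
                    f"fiducial {j} lost at frame {k}: peak {peak_val:g} < {min_intensity:g}"
                )
            cy, cx = _centroid_refine(stack[k], y0 + int(py), x0 + int(px), refine_window)
            track[k, j] = (cx, cy)
            prev = (cx, cy)

    drift = track.mean(axis=1) - track[0].mean(axis=0)
    drift[0] = 0.0
    return drift


def apply_drift(detections: pd.DataFrame, drift: np.ndarray) -> pd.DataFrame:
    """Subtract per-frame drift from detection coordinates."""
    drift = np.asarray(drift, dtype=float)
    out = detections.copy()
    frames = out["frame"].to_numpy(dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= drift.shape[0]):
        raise ValueError("detection frame index outside the drift track")
    out["x"] = out["x"].to_numpy(dtype=float) - drift[frames, 0]
    out["y"] = out["y"].to_numpy(dtype=float) - drift[frames, 1]
    return out


def link_trajectories(
    detections: pd.DataFrame,
    *,
    max_step_px: float,
    scale: float,
    frame_interval: float,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories by greedy nearest neighbour.

    Candidate links between open tracks and the next frame's detections are
    taken in ascending distance order; a link farther than
    ``max_step_px × (gap + 1)`` is forbidden.  A track may bridge up to
    ``max_gap`` missing frames; bridged frames are filled by linear
    interpolation and flagged as imputed.  Unmatched detections start new
    tracks; tracks shorter than 2 frames are discarded as singletons.
    """
    if detections.empty:
        return []
    req = {"frame", "x", "y"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections need columns {sorted(req)}")

    by_frame = {int(f): g[["x", "y"]].to_numpy(dtype=float)
                for f, g in detections.groupby("frame")}
    frames_sorted = sorted(by_frame)

    # open tracks: list of dict(frames=[...], pts=[(x,y)...])
    open_tracks: list[dict] = []
    done: list[dict] = []

    for f in frames_sorted:
        pts = by_frame[f]
        # candidate (distance, track_idx, det_idx)
        cands = []
        for ti, tr in enumerate(open_tracks):
            gap = f - tr["frames"][-1] - 1
            if gap > max_gap:
                continue
            limit = max_step_px * (gap + 1)
            last = np.asarray(tr["pts"][-1])
            d = np.hypot(pts[:, 0] - last[0], pts[:, 1] - last[1])
            for di in np.flatnonzero(d <= limit):
                cands.append((float(d[di]), ti, int(di)))
        cands.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            prev_f, prev_p = tr["frames"][-1], np.asarray(tr["pts"][-1])
            gap = f - prev_f - 1
            for g in range(1, gap + 1):  # bridge the gap by interpolation
                w = g / (gap + 1)
                tr["frames"].append(prev_f + g)
                tr["pts"].append(tuple(prev_p + w * (pts[di] - prev_p)))
                tr["imputed"].append(True)
            tr["frames"].append(f)
            tr["pts"].append(tuple(pts[di]))
            tr["imputed"].append(False)
        # expire tracks that cannot reach the next frame within max_gap
        still_open = []
        for tr in open_tracks:
            if f - tr["frames"][-1] <= max_gap:
                still_open.append(tr)
            else:
                done.append(tr)
        open_tracks = still_open
        for di in range(pts.shape[0]):
            if di not in used_d:
                open_tracks.append(
                    {"frames": [f], "pts": [tuple(pts[di])], "imputed": [False]}
                )
    done.extend(open_tracks)

    out = []
    pid = 0
    for tr in done:
        if len(tr["frames"]) < 2:
            continue
        xs, ys = zip(*tr["pts"])
        out.append(Trajectory(
            punctum_id=pid,
            frames=np.array(tr["frames"]),
            x=np.array(xs), y=np.array(ys),
            scale=scale, frame_interval=frame_interval,
            imputed=np.array(tr["imputed"], dtype=bool),
        ))
        pid += 1
    return out


def filter_trajectories(
    trajectories: Sequence[Trajectory],
    axon_path: np.ndarray | None = None,
    *,
    static_min_um: float = 1.0,
    axon_max_dist_um: float = 3.0,
    anterior_axis: tuple[float, float] = (1.0, 0.0),
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Apply the trajectory exclusion rules and record the reasons.

    A trajectory is excluded when it is

    * ``static`` — net start→end displacement below ``static_min_um`` µm;
    * ``off-axon`` — any point farther than ``axon_max_dist_um`` µm from the
      axon polyline (``axon_path``, (k, 2) array of (x, y) pixels; rule
      skipped when no path is given);
    * ``non-anterior`` — net displacement along the anterior axis ≤ 0.

    Every rule is evaluated for every trajectory, so the exclusion log is
    independent of rule order and re-filtering kept trajectories is a no-op.

    Returns
    -------
    (kept, log) where ``log`` has columns ``punctum_id, excluded, reasons``
    (reasons ``;``-joined, empty when kept).
    """
    axis = np.asarray(anterior_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("anterior_axis must be non-zero")
    axis = axis / nrm
    line = None
    if axon_path is not None:
        path = np.asarray(axon_path, dtype=float)
        if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
            raise ValueError("axon_path must be a (k>=2, 2) polyline in pixels")
        line = LineString(path)

    kept, rows = [], []
    for traj in trajectories:
        reasons = []
        net = traj.net_displacement_um()
        if float(np.linalg.norm(net)) < static_min_um:
            reasons.append("static")
        if line is not None:
            dmax = max(
                line.distance(Point(px, py)) for px, py in traj.positions
            ) * traj.scale
            if dmax > axon_max_dist_um:
                reasons.append("off-axon")
        if float(net @ axis) <= 0:
            reasons.append("non-anterior")
        rows.append((traj.punctum_id, bool(reasons), ";".join(reasons)))
        if not reasons:
            kept.append(traj)
    log = pd.DataFrame(rows, columns=["punctum_id", "excluded", "reasons"])
    return kept, log


_CSV_HEADER = (
    "# trajectories: pixel-centered 0-based coordinates, x = column, y = row;\n"
    "# positions are drift-corrected; scale in um/pixel, frame_interval in s\n"
)


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories to CSV with a documented coordinate header."""
    frames = []
    for t in trajectories:
        frames.append(pd.DataFrame({
            "punctum_id": t.punctum_id,
            "frame": t.frames,
            "x_px": t.x,
            "y_px": t.y,
            "imputed": t.imputed.astype(int),
            "scale_um_per_px": t.scale,
            "frame_interval_s": t.frame_interval,
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["punctum_id", "frame", "x_px", "y_px", "imputed",
                 "scale_um_per_px", "frame_interval_s"])
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories` (or pre-tracked
    CSVs with the same columns), bypassing detection and linking."""
    df = pd.read_csv(path, comment="#")
    out = []
    for pid, g in df.groupby("punctum_id"):
        g = g.sort_values("frame")
        out.append(Trajectory(
            punctum_id=int(pid),
            frames=g["frame"].to_numpy(int),
            x=g["x_px"].to_numpy(float),
            y=g["y_px"].to_numpy(float),
            scale=float(g["scale_um_per_px"].iloc[0]),
            frame_interval=float(g["frame_interval_s"].iloc[0]),
            imputed=g["imputed"].to_numpy(bool) if "imputed" in g else None,
        ))
    return out
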