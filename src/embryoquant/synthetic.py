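"""Seeded synthetic data with known ground truth for every analysis stage.

Four generators emulate the imaging assays this package quantifies:

* two-state (run/pause) Markov trajectories of axonal puncta sampled at the
  frame interval, with geometric dwell times, anterograde bias and
  positional jitter while paused;
* time-lapse stacks rendering those trajectories as Gaussian spots over a
  faint axon polyline, with stationary fiducial landmarks, rigid stage
  drift and additive Gaussian noise (clipped at zero);
* star-shaped pigment cells — a disk body plus radial filopodia spikes —
  with analytic ground-truth polygons;
* spot-count scenes with a known number of point-like labeled cells inside
  and outside a binary region-of-interest mask.

Every generator is a pure function of its parameters and a single integer
seed.  Anterior is +x in scene coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .tracking import Trajectory

__all__ = [
    "MotionParams",
    "SceneParams",
    "CellShapeParams",
    "SpotSceneParams",
    "simulate_trajectory",
    "pause_occupancy",
    "render_timelapse",
    "simulate_timelapse",
    "star_polygon",
    "render_cells",
    "render_spots",
]


def _check_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    ok = np.isfinite(value) and (value >= 0 if allow_zero else value > 0)
    if not ok:
        kind = "non-negative" if allow_zero else "positive"
        raise ValueError(f"{name} must be a finite {kind} number, got {value}")


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the two-state run/pause motion model.

    Dwell times are geometric in frame units with the stated means in
    seconds; a mean of zero disables the state entirely (``pause_dwell_mean=0``
    never pauses, ``run_dwell_mean=0`` never runs).  Means shorter than one
    frame interval are clamped to a one-frame mean.  ``anterior_bias`` is the
    fraction of run steps directed anteriorly (+x).
    """

    run_speed: float = 0.24          # µm/s, so 1.2 µm per 5 s frame
    run_dwell_mean: float = 30.0     # s
    pause_dwell_mean: float = 20.0   # s
    pause_jitter_sd: float = 0.05    # µm per frame while paused
    anterior_bias: float = 1.0       # in [0, 1]
    frame_interval: float = 5.0      # s, the movies' acquisition interval
    n_frames: int = 240              # 20 min at 5 s
    scale: float = 0.2               # µm/pixel (50 µm field over 250 px)

    def __post_init__(self) -> None:
        _check_positive("run_speed", self.run_speed, allow_zero=True)
        _check_positive("run_dwell_mean", self.run_dwell_mean, allow_zero=True)
        _check_positive("pause_dwell_mean", self.pause_dwell_mean, allow_zero=True)
        _check_positive("pause_jitter_sd", self.pause_jitter_sd, allow_zero=True)
        _check_positive("frame_interval", self.frame_interval)
        _check_positive("scale", self.scale)
        if not (0.0 <= self.anterior_bias <= 1.0):
            raise ValueError(f"anterior_bias must lie in [0, 1], got {self.anterior_bias}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.run_dwell_mean == 0 and self.pause_dwell_mean == 0:
            raise ValueError("run_dwell_mean and pause_dwell_mean cannot both be 0")


def pause_occupancy(params: MotionParams) -> float:
    """Stationary fraction of time in the pause state,
    pause_dwell / (pause_dwell + run_dwell)."""
    if params.pause_dwell_mean == 0:
        return 0.0
    if params.run_dwell_mean == 0:
        return 1.0
    dt = params.frame_interval
    # leave probabilities after clamping dwell means to >= one frame
    q_run = min(1.0, dt / params.run_dwell_mean)
    q_pause = min(1.0, dt / params.pause_dwell_mean)
    return q_run / (q_run + q_pause)


def simulate_trajectory(
    params: MotionParams,
    seed: int,
    *,
    punctum_id: int = 0,
    start_px: tuple[float, float] = (0.0, 0.0),
) -> tuple[Trajectory, np.ndarray]:
    """Sample one run/pause trajectory and its ground-truth state sequence.

    The hidden state is Markov over the n_frames − 1 intervals, initialised
    from its stationary distribution.  A run interval displaces the punctum
    by ``run_speed · Δt`` along +x with probability ``anterior_bias`` (else
    −x); a pause interval adds independent N(0, pause_jitter_sd²) µm to each
    coordinate.  Returns the trajectory (positions in pixels) and an array of
    ``"run"`` / ``"pause"`` labels, one per interval.
    """
    rng = np.random.default_rng(seed)
    dt = params.frame_interval
    p_pause = pause_occupancy(params)
    q_run = 1.0 if params.run_dwell_mean == 0 else min(1.0, dt / params.run_dwell_mean)
    q_pause = 1.0 if params.pause_dwell_mean == 0 else min(1.0, dt / params.pause_dwell_mean)

    n_int = params.n_frames - 1
    states = np.empty(n_int, dtype=object)
    if params.pause_dwell_mean == 0:
        states[:] = "run"
    elif params.run_dwell_mean == 0:
        states[:] = "pause"
    else:
        s = "pause" if rng.random() < p_pause else "run"
        for i in range(n_int):
            states[i] = s
            if s == "run":
                if rng.random() < q_run:
                    s = "pause"
            else:
                if rng.random() < q_pause:
                    s = "run"

    pos = np.zeros((params.n_frames, 2))  # µm, starts at origin
    for i, s in enumerate(states):
        if s == "run":
            direction = 1.0 if rng.random() < params.anterior_bias else -1.0
            step = np.array([direction * params.run_speed * dt, 0.0])
        else:
            step = rng.normal(0.0, params.pause_jitter_sd, size=2)
        pos[i + 1] = pos[i] + step

    traj = Trajectory(
        punctum_id=punctum_id,
        frames=np.arange(params.n_frames),
        x=pos[:, 0] / params.scale + start_px[0],
        y=pos[:, 1] / params.scale + start_px[1],
        scale=params.scale,
        frame_interval=dt,
    )
    return traj, states.astype(str)


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for a synthetic time-lapse field of view."""

    image_size: tuple[int, int] = (256, 256)         # (rows, cols)
    n_puncta: int = 5
    psf_sigma: float = 1.5                           # px
    fiducial_positions: tuple[tuple[float, float], ...] = ((20.0, 20.0), (230.0, 30.0))
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px
    noise_sd: float = 0.0                            # intensity units
    axon_path: tuple[tuple[float, float], ...] = ((10.0, 128.0), (246.0, 128.0))
    spot_amplitude: float = 100.0
    fiducial_amplitude: float = 150.0
    axon_amplitude: float = 8.0                      # "faintly labeled" axon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        _check_positive("psf_sigma", self.psf_sigma)
        _check_positive("noise_sd", self.noise_sd, allow_zero=True)
        if len(self.axon_path) < 2:
            raise ValueError("axon_path needs at least 2 vertices")


def _add_gaussian_spot(
    frame: np.ndarray, x: float, y: float, amplitude: float, sigma: float
) -> None:
    """Add a 2-D Gaussian at subpixel (x, y); no-op outside the field."""
    h, w = frame.shape
    r = int(math.ceil(4 * sigma))
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0c, y1c = max(0, y0), min(h, y1)
    x0c, x1c = max(0, x0), min(w, x1)
    if y0c >= y1c or x0c >= x1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    frame[y0c:y1c, x0c:x1c] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma ** 2)
    )


def _add_axon(frame: np.ndarray, path: np.ndarray, amplitude: float, sigma: float) -> None:
    """Faint blurred polyline, sampled densely and rendered as tiny Gaussians."""
    for (x0, y0), (x1, y1) in zip(path[:-1], path[1:]):
        n = max(2, int(math.hypot(x1 - x0, y1 - y0) * 2))
        for t in np.linspace(0.0, 1.0, n):
            _add_gaussian_spot(frame, x0 + t * (x1 - x0), y0 + t * (y1 - y0),
                               amplitude / 4.0, sigma)


def render_timelapse(
    trajectories: Sequence[Trajectory],
    scene: SceneParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories into a noisy drifting time-lapse stack.

    Everything in the scene — puncta, fiducials, axon — is rigidly
    translated by ``drift_per_frame × k`` in frame k, emulating stage drift.
    Returns the float32 stack and a ground-truth table with columns
    ``punctum_id, frame, x_px, y_px, state`` in *scene* (un-drifted)
    coordinates; rows where a punctum's spot centre left the field are
    truncated from the truth, not an error.
    """
    n_frames = max((int(t.frames.max()) + 1 for t in trajectories), default=1)
    h, w = scene.image_size
    rng = np.random.default_rng(scene.seed)
    drift = np.asarray(scene.drift_per_frame, dtype=float)
    axon = np.asarray(scene.axon_path, dtype=float)

    stack = np.zeros((n_frames, h, w), dtype=np.float32)
    truth_rows = []
    for k in range(n_frames):
        frame = np.zeros((h, w))
        off = drift * k
        _add_axon(frame, axon + off, scene.axon_amplitude, scene.psf_sigma)
        for fx, fy in scene.fiducial_positions:
            _add_gaussian_spot(frame, fx + off[0], fy + off[1],
                               scene.fiducial_amplitude, scene.psf_sigma)
        for t in trajectories:
            idx = np.flatnonzero(t.frames == k)
            if idx.size == 0:
                continue
            i = int(idx[0])
            ix, iy = t.x[i] + off[0], t.y[i] + off[1]
            _add_gaussian_spot(frame, ix, iy, scene.spot_amplitude, scene.psf_sigma)
            if 0 <= ix < w and 0 <= iy < h:
                truth_rows.append((t.punctum_id, k, t.x[i], t.y[i]))
        if scene.noise_sd > 0:
            frame = np.clip(frame + rng.normal(0.0, scene.noise_sd, frame.shape), 0.0, None)
        stack[k] = frame
    truth = pd.DataFrame(truth_rows, columns=["punctum_id", "frame", "x_px", "y_px"])
    return stack, truth


def simulate_timelapse(
    motion: MotionParams,
    scene: SceneParams,
    seed: int,
    *,
    lane_spacing_px: float = 30.0,
) -> tuple[np.ndarray, pd.DataFrame, list[Trajectory]]:
    """Simulate ``scene.n_puncta`` trajectories and render the full stack.

    Puncta are started along the axon path on parallel, non-crossing lanes
    offset perpendicular to it by multiples of ``lane_spacing_px``, so
    ground-truth identities are recoverable by any reasonable linker.  The
    truth table carries the per-interval state of each punctum.
    """
    rng = np.random.default_rng(seed)
    axon = np.asarray(scene.axon_path, dtype=float)
    start, end = axon[0], axon[-1]
    direction = (end - start) / np.linalg.norm(end - start)
    normal = np.array([-direction[1], direction[0]])

    trajectories, state_rows = [], []
    for i in range(scene.n_puncta):
        lane = (i - (scene.n_puncta - 1) / 2.0) * lane_spacing_px
        along = 10.0 + 0.5 * i * lane_spacing_px
        origin = start + along * direction + lane * normal
        traj, states = simulate_trajectory(
            motion, int(rng.integers(0, 2 ** 31 - 1)),
            punctum_id=i, start_px=(float(origin[0]), float(origin[1])),
        )
        trajectories.append(traj)
        for k, s in enumerate(states):
            state_rows.append((i, k, s))

    stack, truth = render_timelapse(trajectories, scene)
    states = pd.DataFrame(state_rows, columns=["punctum_id", "interval", "state"])
    truth = truth.merge(
        states.rename(columns={"interval": "frame"}), how="left",
        on=["punctum_id", "frame"],
    )
    return stack, truth, trajectories


@dataclass(frozen=True)
class CellShapeParams:
    """Star-shaped pigment cell scenes: disk body plus radial filopodia."""

    n_cells: int = 4
    body_radius: float = 30.0        # px
    n_filopodia: int = 6
    filopodia_length: float = 12.0   # px beyond the body
    placement_margin: float = 10.0   # px between cells and to the border
    image_size: tuple[int, int] = (512, 512)
    n_body_vertices: int = 64
    spike_half_angle: float = 0.18   # rad; base half-width of a filopodium
    tip_fraction: float = 0.5        # tip half-angle / base half-angle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_filopodia < 0:
            raise ValueError("counts must be >= 0")
        _check_positive("body_radius", self.body_radius)
        _check_positive("filopodia_length", self.filopodia_length, allow_zero=True)
        if not (0.0 <= self.tip_fraction < 1.0):
            raise ValueError("tip_fraction must lie in [0, 1)")
        if self.n_filopodia > 0:
            if self.n_filopodia * 2 * self.spike_half_angle >= 2 * math.pi:
                raise ValueError("filopodia bases overlap; reduce count or spike_half_angle")


def star_polygon(
    center: tuple[float, float],
    body_radius: float,
    n_filopodia: int,
    filopodia_length: float,
    *,
    n_body_vertices: int = 64,
    spike_half_angle: float = 0.18,
    tip_fraction: float = 0.5,
    rotation: float = 0.0,
) -> np.ndarray:
    """Vertices (x, y) of a disk-approximating polygon with radial spikes.

    Filopodia are trapezoidal finger-like spikes at equally spaced angles:
    the boundary leaves the body circle at ``φ − spike_half_angle``, runs to
    a flat tip spanning ``φ ± spike_half_angle·tip_fraction`` at radius
    ``body_radius + filopodia_length``, and rejoins the circle at
    ``φ + spike_half_angle``.  The finite tip width keeps the spikes
    faithfully rasterisable (real filopodia have finite width too);
    ``tip_fraction=0`` gives pointed spikes.  With zero filopodia this is a
    regular ``n_body_vertices``-gon whose isoperimetric quotient approaches 1.
    """
    cx, cy = center
    spikes = [rotation + 2 * math.pi * k / n_filopodia for k in range(n_filopodia)] \
        if n_filopodia else []
    events: list[tuple[float, float]] = []  # (angle, radius)
    for theta in np.linspace(0.0, 2 * math.pi, n_body_vertices, endpoint=False):
        a = (theta + rotation) % (2 * math.pi)
        if any(abs((a - s + math.pi) % (2 * math.pi) - math.pi) < spike_half_angle
               for s in spikes):
            continue  # body vertex swallowed by a spike base
        events.append((a, body_radius))
    tip_half = spike_half_angle * tip_fraction
    for s in spikes:
        events.append(((s - spike_half_angle) % (2 * math.pi), body_radius))
        if tip_half > 0:
            events.append(((s - tip_half) % (2 * math.pi), body_radius + filopodia_length))
            events.append(((s + tip_half) % (2 * math.pi), body_radius + filopodia_length))
        else:
            events.append((s % (2 * math.pi), body_radius + filopodia_length))
        events.append(((s + spike_half_angle) % (2 * math.pi), body_radius))
    events.sort()
    return np.array([(cx + r * math.cos(a), cy + r * math.sin(a)) for a, r in events])


def render_cells(params: CellShapeParams) -> tuple[np.ndarray, pd.DataFrame, list[np.ndarray]]:
    """Render non-overlapping star cells with analytic ground truth.

    Returns the binary-valued float image (cells = 1), a truth table with
    the analytic area, perimeter and isoperimetric quotient of each
    ground-truth polygon, and the polygons themselves.  Raises if the
    requested number of cells cannot be packed without overlap.
    """
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    reach = params.body_radius + (params.filopodia_length if params.n_filopodia else 0.0)
    min_c = reach + params.placement_margin
    if 2 * min_c > min(h, w) and params.n_cells > 0:
        raise ValueError("image too small for the requested cell size")

    centers: list[tuple[float, float]] = []
    for _ in range(params.n_cells):
        for _attempt in range(2000):
            c = (rng.uniform(min_c, w - min_c), rng.uniform(min_c, h - min_c))
            if all(math.hypot(c[0] - o[0], c[1] - o[1]) >= 2 * reach + params.placement_margin
                   for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError(
                f"could not place {params.n_cells} non-overlapping cells "
                f"(placed {len(centers)}); enlarge the image or shrink the cells"
            )

    image = np.zeros((h, w), dtype=float)
    rows, polys = [], []
    for label, c in enumerate(centers, start=1):
        verts = star_polygon(
            c, params.body_radius, params.n_filopodia, params.filopodia_length,
            n_body_vertices=params.n_body_vertices,
            spike_half_angle=params.spike_half_angle,
            tip_fraction=params.tip_fraction,
            rotation=float(rng.uniform(0.0, 2 * math.pi)),
        )
        poly = Polygon(verts)
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=image.shape)
        image[rr, cc] = 1.0
        rows.append({
            "label": label,
            "cx": c[0], "cy": c[1],
            "area": poly.area,
            "perimeter": poly.length,
            "iq": 4.0 * math.pi * poly.area / poly.length ** 2,
            "n_filopodia": params.n_filopodia,
        })
        polys.append(verts)
    truth = pd.DataFrame(rows, columns=["label", "cx", "cy", "area", "perimeter",
                                        "iq", "n_filopodia"])
    return image, truth, polys


@dataclass(frozen=True)
class SpotSceneParams:
    """Scene of point-like labeled cells inside and outside a binary ROI."""

    image_size: tuple[int, int] = (256, 256)
    n_spots_in_roi: int = 7
    n_spots_outside: int = 3
    roi_mask: np.ndarray = None  # type: ignore[assignment]
    spot_sigma: float = 2.0
    spot_amplitude: float = 100.0
    noise_sd: float = 0.0
    min_separation: float = 12.0  # px between spot centres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots_in_roi < 0 or self.n_spots_outside < 0:
            raise ValueError("spot counts must be >= 0")
        _check_positive("spot_sigma", self.spot_sigma)
        _check_positive("noise_sd", self.noise_sd, allow_zero=True)
        mask = self.roi_mask
        if mask is None:
            h, w = self.image_size
            mask = np.zeros((h, w), dtype=bool)
            mask[: h // 2, :] = True  # default ROI: upper half
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(self.image_size):
            raise ValueError(
                f"roi_mask shape {mask.shape} != image_size {self.image_size}"
            )
        object.__setattr__(self, "roi_mask", mask)


def render_spots(params: SpotSceneParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Render Gaussian spots at known positions in and out of the ROI.

    Spot centres sit on pixel centres drawn from the mask-true (inside) and
    mask-false (outside) pixel sets, at least ``min_separation`` px apart
    and 4σ from the image border.  Returns the image and a truth table with
    columns ``x, y, in_roi``.
    """
    h, w = params.image_size
    rng = np.random.default_rng(params.seed)
    border = int(math.ceil(4 * params.spot_sigma))
    valid = np.zeros((h, w), dtype=bool)
    valid[border:h - border, border:w - border] = True

    placed: list[tuple[int, int, bool]] = []

    def _place(region_mask: np.ndarray, count: int, inside: bool) -> None:
        candidates = np.argwhere(region_mask & valid)  # (y, x)
        if candidates.shape[0] == 0 and count > 0:
            raise ValueError("no room for spots in the requested region")
        for _ in range(count):
            for _attempt in range(5000):
                cy, cx = candidates[rng.integers(0, candidates.shape[0])]
                if all(math.hypot(cx - px, cy - py) >= params.min_separation
                       for px, py, _ in placed):
                    placed.append((int(cx), int(cy), inside))
                    break
            else:
                raise ValueError("could not place spots at the requested separation")

    _place(params.roi_mask, params.n_spots_in_roi, True)
    _place(~params.roi_mask, params.n_spots_outside, False)

    image = np.zeros((h, w), dtype=float)
    for cx, cy, _ in placed:
        _add_gaussian_spot(image, cx, cy, params.spot_amplitude, params.spot_sigma)
    if params.noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, params.noise_sd, image.shape), 0.0, None)
    truth = pd.DataFrame(placed, columns=["x", "y", "in_roi"])
    return image, truth
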