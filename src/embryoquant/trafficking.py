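"""Saltatory-transport statistics for axonal vesicle trajectories.

Intracellular dextran-filled puncta move in a run-and-pause (saltatory)
regime.  A *pause* is a maximal run of consecutive inter-frame displacements
strictly below a threshold θ (default 0.5 µm at a 5 s frame interval); a
displacement of exactly θ counts as moving.  From the pause segmentation we
derive, per punctum:

* overall speed — total path length / total time (µm/s),
* moving speed — path length over non-pause intervals / non-pause time
  (NaN sentinel when every interval is a pause),
* % time paused — 100 · paused time / total time,
* pause durations — one value per pause, in seconds.

Speeds use path length (the summed per-frame distances), not net
displacement.  Gap-bridged (imputed) intervals count toward time; linear
interpolation across the gap spreads the displacement evenly, and the flags
are carried through so downstream consumers can drop them if they wish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import GroupComparison, compare
from .tracking import Trajectory

__all__ = [
    "StepSeries",
    "PauseSegment",
    "TrajectoryStats",
    "PAUSE_THRESHOLD_UM",
    "step_displacements",
    "segment_pauses",
    "trajectory_stats",
    "rolling_speed",
    "group_trafficking_summary",
    "stats_frame",
]

#: Default pause threshold θ in µm per frame interval.
PAUSE_THRESHOLD_UM = 0.5


@dataclass(frozen=True)
class StepSeries:
    """Per-interval displacements of one trajectory, in physical units."""

    displacement_um: np.ndarray   # ≥ 0, length n_frames − 1
    frame_interval: float         # s
    imputed: np.ndarray           # True where either endpoint was interpolated

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement_um, dtype=float)
        imp = np.asarray(self.imputed, dtype=bool)
        if d.size != imp.size:
            raise ValueError("displacement and imputed flags must align")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("displacements must be finite and non-negative")
        object.__setattr__(self, "displacement_um", d)
        object.__setattr__(self, "imputed", imp)

    def __len__(self) -> int:
        return int(self.displacement_um.size)

    @property
    def total_time(self) -> float:
        return len(self) * self.frame_interval


@dataclass(frozen=True)
class PauseSegment:
    """Maximal run of consecutive sub-threshold intervals (inclusive indices)."""

    start: int
    end: int
    duration: float  # s = (#intervals) · Δt


@dataclass(frozen=True)
class TrajectoryStats:
    """Per-punctum trafficking metrics."""

    punctum_id: int
    overall_speed: float          # µm/s
    moving_speed: float           # µm/s; NaN when the punctum never moves
    pct_paused: float             # % of total time
    pause_durations: tuple[float, ...]
    n_pauses: int
    total_time: float             # s
    path_length: float            # µm


def step_displacements(traj: Trajectory) -> StepSeries:
    """Euclidean distance between consecutive positions, scaled to µm.

    An interval is flagged imputed when either of its endpoint frames was
    gap-bridged by the linker.
    """
    d = np.hypot(np.diff(traj.x), np.diff(traj.y)) * traj.scale
    imp = traj.imputed[:-1] | traj.imputed[1:]
    return StepSeries(displacement_um=d, frame_interval=traj.frame_interval, imputed=imp)


def segment_pauses(
    steps: StepSeries | np.ndarray,
    theta: float = PAUSE_THRESHOLD_UM,
    *,
    frame_interval: float | None = None,
) -> list[PauseSegment]:
    """Maximal runs of intervals with displacement strictly below θ.

    A pause ends at the first interval with displacement ≥ θ; a pause
    touching a series boundary is still a pause.  Also accepts a bare
    displacement array plus ``frame_interval``.
    """
    if theta <= 0 or not math.isfinite(theta):
        raise ValueError(f"theta must be a positive finite µm value, got {theta}")
    if isinstance(steps, StepSeries):
        d = steps.displacement_um
        dt = steps.frame_interval
    else:
        if frame_interval is None:
            raise ValueError("frame_interval required with a bare displacement array")
        d = np.asarray(steps, dtype=float)
        dt = frame_interval
    below = d < theta
    segments: list[PauseSegment] = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            segments.append(PauseSegment(start, i - 1, (i - start) * dt))
            start = None
    if start is not None:
        segments.append(PauseSegment(start, below.size - 1, (below.size - start) * dt))
    return segments


def trajectory_stats(
    traj: Trajectory,
    theta: float = PAUSE_THRESHOLD_UM,
) -> TrajectoryStats:
    """All per-punctum metrics from one trajectory.

    Exact conservation holds: paused time + moving time = total time, and
    pct_paused = 100 · Σ pause_durations / total time.
    """
    steps = step_displacements(traj)
    n = len(steps)
    dt = steps.frame_interval
    pauses = segment_pauses(steps, theta)
    paused_intervals = sum(p.end - p.start + 1 for p in pauses)
    total_time = n * dt
    paused_time = paused_intervals * dt
    moving_time = total_time - paused_time
    path = float(steps.displacement_um.sum())

    mask = np.zeros(n, dtype=bool)
    for p in pauses:
        mask[p.start:p.end + 1] = True
    moving_path = float(steps.displacement_um[~mask].sum())

    return TrajectoryStats(
        punctum_id=traj.punctum_id,
        overall_speed=path / total_time,
        moving_speed=(moving_path / moving_time) if moving_time > 0 else float("nan"),
        pct_paused=100.0 * paused_time / total_time,
        pause_durations=tuple(p.duration for p in pauses),
        n_pauses=len(pauses),
        total_time=total_time,
        path_length=path,
    )


def rolling_speed(traj: Trajectory, window: float = 15.0) -> np.ndarray:
    """Trailing-window mean speed, one value per interval (µm/s).

    At interval k the value is the mean speed over the preceding
    ``window / Δt`` intervals; the first ``window/Δt − 1`` entries are NaN.
    ``window`` must be an integer multiple of the frame interval;
    ``window == Δt`` reduces to the per-interval speeds.
    """
    steps = step_displacements(traj)
    dt = steps.frame_interval
    ratio = window / dt
    w = int(round(ratio))
    if w < 1 or abs(ratio - w) > 1e-9:
        raise ValueError(
            f"window ({window} s) must be a positive integer multiple of "
            f"the frame interval ({dt} s)"
        )
    speeds = steps.displacement_um / dt
    out = np.full(len(steps), np.nan)
    if len(steps) >= w:
        kernel = np.ones(w) / w
        out[w - 1:] = np.convolve(speeds, kernel, mode="valid")
    return out


#: The four group-level trafficking metrics and how each pools per-punctum data.
TRAFFIC_METRICS = ("overall_speed", "moving_speed", "pct_paused", "pause_duration")


def _metric_values(stats: Sequence[TrajectoryStats], metric: str) -> list[float]:
    if metric == "pause_duration":
        return [d for s in stats for d in s.pause_durations]
    return [getattr(s, metric) for s in stats]


def group_trafficking_summary(
    groups: Mapping[str, Sequence[TrajectoryStats]],
    *,
    welch: bool = False,
) -> dict[str, GroupComparison]:
    """Two-group comparison of the four trafficking metrics.

    ``groups`` maps exactly two group labels to their per-punctum stats.
    Speeds and % paused contribute one value per punctum; pause duration
    contributes one value per pause.  NaN moving speeds (puncta that never
    moved) are dropped from that metric.
    """
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    (name_a, stats_a), (name_b, stats_b) = groups.items()
    if len(stats_a) < 2 or len(stats_b) < 2:
        raise ValueError("at least 2 puncta per group are required")
    out = {}
    for metric in TRAFFIC_METRICS:
        va = _metric_values(stats_a, metric)
        vb = _metric_values(stats_b, metric)
        out[metric] = compare(metric, va, vb, welch=welch, drop_nan=True)
    return out


def pooled_pct_paused(stats: Sequence[TrajectoryStats]) -> float:
    """% paused pooled over all intervals of a group (time-weighted), the
    alternative to the default per-punctum average."""
    total = sum(s.total_time for s in stats)
    if total == 0:
        raise ValueError("no intervals")
    paused = sum(s.pct_paused / 100.0 * s.total_time for s in stats)
    return 100.0 * paused / total


def stats_frame(stats: Sequence[TrajectoryStats]) -> pd.DataFrame:
    """Tidy per-punctum stats table (pause durations summarised by count/mean)."""
    rows = []
    for s in stats:
        rows.append({
            "punctum_id": s.punctum_id,
            "overall_speed_um_s": s.overall_speed,
            "moving_speed_um_s": s.moving_speed,
            "pct_paused": s.pct_paused,
            "n_pauses": s.n_pauses,
            "mean_pause_duration_s":
                float(np.mean(s.pause_durations)) if s.pause_durations else float("nan"),
            "total_time_s": s.total_time,
            "path_length_um": s.path_length,
        })
    return pd.DataFrame(rows)
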