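"""Dying-cell counting in maximum-projected z-stacks restricted to ROIs.

Apoptotic cells labeled with Acridine Orange or activated caspase-3 are
counted on "compressed" (maximum-projected) confocal stacks within
anatomical regions of interest supplied as binary masks — the study's head
and trunk regions are bounded by landmarks (otic vesicle, yolk) that are
not computable from the label channel, so the masks are user input.

A spot belongs to an ROI when the mask is true at its rounded centroid;
the spot's full extent is not considered, so counts are exactly additive
over disjoint masks as long as no centroid lands on a shared boundary
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import GroupComparison, compare
from .tracking import detect_puncta

__all__ = ["CountResult", "max_project", "count_spots", "compare_counts"]


@dataclass(frozen=True)
class CountResult:
    """Spot count for one embryo in one ROI, with detection provenance."""

    embryo_id: str
    roi_name: str
    count: int
    min_intensity: float
    min_separation: float
    positions: pd.DataFrame = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z — the "compressed" stack counted on."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3:
        raise ValueError(f"expected a (z, rows, cols) stack, got shape {zstack.shape}")
    return zstack.max(axis=0)


def count_spots(
    image: np.ndarray,
    roi_mask: np.ndarray,
    min_intensity: float,
    min_separation: float,
    *,
    roi_name: str = "roi",
    embryo_id: str = "",
    smooth_sigma: float = 0.0,
) -> CountResult:
    """Count labeled cells whose centroid falls inside the ROI mask.

    Detection is the shared bright-spot detector (local maxima above
    ``min_intensity``, at least ``min_separation`` px apart, centroid
    refined); ``min_separation`` also governs whether spots overlapping in
    projection merge into one count.  On noisy images set ``smooth_sigma``
    to roughly the spot size; ``min_intensity`` then refers to the filtered
    image, whose peaks are lower.
    """
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError(
            f"roi_mask shape {roi_mask.shape} does not match image shape {image.shape}"
        )
    det = detect_puncta(image, min_intensity, min_separation, smooth_sigma=smooth_sigma)
    if det.empty:
        inside = det
    else:
        iy = det["y"].round().astype(int).clip(0, image.shape[0] - 1).to_numpy()
        ix = det["x"].round().astype(int).clip(0, image.shape[1] - 1).to_numpy()
        inside = det[roi_mask[iy, ix]].reset_index(drop=True)
    return CountResult(
        embryo_id=embryo_id,
        roi_name=roi_name,
        count=len(inside),
        min_intensity=min_intensity,
        min_separation=min_separation,
        positions=inside,
    )


def compare_counts(
    group_a: Iterable[int | CountResult],
    group_b: Iterable[int | CountResult],
    *,
    metric: str = "cell_count",
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison of per-embryo counts (mean ± SEM, Student's t)."""
    def _values(group) -> list[float]:
        return [float(g.count) if isinstance(g, CountResult) else float(g) for g in group]

    a, b = _values(group_a), _values(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"insufficient n: need >= 2 embryos per group, got {len(a)} and {len(b)}"
        )
    return compare(metric, a, b, welch=welch)
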