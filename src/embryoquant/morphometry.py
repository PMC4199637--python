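"""Cell-shape circularity and neural-crest stream-width measurement.

Cell circularity is scored by the isoperimetric quotient IQ = 4πA/L², where
A is the region's area and L its outer perimeter: 1 for a perfect circle
and below 1 for irregular shapes — a cell with more filopodia carries more
boundary per unit area and scores lower.

Perimeter estimation matters: naive boundary-pixel counting overestimates L
(depressing IQ), and direction-counting estimators such as 4-direction
Crofton are anisotropic — on cells with straight filopodia edges their
orientation-dependent bias reaches ~10% of IQ.  The estimator used here
reconstructs the outer boundary at subpixel precision instead: the
marching-squares contour of the region is simplified with Douglas–Peucker,
each simplified segment is fit by a total-least-squares line through its
contour points, and adjacent lines are intersected to recover corner
positions (including spike apexes blunted by rasterisation).  L is the
length of the reconstructed polygon.  Its IQ bias is within ~5% of the
analytic value for shapes ≥ 30 px in radius (shrinking as size grows) and
can exceed 1 slightly on near-circular rasters; single-pixel-scale regions
fall back to the raw contour length and are not meaningfully scored.

Stream widths: given labelled masks of the ventrally migrating neural-crest
streams, each stream's width is its extent along the anterior–posterior
axis; the mean over the 6 most anterior streams is the per-embryo summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import approximate_polygon, find_contours, label as sk_label, regionprops
from skimage.morphology import dilation, disk

__all__ = [
    "LabeledRegion",
    "isoperimetric_quotient",
    "perimeter_subpixel",
    "segment_cells",
    "region_metrics",
    "measure_regions",
    "filter_regions",
    "measure_stream_widths",
]


def perimeter_subpixel(mask: np.ndarray, *, dp_tolerance: float = 0.7,
                       max_corner_shift: float = 3.0) -> float:
    """Outer perimeter of a region by subpixel boundary reconstruction.

    The longest (outer) marching-squares contour is simplified with
    Douglas–Peucker at ``dp_tolerance`` px, a total-least-squares line is
    fit to the contour points of every simplified segment, and adjacent
    lines are intersected to place the polygon corners — this extrapolates
    spike apexes that rasterisation blunts.  An intersection farther than
    ``max_corner_shift`` px from the raster corner (near-parallel lines,
    noise) falls back to the raster corner.  Contours of fewer than 8
    points return the raw contour length.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    c = max(contours, key=len)[:-1]  # closed contour; drop repeated endpoint
    if len(c) < 8:
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    ap = approximate_polygon(np.vstack([c, c[:1]]), tolerance=dp_tolerance)
    idx = sorted({int(np.argmin(np.hypot(c[:, 0] - v[0], c[:, 1] - v[1])))
                  for v in ap[:-1]})
    m = len(idx)
    if m < 3:
        d = np.diff(np.vstack([c, c[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    lines = []
    for j in range(m):
        i0, i1 = idx[j], idx[(j + 1) % m]
        seg = c[i0:i1 + 1] if i1 > i0 else np.vstack([c[i0:], c[:i1 + 1]])
        mu = seg.mean(axis=0)
        if len(seg) >= 3:
            direction = np.linalg.svd(seg - mu)[2][0]
        else:
            direction = seg[-1] - seg[0]
            direction = direction / (np.linalg.norm(direction) + 1e-12)
        lines.append((mu, direction))
    verts = []
    for j in range(m):
        (p1, d1), (p2, d2) = lines[j - 1], lines[j]
        a_mat = np.array([[d1[0], -d2[0]], [d1[1], -d2[1]]])
        raster = c[idx[j]]
        if abs(np.linalg.det(a_mat)) < 1e-3:
            verts.append(raster)
            continue
        t = np.linalg.solve(a_mat, p2 - p1)
        pt = p1 + t[0] * d1
        verts.append(pt if float(np.hypot(*(pt - raster))) <= max_corner_shift else raster)
    verts = np.asarray(verts)
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class LabeledRegion:
    """One segmented cell: area, subpixel perimeter and derived IQ."""

    label: int
    area_px: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    bbox: tuple[int, int, int, int]   # (min_row, min_col, max_row, max_col)
    touches_border: bool
    iq: float


def isoperimetric_quotient(area, perimeter):
    """IQ = 4πA/L²; scale-invariant, 1 for a circle, < 1 for irregular shapes.

    Accepts scalars or arrays; rejects non-positive inputs.
    """
    a = np.asarray(area, dtype=float)
    l = np.asarray(perimeter, dtype=float)
    if np.any(a <= 0) or np.any(l <= 0) or not (np.all(np.isfinite(a)) and np.all(np.isfinite(l))):
        raise ValueError("area and perimeter must be finite and positive")
    iq = 4.0 * np.pi * a / l ** 2
    return float(iq) if iq.ndim == 0 else iq


def segment_cells(image: np.ndarray, threshold="auto") -> np.ndarray:
    """Threshold and label cells (8-connectivity).

    ``threshold="auto"`` splits a bimodal histogram with Otsu's method;
    pixels ≥ threshold are foreground.  An all-background result is a valid
    empty label image, as is a threshold above the image maximum.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if threshold == "auto":
        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=int)
        threshold = threshold_otsu(image)
    mask = image >= float(threshold)
    return sk_label(mask, connectivity=2)


def _region_record(prop, scale: float, shape: tuple[int, int]) -> LabeledRegion:
    area_px = float(prop.area)
    perim_px = perimeter_subpixel(prop.image)
    minr, minc, maxr, maxc = prop.bbox
    touches = minr == 0 or minc == 0 or maxr == shape[0] or maxc == shape[1]
    return LabeledRegion(
        label=int(prop.label),
        area_px=area_px,
        area_um2=area_px * scale ** 2,
        perimeter_px=perim_px,
        perimeter_um=perim_px * scale,
        bbox=(minr, minc, maxr, maxc),
        touches_border=touches,
        iq=isoperimetric_quotient(area_px, perim_px) if perim_px > 0 else float("nan"),
    )


def region_metrics(mask: np.ndarray, scale: float = 1.0, *, label: int = 1) -> LabeledRegion:
    """Metrics of a single region given its boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    props = regionprops(mask.astype(int))
    return replace(_region_record(props[0], scale, mask.shape), label=label)


def measure_regions(labels: np.ndarray, scale: float = 1.0) -> pd.DataFrame:
    """Per-region metrics table for a labelled image.

    Columns: label, area_px, area_um2, perimeter_px, perimeter_um, iq,
    touches_border plus the bbox corners.  Single-pixel regions get a small
    positive contour perimeter, so IQ stays defined (but is meaningless at
    that scale).
    """
    labels = np.asarray(labels)
    rows = []
    for prop in regionprops(labels):
        rec = _region_record(prop, scale, labels.shape)
        rows.append({
            "label": rec.label,
            "area_px": rec.area_px, "area_um2": rec.area_um2,
            "perimeter_px": rec.perimeter_px, "perimeter_um": rec.perimeter_um,
            "iq": rec.iq, "touches_border": rec.touches_border,
            "min_row": rec.bbox[0], "min_col": rec.bbox[1],
            "max_row": rec.bbox[2], "max_col": rec.bbox[3],
        })
    return pd.DataFrame(rows, columns=[
        "label", "area_px", "area_um2", "perimeter_px", "perimeter_um", "iq",
        "touches_border", "min_row", "min_col", "max_row", "max_col"])


def filter_regions(
    labels: np.ndarray,
    *,
    scale: float = 1.0,
    area_range_um2: tuple[float, float] | None = None,
    border_exclusion: bool = True,
    isolation_px: int = 3,
) -> tuple[list[int], pd.DataFrame]:
    """Keep only whole, isolated cells; log a reason for every drop.

    Drops regions that touch the image border (clipped cells), fall outside
    ``area_range_um2`` (debris or fused cells), or have another region
    within an ``isolation_px`` dilation of their footprint (not isolated).
    All rules are evaluated for every region; reasons are ``;``-joined.

    Returns (kept labels, log DataFrame with columns label, kept, reasons).
    """
    labels = np.asarray(labels)
    table = measure_regions(labels, scale)
    selem = disk(isolation_px)
    rows, kept = [], []
    for _, r in table.iterrows():
        reasons = []
        if border_exclusion and r["touches_border"]:
            reasons.append("border")
        if area_range_um2 is not None:
            lo, hi = area_range_um2
            if not (lo <= r["area_um2"] <= hi):
                reasons.append("area")
        if isolation_px > 0:
            dilated = dilation(labels == r["label"], selem)
            neighbours = np.unique(labels[dilated])
            if any(n not in (0, r["label"]) for n in neighbours):
                reasons.append("not-isolated")
        rows.append((int(r["label"]), not reasons, ";".join(reasons)))
        if not reasons:
            kept.append(int(r["label"]))
    log = pd.DataFrame(rows, columns=["label", "kept", "reasons"])
    return kept, log


def measure_stream_widths(
    stream_masks: Sequence[np.ndarray] | np.ndarray,
    *,
    ap_axis: str = "x",
    scale: float = 1.0,
    n_streams: int = 6,
) -> tuple[float, pd.DataFrame]:
    """Mean anterior–posterior width of the most anterior migration streams.

    ``stream_masks`` is either a labelled image or a list of binary masks,
    one per stream.  Width = pixel extent along the AP axis × scale;
    anterior = smaller coordinate along that axis.  Streams are ordered by
    their anterior edge and the mean is taken over the ``n_streams`` most
    anterior (default 6, the per-embryo summary); fewer streams is an error.

    Returns (mean width in µm, per-stream table ordered anterior→posterior).
    """
    if ap_axis not in ("x", "y"):
        raise ValueError("ap_axis must be 'x' (columns) or 'y' (rows)")
    axis = 1 if ap_axis == "x" else 0

    masks: list[np.ndarray]
    arr = np.asarray(stream_masks[0]) if isinstance(stream_masks, (list, tuple)) else np.asarray(stream_masks)
    if isinstance(stream_masks, (list, tuple)):
        masks = [np.asarray(m, dtype=bool) for m in stream_masks]
    else:
        masks = [arr == lab for lab in np.unique(arr) if lab != 0]

    rows = []
    for i, m in enumerate(masks):
        coords = np.argwhere(m)
        if coords.size == 0:
            continue
        lo = int(coords[:, axis].min())
        hi = int(coords[:, axis].max())
        rows.append({"stream": i, "anterior_edge_px": lo,
                     "width_px": hi - lo + 1, "width_um": (hi - lo + 1) * scale})
    if len(rows) < n_streams:
        raise ValueError(
            f"need at least {n_streams} streams, found {len(rows)}"
        )
    table = pd.DataFrame(rows).sort_values("anterior_edge_px", kind="stable").reset_index(drop=True)
    mean_width = float(table["width_um"].iloc[:n_streams].mean())
    return mean_width, table
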