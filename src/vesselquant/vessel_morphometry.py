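"""Per-vessel and per-image morphometric metrics.

Vessel size is the minimal Feret diameter — the minimum over orientations
of the distance between two parallel tangents of the object ("caliper
width").  On a section, a tube cut obliquely elongates in one direction
only, so the minimal caliper is robust to non-tangential sectioning and
is the size measure used throughout.

The perivascular compartment of each vessel is the band of pixels within
a fixed Euclidean distance (default 10 px, i.e. 2.5 um at 4 px/um) of the
vessel footprint, excluding all vessel pixels; mural-marker (a-SMA) OD is
scored only inside those bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .images import pixel_area_mm2


class UndefinedMetric(Exception):
    """A metric is undefined for this input (e.g. no vessels, no stroma)."""


# ---------------------------------------------------------------------------
# minimal Feret diameter (rotating calipers)
# ---------------------------------------------------------------------------

def _pixel_corner_points(coords: np.ndarray) -> np.ndarray:
    """All 4 corner points of each pixel (r, c) -> (r±0.5, c±0.5)."""
    coords = np.asarray(coords, dtype=float)
    offsets = np.array(
        [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=float
    )
    return (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def min_width_convex(points: np.ndarray) -> float:
    """Minimal caliper width of a planar point set.

    The minimum width of a convex polygon is attained with one caliper
    jaw flush against an edge, so scanning hull edges and taking the
    farthest-vertex distance for each is exact (rotating calipers).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points")
    hull = ConvexHull(points)
    pts = points[hull.vertices]
    n = len(pts)
    best = np.inf
    for i in range(n):
        p = pts[i]
        q = pts[(i + 1) % n]
        e = q - p
        ln = np.hypot(*e)
        if ln == 0:
            continue
        normal = np.array([-e[1], e[0]]) / ln
        proj = (pts - p) @ normal
        best = min(best, float(proj.max() - proj.min()))
    return best


def min_feret(footprint, resolution_px_per_um: float) -> float:
    """Minimal Feret diameter of a pixel footprint, in micrometres.

    ``footprint`` is a boolean mask or an ``(N, 2)`` array of pixel
    (row, col) indices.  The caliper is computed on the convex hull of
    the pixel *corner* points, so a single pixel has width 1 px.
    """
    footprint = np.asarray(footprint)
    if footprint.ndim == 2 and footprint.dtype == bool:
        coords = np.argwhere(footprint)
    else:
        coords = footprint.reshape(-1, 2)
    if coords.shape[0] == 0:
        raise ValueError("empty footprint")
    width_px = min_width_convex(_pixel_corner_points(coords))
    return width_px / resolution_px_per_um


# ---------------------------------------------------------------------------
# image-level metrics
# ---------------------------------------------------------------------------

def vessel_density(n_vessels: int, tissue_area_mm2: float) -> float:
    """Detected vessels per mm**2 of analyzed tissue."""
    if not tissue_area_mm2 > 0:
        raise ValueError("tissue area must be positive")
    return n_vessels / tissue_area_mm2


def median_vessel_diameter(diameters_um) -> float:
    """Median of per-vessel minimal Feret diameters (midpoint for even n)."""
    diameters_um = np.asarray(diameters_um, dtype=float)
    if diameters_um.size == 0:
        raise UndefinedMetric("no vessels: median diameter undefined")
    return float(np.median(diameters_um))


def perivascular_rings(
    labels: np.ndarray, ring_distance_px: int = 10
) -> np.ndarray:
    """Per-vessel perivascular bands as a labeled raster.

    Returns an int array shaped like ``labels`` where pixel value ``k > 0``
    means the pixel lies within ``ring_distance_px`` (Euclidean) of vessel
    ``k``'s footprint, is not part of any vessel, and vessel ``k`` is the
    nearest vessel (ties broken toward the lower label).  Bands are
    clipped at image borders.
    """
    labels = np.asarray(labels)
    if ring_distance_px <= 0:
        raise ValueError("ring_distance_px must be positive")
    vessel_mask = labels > 0
    ring_labels = np.zeros(labels.shape, dtype=np.int32)
    best_dist = np.full(labels.shape, np.inf)
    pad = ring_distance_px + 1
    for sl, lab in zip(
        ndimage.find_objects(labels), range(1, int(labels.max()) + 1)
    ):
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, labels.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, labels.shape[1])
        win = (slice(r0, r1), slice(c0, c1))
        dist = ndimage.distance_transform_edt(labels[win] != lab)
        upd = dist < best_dist[win]  # strict: earlier (lower) label keeps ties
        best_dist[win][upd] = dist[upd]
        ring_labels[win][upd] = lab
    in_band = (best_dist > 0) & (best_dist <= ring_distance_px) & ~vessel_mask
    ring_labels[~in_band] = 0
    return ring_labels


def perivascular_intensity(
    ring_labels: np.ndarray, sma_od: np.ndarray
) -> tuple[dict[int, float], float]:
    """Median mural-marker OD per vessel band, and the pooled image PVI.

    The image PVI is the median OD over *all* band pixels of the image;
    marker signal outside perivascular bands is ignored.  Vessels whose
    band is empty (fully occluded by neighbors/borders) are omitted.
    """
    ring_labels = np.asarray(ring_labels)
    sma_od = np.asarray(sma_od, dtype=float)
    if ring_labels.shape != sma_od.shape:
        raise ValueError("ring labels and OD map must be co-registered")
    in_band = ring_labels > 0
    per_vessel: dict[int, float] = {}
    for lab in np.unique(ring_labels[in_band]):
        per_vessel[int(lab)] = float(np.median(sma_od[ring_labels == lab]))
    if not per_vessel:
        raise UndefinedMetric("no perivascular pixels: PVI undefined")
    pvi = float(np.median(sma_od[in_band]))
    return per_vessel, pvi


def fraction_covered(per_vessel_pv_od, cutoff: float) -> float:
    """Fraction of vessels whose perivascular OD exceeds the cutoff.

    Strict inequality: a vessel exactly at the cutoff counts as
    uncovered.  The cutoff convention (cohort-level median by default)
    is decided by the caller.
    """
    vals = np.asarray(list(per_vessel_pv_od), dtype=float)
    if vals.size == 0:
        raise UndefinedMetric("no vessels: FCV undefined")
    return float(np.mean(vals > cutoff))


def stromal_metrics(
    sma_od: np.ndarray,
    vessel_mask: np.ndarray,
    resolution_px_per_um: float,
    exclusion_mask: np.ndarray | None = None,
    stroma_threshold_od: float = 0.15,
) -> tuple[float, float | None]:
    """Marker-defined stromal area (mm**2) and its median OD.

    Stroma = pixels with a-SMA OD >= threshold, outside vessels and
    exclusions.  Returns ``(area_mm2, median_od)``; the median is ``None``
    when no stroma pixel exists (area 0).
    """
    sma_od = np.asarray(sma_od, dtype=float)
    stroma = (sma_od >= stroma_threshold_od) & ~np.asarray(vessel_mask, dtype=bool)
    if exclusion_mask is not None:
        stroma &= ~np.asarray(exclusion_mask, dtype=bool)
    n = int(stroma.sum())
    area = pixel_area_mm2(n, resolution_px_per_um)
    if n == 0:
        return 0.0, None
    return area, float(np.median(sma_od[stroma]))


# ---------------------------------------------------------------------------
# per-image bundle
# ---------------------------------------------------------------------------

@dataclass
class ImageMetrics:
    """All tissue metrics of one core / ROI image."""

    image_id: str
    tissue_area_mm2: float
    n_vessels: int
    vessel_density: float
    diameters_um: np.ndarray
    pv_od: np.ndarray  # per-vessel perivascular median OD, aligned to diameters
    pvi: float | None
    stromal_area_mm2: float
    stromal_sma_od_median: float | None
    fcv: float | None = field(default=None)  # filled once a cohort cutoff exists

    @property
    def median_diameter_um(self) -> float | None:
        if self.diameters_um.size == 0:
            return None
        return float(np.median(self.diameters_um))


def compute_image_metrics(
    image_id: str,
    vessel_set,
    sma_od: np.ndarray,
    ring_distance_px: int = 10,
    stroma_threshold_od: float = 0.15,
    exclusion_mask: np.ndarray | None = None,
) -> ImageMetrics:
    """Assemble the full metric bundle for one segmented image."""
    labels = vessel_set.labels
    res = vessel_set.resolution_px_per_um
    h, w = labels.shape
    n_px = h * w - (0 if exclusion_mask is None else int(exclusion_mask.sum()))
    area = pixel_area_mm2(n_px, res)
    table = vessel_set.table
    n = len(table)
    if n:
        ring_labels = perivascular_rings(labels, ring_distance_px)
        try:
            per_vessel, pvi = perivascular_intensity(ring_labels, sma_od)
        except UndefinedMetric:
            per_vessel, pvi = {}, None
        pv = np.array([per_vessel.get(int(l), np.nan) for l in table["label"]])
    else:
        pv, pvi = np.array([]), None
    stro_area, stro_med = stromal_metrics(
        sma_od, labels > 0, res, exclusion_mask, stroma_threshold_od
    )
    return ImageMetrics(
        image_id=image_id,
        tissue_area_mm2=area,
        n_vessels=n,
        vessel_density=vessel_density(n, area),
        diameters_um=np.asarray(table["min_feret_um"], dtype=float),
        pv_od=pv,
        pvi=pvi,
        stromal_area_mm2=stro_area,
        stromal_sma_od_median=stro_med,
    )
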