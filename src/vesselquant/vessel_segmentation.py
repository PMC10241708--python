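"""Vessel mask extraction from the CD34 stain layer.

The pipeline mirrors classical ImageJ-style binary processing: intensity
threshold -> despeckle (binary median, r=2) -> repair of broken or hollow
vessel profiles (enlarge, fill holes, mean+median smoothing, shrink) ->
connected-component labeling with a minimal-Feret size floor that drops
single endothelial cells and debris.  Every stage is binary-in/binary-out
and records itself in the mask's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .vessel_morphometry import min_feret


@dataclass
class VesselMask:
    """Binary vessel raster plus the ordered list of steps that produced it."""

    mask: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def with_step(self, mask: np.ndarray, step: str, **params) -> "VesselMask":
        return VesselMask(mask, self.provenance + [{"step": step, **params}])


@dataclass
class VesselSet:
    """Labeled vessel objects on one image.

    ``labels`` is the int label raster (0 = background); ``table`` has one
    row per retained vessel: label, centroid (px), area (um**2), minimal
    Feret diameter (um).
    """

    labels: np.ndarray
    table: pd.DataFrame
    resolution_px_per_um: float

    def __len__(self) -> int:
        return len(self.table)

    def footprint(self, label: int) -> np.ndarray:
        return self.labels == label


def _otsu_threshold(layer: np.ndarray) -> int:
    """Exhaustive between-class-variance sweep over the 0..255 histogram.

    Returns the smallest integer t maximizing the Otsu criterion for the
    split ``layer >= t`` vs ``layer < t``.
    """
    hist = np.bincount(layer.ravel(), minlength=256).astype(float)
    total = hist.sum()
    omega0 = np.cumsum(hist)  # count of values < t is omega0[t-1]
    mu = np.cumsum(hist * np.arange(256))
    best_t, best_var = 1, -1.0
    for t in range(1, 256):
        w0 = omega0[t - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = mu[t - 1] / w0
        mu1 = (mu[255] - mu[t - 1]) / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def binarize(cd34_layer: np.ndarray, threshold: int | str = "otsu") -> VesselMask:
    """Threshold the 8-bit CD34 layer: mask = (layer >= threshold)."""
    layer = np.asarray(cd34_layer)
    if layer.size == 0:
        raise ValueError("empty image")
    if layer.dtype != np.uint8:
        raise ValueError("binarize expects an 8-bit single-channel layer")
    if threshold == "otsu":
        t = _otsu_threshold(layer)
    else:
        t = int(threshold)
        if not 0 <= t <= 255:
            raise ValueError("threshold must be in 0..255")
    mask = layer >= t
    return VesselMask(mask, [{"step": "binarize", "threshold": t,
                              "method": "otsu" if threshold == "otsu" else "fixed"}])


def _majority_filter(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary majority vote over a disc neighborhood (= binary median).

    Border neighborhoods are padded by edge replication so constant masks
    are fixed points.
    """
    footprint = disk(radius_px).astype(np.int32)
    counts = ndimage.correlate(mask.astype(np.int32), footprint, mode="nearest")
    return counts * 2 > footprint.sum()


def despeckle(vm: VesselMask, radius_px: int = 2) -> VesselMask:
    """Binary median filter (disc radius r) removing speckle noise."""
    out = _majority_filter(vm.mask, radius_px)
    return vm.with_step(out, "despeckle", radius_px=radius_px)


def repair_vessels(
    vm: VesselMask, enlarge_radius_px: int = 3, smooth_radius_px: int = 2
) -> VesselMask:
    """Close staining breaks and fill lumina of hollow vessel profiles.

    dilate(r_e) -> fill enclosed holes -> binary mean (majority) filter ->
    binary median filter -> erode(r_e).  A C-shaped wall whose gap is at
    most ``2 * enlarge_radius_px`` wide becomes a closed, filled object of
    approximately the original outer size.  Holes open to the image border
    are not filled.
    """
    se = disk(enlarge_radius_px)
    m = ndimage.binary_dilation(vm.mask, structure=se)
    m = ndimage.binary_fill_holes(m)
    m = _majority_filter(m, smooth_radius_px)  # mean filter, majority rule
    m = _majority_filter(m, smooth_radius_px)  # median filter
    m = ndimage.binary_erosion(m, structure=se, border_value=1)
    steps = [
        ("enlarge", {"radius_px": enlarge_radius_px}),
        ("fill_holes", {}),
        ("mean_filter", {"radius_px": smooth_radius_px}),
        ("median_filter", {"radius_px": smooth_radius_px}),
        ("shrink", {"radius_px": enlarge_radius_px}),
    ]
    out = vm
    for name, params in steps:
        out = out.with_step(out.mask, name, **params)
    return VesselMask(m, out.provenance)


def label_vessels(
    vm: VesselMask,
    resolution_px_per_um: float,
    min_feret_floor_um: float = 4.0,
) -> VesselSet:
    """Label 8-connected components and drop sub-capillary objects.

    Components with minimal Feret diameter below the floor (default 4 um,
    below the smallest capillary profile expected after fixation) are
    discarded — this is the size filter that excludes single CD34+ cells.
    Surviving components are relabeled 1..n in scan order.
    """
    labels, n = ndimage.label(vm.mask, structure=np.ones((3, 3), dtype=int))
    rows = []
    keep = np.zeros(n + 1, dtype=bool)
    um_per_px = 1.0 / resolution_px_per_um
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        foot = labels[sl] == lab
        feret = min_feret(np.argwhere(foot), resolution_px_per_um)
        if feret < min_feret_floor_um:
            continue
        keep[lab] = True
        coords = np.argwhere(foot).astype(float)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        rows.append(
            {
                "label": lab,
                "centroid_y_px": coords[:, 0].mean(),
                "centroid_x_px": coords[:, 1].mean(),
                "area_um2": coords.shape[0] * um_per_px**2,
                "min_feret_um": feret,
            }
        )
    # relabel retained components 1..k, preserving scan order
    new_labels = np.zeros_like(labels)
    mapping = {}
    for new, row in enumerate(rows, start=1):
        mapping[row["label"]] = new
        row["label"] = new
    for old, new in mapping.items():
        new_labels[labels == old] = new
    table = pd.DataFrame(
        rows,
        columns=["label", "centroid_y_px", "centroid_x_px", "area_um2", "min_feret_um"],
    )
    return VesselSet(new_labels, table, resolution_px_per_um)


def segment_image(
    cd34_layer: np.ndarray,
    resolution_px_per_um: float,
    threshold: int | str = "otsu",
    despeckle_radius_px: int = 2,
    enlarge_radius_px: int = 3,
    smooth_radius_px: int = 2,
    min_feret_floor_um: float = 4.0,
) -> tuple[VesselMask, VesselSet]:
    """Full threshold -> despeckle -> repair -> label sequence."""
    vm = binarize(cd34_layer, threshold)
    vm = despeckle(vm, despeckle_radius_px)
    vm = repair_vessels(vm, enlarge_radius_px, smooth_radius_px)
    vessels = label_vessels(vm, resolution_px_per_um, min_feret_floor_um)
    return vm, vessels
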