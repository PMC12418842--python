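"""Membrane ROI extraction from dual-channel Di-4-ANEPPDHQ images.

The original workflow selected plasma-membrane regions by hand; this module
provides a deterministic automated stand-in (Otsu threshold on the summed
channels, hole filling, connected components, ring extraction by erosion
difference) plus loaders for externally supplied masks and polygon ROIs so a
manual workflow remains possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import draw, filters, morphology, segmentation as sk_seg

from .gp import ChannelPair

__all__ = ["MembraneROI", "segment_membranes", "load_roi_masks", "load_roi_polygons"]

DEFAULT_MIN_ROI_PX = 50
DEFAULT_RING_WIDTH = 3


@dataclass(frozen=True)
class MembraneROI:
    """Boolean membrane mask for one cell."""

    mask: np.ndarray
    cell_id: str
    provenance: Literal["manual", "automatic"]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def segment_membranes(
    channels: ChannelPair,
    min_roi_px: int = DEFAULT_MIN_ROI_PX,
    ring_width: int = DEFAULT_RING_WIDTH,
    keep_border: bool = False,
    threshold: float | None = None,
) -> list[MembraneROI]:
    """Extract ring-shaped membrane ROIs from the summed-channel image.

    Pipeline: threshold (Otsu unless a fixed ``threshold`` is given) -> fill
    holes -> label connected components -> drop components smaller than
    ``min_roi_px`` and, unless ``keep_border``, components touching the image
    border -> ring mask = filled component minus its erosion by
    ``ring_width``. Fully deterministic. Returns an empty list (with a
    warning) when nothing survives.
    """
    total = channels.ordered_channel + channels.disordered_channel
    if threshold is None:
        if np.ptp(total) == 0:
            warnings.warn("flat image: no membrane signal found", stacklevel=2)
            return []
        threshold = filters.threshold_otsu(total)
    binary = total > threshold
    filled = ndimage.binary_fill_holes(binary)
    if not keep_border:
        filled = sk_seg.clear_border(filled)
    labels, n = ndimage.label(filled)
    rois: list[MembraneROI] = []
    footprint = morphology.disk(ring_width)
    for k in range(1, n + 1):
        comp = labels == k
        if comp.sum() < min_roi_px:
            continue
        ring = comp & ~morphology.erosion(comp, footprint)
        if ring.sum() < min_roi_px:
            continue
        rois.append(MembraneROI(mask=ring, cell_id=f"auto_{len(rois):03d}",
                                provenance="automatic"))
    if not rois:
        warnings.warn("no membrane component survived filtering", stacklevel=2)
    return rois


def load_roi_masks(path: str | Path, image_shape: tuple[int, int] | None = None,
                   min_roi_px: int = 1) -> list[MembraneROI]:
    """Load ROIs from a labeled 8-bit TIFF mask (0 = background, k = cell k)."""
    labels = tifffile.imread(str(path))
    if labels.ndim != 2:
        raise ValueError(f"{path}: mask must be a single-page 2-D image")
    if image_shape is not None and labels.shape != tuple(image_shape):
        raise ValueError(f"{path}: mask shape {labels.shape} does not match "
                         f"image shape {tuple(image_shape)}")
    rois = []
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = labels == k
        if mask.sum() >= min_roi_px:
            rois.append(MembraneROI(mask=mask, cell_id=f"manual_{int(k):03d}",
                                    provenance="manual"))
    return rois


def load_roi_polygons(path: str | Path, image_shape: tuple[int, int]) -> list[MembraneROI]:
    """Load ROIs from a polygon table ``cell_id, vertex_index, row, col``.

    Vertices are 0-based pixel coordinates; each polygon is filled on the
    pixel grid (even-odd rule, vertices inclusive). Polygons must be simple.
    """
    table = pd.read_csv(path, comment="#")
    required = {"cell_id", "vertex_index", "row", "col"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    rois = []
    for cell_id, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        r = grp["row"].to_numpy(float)
        c = grp["col"].to_numpy(float)
        if len(r) < 3:
            raise ValueError(f"polygon {cell_id!r}: need at least 3 vertices")
        if _self_intersects(r, c):
            raise ValueError(f"polygon {cell_id!r} is self-intersecting")
        rr, cc = draw.polygon(r, c, shape=image_shape)
        mask = np.zeros(image_shape, dtype=bool)
        mask[rr, cc] = True
        # skimage.draw.polygon excludes some boundary pixels; add the outline
        rr, cc = draw.polygon_perimeter(r, c, shape=image_shape)
        mask[rr, cc] = True
        rois.append(MembraneROI(mask=mask, cell_id=str(cell_id), provenance="manual"))
    return rois


def _self_intersects(r: np.ndarray, c: np.ndarray) -> bool:
    """Brute-force segment intersection check for small polygons."""
    pts = list(zip(r, c))
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]

    def ccw(a, b, c_):
        return (c_[1] - a[1]) * (b[0] - a[0]) > (b[1] - a[1]) * (c_[0] - a[0])

    def crosses(s1, s2):
        a, b = s1
        c_, d = s2
        return (ccw(a, c_, d) != ccw(b, c_, d)) and (ccw(a, b, c_) != ccw(a, b, d))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # shared endpoint
            if crosses(segs[i], segs[j]):
                return True
    return False
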