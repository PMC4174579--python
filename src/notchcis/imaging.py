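"""Image quantification: segmentation, local background, per-cell means.

Mirrors a standard fixed-cell fluorescence workflow: cells are segmented on
a cytoplasmic-stain channel, the local background of each cell is the
median of unsegmented pixels in an annular neighborhood, and the cell's
mean fluorescence in every channel is the mean of background-subtracted
pixels.  Doublets and clumps are removed afterwards by an area gate and a
mask-separation (isolation) gate rather than by manual screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_li, threshold_mean, threshold_otsu
from skimage.measure import label as cc_label

log = logging.getLogger(__name__)

__all__ = ["CellMeasurement", "segment_cytoplasm", "measure_cells", "gate_cells"]

_THRESHOLDS = {"otsu": threshold_otsu, "li": threshold_li, "mean": threshold_mean}


@dataclass
class CellMeasurement:
    """Per-cell geometry and background-subtracted mean fluorescence."""

    cell_id: int
    area: int
    centroid: tuple[float, float]
    mean_fluor: dict[str, float]
    touches_neighbor: bool = False
    passes_area_gate: bool = True
    background_fallback: bool = False


def segment_cytoplasm(cyto_channel: np.ndarray, min_area: int = 50,
                      threshold_method: str = "otsu",
                      smooth_sigma: float = 2.0) -> np.ndarray:
    """Label mask from the cytoplasmic-stain channel.

    Gaussian smoothing followed by a global threshold and connected-component
    labelling; components below ``min_area`` pixels are dropped.  Returns an
    integer mask with background 0.  A blank image yields an empty mask.
    """
    img = np.asarray(cyto_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thresh = _THRESHOLDS[threshold_method](smoothed)
    labels = cc_label(smoothed > thresh)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area)
    labels[np.isin(labels, small)] = 0
    # relabel consecutively so cell ids stay dense after the area filter
    return cc_label(labels > 0).astype(np.int32)


def measure_cells(image: np.ndarray, mask: np.ndarray,
                  channels: list[str] | None = None,
                  neighborhood_radius: int = 20) -> list[CellMeasurement]:
    """Background-subtracted per-cell mean fluorescence in every channel.

    For each cell the background is the median of unsegmented pixels within
    a dilation of ``neighborhood_radius`` pixels around the cell mask; the
    cell's mean is the mean over its own pixels of (pixel - background).
    Negative means are recorded as-is.  If a cell's neighborhood contains
    no unsegmented pixels the global unsegmented median is used and the
    measurement is flagged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None, :, :]
    if channels is None:
        channels = [f"ch{i}" for i in range(image.shape[0])]
    if len(channels) != image.shape[0]:
        raise ValueError("channels must match image channel count")
    if image.shape[1:] != mask.shape:
        raise ValueError("mask and image must share spatial shape")

    unseg = mask == 0
    global_median = {ch: float(np.median(image[ci][unseg])) if unseg.any() else 0.0
                     for ci, ch in enumerate(channels)}
    structure = _disk(neighborhood_radius)
    out: list[CellMeasurement] = []
    objects = ndi.find_objects(mask)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = neighborhood_radius + 1
        win = (slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, mask.shape[0])),
               slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, mask.shape[1])))
        sub_mask = mask[win]
        own = sub_mask == idx
        hood = ndi.binary_dilation(own, structure=structure) & (sub_mask == 0)
        fallback = not hood.any()
        ys, xs = np.nonzero(own)
        means: dict[str, float] = {}
        for ci, ch in enumerate(channels):
            sub = image[ci][win]
            bg = global_median[ch] if fallback else float(np.median(sub[hood]))
            means[ch] = float(sub[own].mean() - bg)
        centroid = (float(ys.mean() + win[0].start), float(xs.mean() + win[1].start))
        out.append(CellMeasurement(cell_id=idx, area=int(own.sum()),
                                   centroid=centroid, mean_fluor=means,
                                   background_fallback=fallback))
    return out


def gate_cells(measurements: list[CellMeasurement], mask: np.ndarray,
               area_range: tuple[float, float] = (100.0, 5000.0),
               isolation_distance: float = 5.0) -> list[CellMeasurement]:
    """Keep single, isolated cells.

    A cell passes if its area lies in ``area_range`` and the minimum gap
    between its mask and any other cell's mask exceeds
    ``isolation_distance`` pixels (surrogate for the by-eye screening of
    touching cells and doublets).  Reject counts per reason are logged.
    """
    lo, hi = area_range
    if not lo < hi:
        raise ValueError("area_range must satisfy lo < hi")
    kept, n_area, n_iso = [], 0, 0
    for m in measurements:
        sep = _mask_separation(mask, m.cell_id)
        m.touches_neighbor = sep <= isolation_distance
        m.passes_area_gate = lo <= m.area <= hi
        if not m.passes_area_gate:
            n_area += 1
        elif m.touches_neighbor:
            n_iso += 1
        else:
            kept.append(m)
    log.info("gate_cells: kept %d of %d (%d area-rejected, %d isolation-rejected)",
             len(kept), len(measurements), n_area, n_iso)
    return kept


def measurements_to_table(measurements: list[CellMeasurement]) -> pd.DataFrame:
    """Flatten measurements into a DataFrame (one column per channel)."""
    rows = []
    for m in measurements:
        row = {"cell_id": m.cell_id, "area": m.area,
               "centroid_y": m.centroid[0], "centroid_x": m.centroid[1],
               "touches_neighbor": m.touches_neighbor,
               "passes_area_gate": m.passes_area_gate}
        row.update({f"mean_{ch}": v for ch, v in m.mean_fluor.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def _mask_separation(mask: np.ndarray, cell_id: int) -> float:
    """Minimum Euclidean gap between one cell's mask and all other masks."""
    others = (mask > 0) & (mask != cell_id)
    if not others.any():
        return np.inf
    dist = ndi.distance_transform_edt(~others)
    return float(dist[mask == cell_id].min())
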