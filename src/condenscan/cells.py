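"""Cell segmentation and per-cell geometry.

Segmentation here is a deliberately simple threshold(+watershed) pipeline
tuned for the simulator's fluorescence silhouettes; externally produced
label masks (e.g. from Cellpose) are accepted verbatim.  Per-cell length,
width and orientation come from principal-axis extents of the label's
pixels, and volumes from the spherocylinder closed form.

Conventions: coordinates are 0-based pixel indices referring to pixel
centers; multiplying by the pixel size gives µm.  Point coordinates are
(x, y) = (column, row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .geometry import spherocylinder_volume

__all__ = [
    "CellMask",
    "CellShape",
    "segment_cells",
    "cell_axes",
    "cell_volume_from_mask",
    "shape_table",
    "normalize_cell_coordinates",
    "spherocylinder_volume",
]


@dataclass
class CellMask:
    """Integer label image (0 = background) plus the pixel size (µm/px)."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def cell_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)


@dataclass
class CellShape:
    label: int
    centroid_px: tuple[float, float]     # (x, y)
    orientation: float                   # rad, long axis vs x axis
    length_um: float
    width_um: float
    volume_um3: float


def segment_cells(
    image: np.ndarray,
    pixel_size: float,
    blur_sigma: float = 0.066,
    method: str = "threshold-watershed",
    external_mask: np.ndarray | None = None,
    min_area_px: int = 30,
) -> CellMask:
    """Segment cells in a single frame.

    ``blur_sigma`` is in µm (default 0.066, i.e. one pixel at the default
    pixel size).  ``method='external-mask'`` wraps a precomputed label
    image, applying only the border filter.  The built-in fallback is an
    Otsu threshold with a watershed pass that splits merged components.
    Cells touching the image border are removed; an empty image yields
    zero labels.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if method == "external-mask":
        if external_mask is None:
            raise ValueError("external-mask method requires external_mask")
        labels = np.asarray(external_mask).astype(np.int32)
    elif method == "threshold-watershed":
        img = np.asarray(image, dtype=float)
        if blur_sigma > 0:
            img = ndimage.gaussian_filter(img, blur_sigma / pixel_size)
        if np.ptp(img) == 0:
            return CellMask(np.zeros(img.shape, dtype=np.int32), pixel_size)
        binary = img > threshold_otsu(img)
        lab = measure.label(binary)
        areas = np.bincount(lab.ravel())
        binary = areas[lab] >= min_area_px
        binary[lab == 0] = False
        if not binary.any():
            return CellMask(np.zeros(img.shape, dtype=np.int32), pixel_size)
        labels = measure.label(binary).astype(np.int32)
        labels = _split_merged(labels, binary)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    labels = segmentation.clear_border(labels)
    labels = measure.label(labels > 0).astype(np.int32)
    # re-apply the size filter after border clearing
    for lab in np.unique(labels):
        if lab and (labels == lab).sum() < min_area_px:
            labels[labels == lab] = 0
    labels = measure.label(labels > 0).astype(np.int32)
    return CellMask(labels, pixel_size)


def _split_merged(labels: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Watershed pass on components much larger than the median cell."""
    areas = np.bincount(labels.ravel())[1:]
    if len(areas) < 2:
        return labels
    median_area = np.median(areas)
    big = np.flatnonzero(areas > 2.2 * median_area) + 1
    if len(big) == 0:
        return labels
    out = labels.copy()
    next_label = labels.max() + 1
    for lab in big:
        region = labels == lab
        dist = ndimage.distance_transform_edt(region)
        peaks = peak_local_max(dist, labels=region,
                               min_distance=max(3, int(dist.max())),
                               exclude_border=False)
        if len(peaks) < 2:
            continue
        markers = np.zeros_like(labels)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = segmentation.watershed(-dist, markers, mask=region)
        out[region] = 0
        for i in range(1, ws.max() + 1):
            out[ws == i] = next_label
            next_label += 1
    return measure.label(out > 0).astype(np.int32)


def _principal_axes(coords_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, major-axis unit vector and orientation from pixel coords."""
    centroid = coords_xy.mean(axis=0)
    cov = np.cov((coords_xy - centroid).T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major = evecs[:, np.argmax(evals)]
    if major[0] < 0:
        major = -major
    theta = math.atan2(major[1], major[0])
    return centroid, major, theta


def cell_axes(mask: CellMask, label: int) -> CellShape:
    """Length, width and orientation of one labeled cell.

    Length and width are the maximum extents of the pixel footprint along
    and across the major principal axis (plus one pixel to account for
    the footprint of the edge pixels), converted to µm.
    """
    rc = np.argwhere(mask.labels == label)
    if len(rc) == 0:
        raise KeyError(f"label {label} not present in mask")
    coords = rc[:, ::-1].astype(float)           # (x, y)
    centroid, major, theta = _principal_axes(coords)
    minor = np.array([-major[1], major[0]])
    d = coords - centroid
    len_px = np.ptp(d @ major) + 1.0
    wid_px = np.ptp(d @ minor) + 1.0
    if wid_px > len_px:
        len_px, wid_px = wid_px, len_px
        theta = math.atan2(minor[1], minor[0])
    length = len_px * mask.pixel_size
    width = wid_px * mask.pixel_size
    return CellShape(
        label=int(label),
        centroid_px=(float(centroid[0]), float(centroid[1])),
        orientation=theta,
        length_um=length,
        width_um=width,
        volume_um3=spherocylinder_volume(max(length, width), min(length, width)),
    )


def cell_volume_from_mask(mask: CellMask, label: int) -> float:
    """Spherocylinder volume (µm³) with the width refined from the area.

    Extent-based widths carry a fraction-of-a-pixel negative bias that
    enters the volume quadratically; pixel counting of the silhouette
    area is unbiased, so the width is recovered by inverting the 2D
    silhouette area of a spherocylinder, A = wL − w² + πw²/4, given the
    extent-based length L.  Falls back to the extent-based width when
    the inversion has no root in (0, L].
    """
    s = cell_axes(mask, label)
    area = float((mask.labels == label).sum()) * mask.pixel_size**2
    L = s.length_um
    a = math.pi / 4.0 - 1.0
    disc = L * L + 4.0 * a * area
    width = s.width_um
    if disc > 0:
        w = (-L + math.sqrt(disc)) / (2.0 * a)
        if 0 < w <= L * (1 + 1e-9):
            width = min(w, L)
    return spherocylinder_volume(max(L, width), min(L, width))


def shape_table(mask: CellMask) -> pd.DataFrame:
    """Per-cell geometry as a tidy table (one row per label)."""
    rows = []
    for lab in mask.cell_labels:
        s = cell_axes(mask, int(lab))
        rows.append({
            "label": s.label,
            "centroid_x": s.centroid_px[0],
            "centroid_y": s.centroid_px[1],
            "orientation_rad": s.orientation,
            "length_um": s.length_um,
            "width_um": s.width_um,
            "volume_um3": s.volume_um3,
        })
    return pd.DataFrame(rows)


def normalize_cell_coordinates(
    mask: CellMask,
    label: int,
    points_px: np.ndarray,
    shape: CellShape | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map (x, y) pixel points into the normalized cell frame [−1, 1]².

    The cell centroid maps to (0, 0), the poles to (±1, 0) and the
    lateral edges to (0, ±1).  Points outside the labeled cell are
    flagged ``False`` in the returned boolean mask and their coordinates
    are still computed but should be excluded by the caller.
    """
    shape = shape or cell_axes(mask, label)
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    c, s = math.cos(shape.orientation), math.sin(shape.orientation)
    rot = np.array([[c, s], [-s, c]])
    local = (pts - np.asarray(shape.centroid_px)) @ rot.T
    half_len = shape.length_um / mask.pixel_size / 2.0
    half_wid = shape.width_um / mask.pixel_size / 2.0
    norm = np.column_stack([local[:, 0] / half_len, local[:, 1] / half_wid])
    idx = np.rint(pts).astype(int)
    ny, nx = mask.labels.shape
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
    )
    ok = inside.copy()
    ok[inside] = mask.labels[idx[inside, 1], idx[inside, 0]] == label
    return norm, ok
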