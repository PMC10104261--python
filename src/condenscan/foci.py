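"""Focus detection, condensation coefficients, partitioning and FRAP.

Per-cell pixel intensities are background-corrected (median of the
pixels outside all cell regions) and min–max normalized within the cell,

    I_n = (I − I_min) / (I_max − I_min),

before focus detection and condensation statistics.  The condensation
coefficient of a cell is the fraction of its pixels with normalized
intensity below a threshold (0.3, 0.5, 0.7); strongly clustered signal
pushes most pixels towards the bottom of the range, so higher fractions
mean stronger condensation.  Relative coefficients divide by the mean
fraction of a homogeneous control population (free fluorophore).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .cells import CellMask
from .io import ImageStack

__all__ = [
    "FocusParams",
    "Focus",
    "FrapCurve",
    "background_level",
    "normalize_pixels",
    "detect_foci",
    "foci_table",
    "condensation_coefficients",
    "partition_ratio",
    "percent_with_focus",
    "frap_normalize",
]

CONDENSATION_THRESHOLDS = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class FocusParams:
    """Detection-filter settings.

    Defaults follow the printed Methods values: minimum area 4 px,
    eccentricity at most 0.75 (keep round objects, reject streaks),
    detection threshold 0.5 on the normalized intensity and a 0.066-µm
    Gaussian pre-blur.
    """

    blur_sigma: float = 0.066         # µm
    intensity_threshold: float = 0.5  # on normalized intensity
    min_area: int = 4                 # px
    eccentricity_max: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity_threshold < 1.0:
            raise ValueError("intensity_threshold must be in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if not 0.0 <= self.eccentricity_max <= 1.0:
            raise ValueError("eccentricity_max must be in [0, 1]")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass
class Focus:
    cell_label: int
    centroid_px: tuple[float, float]      # (x, y)
    area_px: int
    eccentricity: float
    mean_intensity: float                 # background-corrected counts
    total_intensity: float
    pixels: np.ndarray = field(repr=False)  # (n, 2) row/col indices


@dataclass
class FrapCurve:
    time: np.ndarray
    values: np.ndarray
    bleach_frame: int
    recovery_fraction: float


def background_level(image: np.ndarray, mask: CellMask) -> float:
    """Median of all pixels outside the cell regions."""
    outside = mask.labels == 0
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(image, dtype=float)[outside]))


def normalize_pixels(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min–max normalize a cell's (background-corrected) pixel values.

    Returns ``(normalized, degenerate)``; a constant cell is flagged
    degenerate and must be excluded from condensation statistics.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values), True
    return (values - lo) / (hi - lo), False


def detect_foci(
    image: np.ndarray | ImageStack,
    mask: CellMask,
    params: FocusParams | None = None,
) -> list[Focus]:
    """Detect foci cell by cell.

    Pipeline per cell: Gaussian blur → background subtraction → min–max
    normalization → binary threshold → connected components → area and
    eccentricity filters.  Intensity statistics are taken from the
    unblurred background-corrected image.
    """
    params = params or FocusParams()
    img = np.asarray(image.data if isinstance(image, ImageStack) else image,
                     dtype=float)
    bg = background_level(img, mask)
    corrected = img - bg
    blurred = (
        ndimage.gaussian_filter(corrected, params.blur_sigma / mask.pixel_size)
        if params.blur_sigma > 0 else corrected
    )
    out: list[Focus] = []
    for lab in mask.cell_labels:
        region = mask.labels == lab
        norm_vals, degenerate = normalize_pixels(blurred[region])
        if degenerate:
            continue
        norm_img = np.zeros(img.shape)
        norm_img[region] = norm_vals
        binary = norm_img > params.intensity_threshold
        binary &= region
        comp = measure.label(binary)
        for rp in measure.regionprops(comp):
            if rp.area < params.min_area or rp.eccentricity > params.eccentricity_max:
                continue
            pix = np.array(rp.coords)
            vals = corrected[pix[:, 0], pix[:, 1]]
            out.append(Focus(
                cell_label=int(lab),
                centroid_px=(float(rp.centroid[1]), float(rp.centroid[0])),
                area_px=int(rp.area),
                eccentricity=float(rp.eccentricity),
                mean_intensity=float(vals.mean()),
                total_intensity=float(vals.sum()),
                pixels=pix,
            ))
    return out


def foci_table(foci: list[Focus]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_label": f.cell_label,
            "x_px": f.centroid_px[0],
            "y_px": f.centroid_px[1],
            "area_px": f.area_px,
            "eccentricity": f.eccentricity,
            "mean_intensity": f.mean_intensity,
            "total_intensity": f.total_intensity,
        }
        for f in foci
    ])


def condensation_coefficients(
    image: np.ndarray | ImageStack,
    mask: CellMask,
    thresholds: tuple[float, ...] = CONDENSATION_THRESHOLDS,
    control_fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell fraction of pixels below each normalized-intensity threshold.

    ``control_fractions`` is the same table computed on a homogeneous
    control population; when given, relative coefficients (fraction ÷
    control mean at the same threshold) are appended.  Degenerate
    (constant) cells are excluded.
    """
    img = np.asarray(image.data if isinstance(image, ImageStack) else image,
                     dtype=float)
    bg = background_level(img, mask)
    rows = []
    for lab in mask.cell_labels:
        vals = img[mask.labels == lab] - bg
        norm, degenerate = normalize_pixels(vals)
        if degenerate:
            continue
        row = {"label": int(lab), "n_pixels": len(norm)}
        for thr in thresholds:
            row[f"frac_below_{thr}"] = float(np.mean(norm < thr))
        rows.append(row)
    table = pd.DataFrame(rows)
    if control_fractions is not None:
        if len(control_fractions) == 0:
            warnings.warn("empty control population; relative coefficients omitted")
        else:
            for thr in thresholds:
                col = f"frac_below_{thr}"
                table[f"relative_{thr}"] = table[col] / control_fractions[col].mean()
    return table


def partition_ratio(
    image: np.ndarray | ImageStack,
    mask: CellMask,
    cell_label: int,
    foci: list[Focus],
    background: float | None = None,
) -> float | None:
    """Dense-phase / dilute-phase intensity ratio for one cell.

    Numerator: the average of the per-focus mean background-corrected
    intensities (all foci of the cell).  Denominator: mean background-
    corrected intensity of the cell excluding all focus pixels.  Returns
    ``None`` for cells without a focus and ``nan`` when the cytoplasm
    mean is non-positive after correction.
    """
    cell_foci = [f for f in foci if f.cell_label == cell_label]
    if not cell_foci:
        return None
    img = np.asarray(image.data if isinstance(image, ImageStack) else image,
                     dtype=float)
    if background is None:
        background = background_level(img, mask)
    corrected = img - background
    numerator = float(np.mean([f.mean_intensity for f in cell_foci]))
    cyto = mask.labels == cell_label
    for f in cell_foci:
        cyto[f.pixels[:, 0], f.pixels[:, 1]] = False
    if not cyto.any():
        return float("nan")
    denom = float(corrected[cyto].mean())
    if denom <= 0:
        return float("nan")
    return numerator / denom


def percent_with_focus(
    images: list[np.ndarray | ImageStack],
    masks: list[CellMask],
    params: FocusParams | None = None,
    timepoints: list[float] | None = None,
) -> pd.DataFrame:
    """Percent of cells with at least one focus, per timepoint.

    Each (image, mask) pair is one timepoint/population; a pair with zero
    segmented cells is an error.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must have equal length")
    rows = []
    for i, (img, mask) in enumerate(zip(images, masks)):
        n_cells = mask.n_cells
        if n_cells == 0:
            raise ValueError(f"timepoint {i}: no cells in mask")
        foci = detect_foci(img, mask, params)
        with_focus = len({f.cell_label for f in foci})
        rows.append({
            "timepoint": timepoints[i] if timepoints else i,
            "n_cells": n_cells,
            "n_with_focus": with_focus,
            "percent": 100.0 * with_focus / n_cells,
        })
    return pd.DataFrame(rows)


def frap_normalize(
    stack: ImageStack,
    bleach_roi: tuple[slice, slice],
    bleach_frame: int,
    background_roi: tuple[slice, slice] | None = None,
    reference_roi: tuple[slice, slice] | None = None,
    plateau_frames: int = 5,
) -> FrapCurve:
    """Background-corrected, anchored FRAP curve.

    The curve is scaled so the last pre-bleach frame is exactly 1 and the
    first post-bleach frame exactly 0.  ``reference_roi`` (an unbleached
    focus) optionally corrects for acquisition photobleaching.  The
    recovery fraction is the mean of the final ``plateau_frames`` frames.
    """
    data = stack.data
    if data.ndim != 3:
        raise ValueError("FRAP requires a T×Y×X stack")
    n_frames, ny, nx = data.shape
    if not 1 <= bleach_frame < n_frames:
        raise ValueError("bleach_frame must leave at least one pre-bleach frame")
    _check_roi(bleach_roi, ny, nx)
    sig = data[:, bleach_roi[0], bleach_roi[1]].mean(axis=(1, 2))
    if background_roi is not None:
        _check_roi(background_roi, ny, nx)
        sig = sig - data[:, background_roi[0], background_roi[1]].mean(axis=(1, 2))
    if reference_roi is not None:
        _check_roi(reference_roi, ny, nx)
        ref = data[:, reference_roi[0], reference_roi[1]].mean(axis=(1, 2))
        if background_roi is not None:
            ref = ref - data[:, background_roi[0], background_roi[1]].mean(axis=(1, 2))
        sig = sig * (ref[bleach_frame - 1] / ref)
    pre = sig[bleach_frame - 1]
    post = sig[bleach_frame]
    if pre == post:
        raise ValueError("no intensity drop at the bleach frame")
    values = (sig - post) / (pre - post)
    time = np.arange(n_frames) * (stack.frame_interval or 1.0)
    recovery = float(values[-plateau_frames:].mean())
    return FrapCurve(time=time, values=values, bleach_frame=bleach_frame,
                     recovery_fraction=recovery)


def _check_roi(roi: tuple[slice, slice], ny: int, nx: int) -> None:
    rs, cs = roi
    r0, r1, _ = rs.indices(ny)
    c0, c1, _ = cs.indices(nx)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("ROI lies outside the image")
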