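"""Two-channel chaperone-colocalization analysis.

Reference foci (e.g. an mCherry fusion) are detected with a 30%-of-image-
maximum intensity threshold and the usual area/eccentricity filters; a
23×23 px region of interest is cut around each centroid in both the
reference and the chaperone (IbpA) channel, each pair normalized to its
reference maximum and averaged across foci.  Both averaged projections
are fitted with a symmetric 2D Gaussian; the chaperone-to-reference FWHM
ratio separates coating (rosette, ratio > 1) from a contained punctum
(ratio < 1), and the chaperone projection maximum gives its relative
intensity in percent of the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage import measure

__all__ = [
    "ColocProjection",
    "GaussianFit",
    "ColocMetrics",
    "detect_reference_foci",
    "extract_and_average",
    "fit_gaussian2d",
    "coloc_metrics",
    "analyze_coloc_pair",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class ColocProjection:
    reference: np.ndarray      # 23×23, max exactly 1
    chaperone: np.ndarray      # same scale as the reference
    n_foci: int
    n_skipped: int             # foci too close to the border
    pixel_size: float


@dataclass
class GaussianFit:
    amplitude: float
    center_px: tuple[float, float]
    sigma_px: float
    offset: float
    fwhm_um: float
    success: bool
    residual: float = float("nan")


@dataclass
class ColocMetrics:
    fwhm_reference_um: float
    fwhm_chaperone_um: float
    fwhm_ratio: float                # chaperone / reference
    relative_max_pct: float          # chaperone max, % of reference max
    n_foci: int


def detect_reference_foci(
    reference: np.ndarray,
    threshold_fraction: float = 0.30,
    min_area: int = 4,
    eccentricity_max: float = 0.75,
    background: float | None = None,
) -> np.ndarray:
    """Centroids (x, y) of reference-channel foci.

    Pixels above ``threshold_fraction`` of the (background-corrected)
    image maximum form candidate components, filtered by minimum area and
    maximum eccentricity.
    """
    img = np.asarray(reference, dtype=float)
    bg = float(np.median(img)) if background is None else background
    corrected = img - bg
    peak = corrected.max()
    if peak <= 0:
        return np.empty((0, 2))
    binary = corrected > threshold_fraction * peak
    centroids = []
    for rp in measure.regionprops(measure.label(binary)):
        if rp.area < min_area or rp.eccentricity > eccentricity_max:
            continue
        centroids.append((rp.centroid[1], rp.centroid[0]))
    return np.array(centroids) if centroids else np.empty((0, 2))


def extract_and_average(
    reference: np.ndarray,
    chaperone: np.ndarray,
    centroids: np.ndarray,
    roi_size: int = 23,
    pixel_size: float = 0.066,
    background_correct: bool = True,
) -> ColocProjection:
    """Cut identical ROIs around each focus in both channels and average.

    Each ROI pair is normalized to the maximum of its reference ROI, then
    averaged across foci; finally both averaged projections are rescaled
    by the averaged reference maximum so the reference peak is exactly 1.
    Foci closer than (roi_size−1)/2 px to a border are skipped (counted).
    """
    if roi_size % 2 == 0:
        raise ValueError("roi_size must be odd")
    ref = np.asarray(reference, dtype=float)
    chap = np.asarray(chaperone, dtype=float)
    if ref.shape != chap.shape:
        raise ValueError("channels must have identical shapes")
    if background_correct:
        ref = ref - np.median(ref)
        chap = chap - np.median(chap)
    half = (roi_size - 1) // 2
    ny, nx = ref.shape
    ref_rois, chap_rois, skipped = [], [], 0
    for x, y in np.atleast_2d(centroids):
        c, r = int(round(x)), int(round(y))
        if not (half <= c < nx - half and half <= r < ny - half):
            skipped += 1
            continue
        r_roi = ref[r - half: r + half + 1, c - half: c + half + 1]
        c_roi = chap[r - half: r + half + 1, c - half: c + half + 1]
        peak = r_roi.max()
        if peak <= 0:
            skipped += 1
            continue
        ref_rois.append(r_roi / peak)
        chap_rois.append(c_roi / peak)
    if not ref_rois:
        raise ValueError("no usable foci (all skipped or empty)")
    ref_proj = np.mean(ref_rois, axis=0)
    chap_proj = np.mean(chap_rois, axis=0)
    scale = ref_proj.max()
    return ColocProjection(
        reference=ref_proj / scale,
        chaperone=chap_proj / scale,
        n_foci=len(ref_rois),
        n_skipped=skipped,
        pixel_size=pixel_size,
    )


def fit_gaussian2d(
    projection: np.ndarray,
    pixel_size: float = 0.066,
) -> GaussianFit:
    """Symmetric 2D Gaussian + offset fit; FWHM = 2√(2 ln 2)·σ·pixel size.

    A projection without a significant positive peak returns a failure
    flag with residual diagnostics.
    """
    data = np.asarray(projection, dtype=float)
    ny, nx = data.shape
    yy, xx = np.indices(data.shape).astype(float)
    offset0 = float(np.median(data))
    amp0 = float(data.max() - offset0)
    if amp0 <= 0 or amp0 < 3 * (data.std() + 1e-12) * 0.1:
        return GaussianFit(0.0, (nx / 2, ny / 2), float("nan"), offset0,
                           float("nan"), success=False,
                           residual=float(np.sum((data - offset0) ** 2)))
    cy, cx = np.unravel_index(np.argmax(data), data.shape)
    above = data - offset0 > amp0 / 2
    sigma0 = max(0.8, math.sqrt(above.sum() / (2 * math.pi)))

    def model(p):
        a, x0, y0, s, o = p
        return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) + o

    p0 = np.array([amp0, float(cx), float(cy), sigma0, offset0])
    try:
        res = optimize.least_squares(
            lambda p: (model(p) - data).ravel(), p0,
            bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, nx, ny, max(nx, ny), np.inf]),
            max_nfev=500,
        )
    except Exception:
        return GaussianFit(0.0, (float(cx), float(cy)), float("nan"), offset0,
                           float("nan"), success=False)
    a, x0, y0, s, o = res.x
    resid = float(np.sum(res.fun**2))
    base_var = float(np.sum((data - data.mean()) ** 2))
    ok = res.success and a > 0 and (base_var == 0 or resid < 0.9 * base_var)
    return GaussianFit(
        amplitude=float(a), center_px=(float(x0), float(y0)),
        sigma_px=float(s), offset=float(o),
        fwhm_um=float(FWHM_PER_SIGMA * s * pixel_size),
        success=bool(ok), residual=resid,
    )


def coloc_metrics(
    ref_fit: GaussianFit,
    chap_fit: GaussianFit,
    projection: ColocProjection,
) -> ColocMetrics:
    """FWHM ratio and relative chaperone intensity for one projection.

    The relative maximum reads directly off the chaperone projection
    (already normalized to the reference maximum), so it is available
    even when the chaperone fit failed; the ratio requires both fits.
    """
    if not ref_fit.success:
        raise ValueError("reference fit failed; metrics undefined")
    ratio = (chap_fit.fwhm_um / ref_fit.fwhm_um
             if chap_fit.success else float("nan"))
    return ColocMetrics(
        fwhm_reference_um=ref_fit.fwhm_um,
        fwhm_chaperone_um=chap_fit.fwhm_um if chap_fit.success else float("nan"),
        fwhm_ratio=ratio,
        relative_max_pct=100.0 * float(projection.chaperone.max()),
        n_foci=projection.n_foci,
    )


def analyze_coloc_pair(
    reference: np.ndarray,
    chaperone: np.ndarray,
    pixel_size: float = 0.066,
    roi_size: int = 23,
    threshold_fraction: float = 0.30,
) -> ColocMetrics:
    """End-to-end: detect reference foci, project, fit both channels."""
    centroids = detect_reference_foci(reference, threshold_fraction)
    if len(centroids) == 0:
        raise ValueError("no reference foci detected")
    proj = extract_and_average(reference, chaperone, centroids,
                               roi_size=roi_size, pixel_size=pixel_size)
    ref_fit = fit_gaussian2d(proj.reference, pixel_size)
    chap_fit = fit_gaussian2d(proj.chaperone, pixel_size)
    return coloc_metrics(ref_fit, chap_fit, proj)
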