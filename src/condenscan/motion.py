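"""Single-molecule localization, tracking and diffusion analysis.

Molecules are localized by fitting an offset 2D Gaussian to candidate
peaks, linked into trajectories by minimum-cost assignment, and each
trajectory's time-averaged MSD is fitted with the motion-blur-corrected
diffusion law.  Because the camera averages the molecule's position over
the exposure, the measured MSD of free 2D diffusion is

    MSD(τ) = 4 D_app (τ − Δt/3) + 4σ²,

where Δt is the frame time and σ the localization precision; at a
one-frame lag this reduces to MSD = (8/3) D_app Δt + 4σ².  Fits use lags
of 1–5 frames (40–200 ms at 40 ms/frame), require at least six steps and
are kept only when R² ≥ 0.7.  The per-track log₁₀ D_app values are
summarized with a two-state Gaussian mixture (slow and fast mobility
modes with weight fractions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.mixture import GaussianMixture

from .cells import CellMask, cell_axes, normalize_cell_coordinates
from .io import ImageStack
from .linking import link_frames
from .photometry import CameraCalibration, counts_to_photons

__all__ = [
    "MSDFit",
    "DiffusionMixture",
    "localize",
    "link",
    "trajectories",
    "fit_msd",
    "fit_msd_table",
    "fit_mixture",
    "build_heatmap",
]


@dataclass
class MSDFit:
    D_app: float
    sigma: float              # µm; nan when the intercept is negative
    sigma_defined: bool
    r_squared: float
    n_steps: int
    accepted: bool
    reason: str = ""
    lags_s: np.ndarray | None = None
    msd: np.ndarray | None = None


@dataclass
class DiffusionMixture:
    """Two-component Gaussian mixture over log₁₀ D_app (slow first)."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    merged: bool              # components closer than their spreads
    degenerate: bool = False


def _gauss2d(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    amp, x0, y0, sigma, offset = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + offset


def _fit_spot(win: np.ndarray, sigma_guess: float,
              fit_sigma: bool = True) -> tuple[np.ndarray, bool]:
    ny, nx = win.shape
    yy, xx = np.indices(win.shape).astype(float)
    offset0 = float(np.median(win))
    amp0 = float(win.max() - offset0)
    cy, cx = np.unravel_index(np.argmax(win), win.shape)
    try:
        if fit_sigma:
            p0 = np.array([max(amp0, 1e-3), float(cx), float(cy),
                           sigma_guess, offset0])
            # moderate prior on the spot width: the PSF scale is known to ~2x
            lo = [0.0, -1.0, -1.0, 0.5 * sigma_guess, -np.inf]
            hi = [np.inf, nx, ny, 2.5 * sigma_guess, np.inf]
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, xx, yy) - win).ravel(), p0,
                bounds=(lo, hi), max_nfev=200,
            )
            return res.x, res.success and res.x[0] > 0
        p0 = np.array([max(amp0, 1e-3), float(cx), float(cy), offset0])
        res = optimize.least_squares(
            lambda p: (_gauss2d([p[0], p[1], p[2], sigma_guess, p[3]],
                                xx, yy) - win).ravel(), p0,
            bounds=([0.0, -1.0, -1.0, -np.inf], [np.inf, nx, ny, np.inf]),
            max_nfev=200,
        )
        params = np.array([res.x[0], res.x[1], res.x[2], sigma_guess, res.x[3]])
        return params, res.success and res.x[0] > 0
    except Exception:
        return np.array([amp0, cx, cy, sigma_guess, offset0]), False


def localize(
    frames: ImageStack | np.ndarray,
    threshold: float,
    psf_sigma_px: float = 1.5,
    pixel_size: float | None = None,
    window: int = 9,
    min_separation_px: int | None = None,
    calibration: CameraCalibration | None = None,
    nominal_em: float = 0.0,
    fit_sigma: bool = True,
) -> pd.DataFrame:
    """Detect and localize sparse single-molecule spots.

    Each frame is median-subtracted; local maxima more than ``threshold``
    counts above the median are fitted with an offset symmetric 2D
    Gaussian on a ``window``-pixel cutout.  The integrated intensity is
    2π·A·σ² counts, converted to photons when a calibration is given.
    ``fit_sigma=False`` pins the width to ``psf_sigma_px`` — the right
    choice for photometry of in-focus molecules with a calibrated PSF,
    since width noise enters the integrated intensity quadratically.
    Diverged fits are dropped; their number is in ``df.attrs['n_failed']``.
    """
    if isinstance(frames, ImageStack):
        pixel_size = pixel_size or frames.pixel_size
        data = frames.data
    else:
        data = np.asarray(frames, dtype=float)
    if pixel_size is None:
        pixel_size = 1.0
    if data.ndim == 2:
        data = data[None]
    half = window // 2
    sep = min_separation_px or max(3, int(round(2 * psf_sigma_px)))
    rows, n_failed = [], 0
    for t, frame in enumerate(data):
        frame = np.asarray(frame, dtype=float)
        sub = frame - np.median(frame)
        maxed = ndimage.maximum_filter(sub, size=2 * sep + 1)
        peaks = np.argwhere((sub == maxed) & (sub > threshold))
        for r, c in peaks:
            if not (half <= r < frame.shape[0] - half
                    and half <= c < frame.shape[1] - half):
                continue
            win = sub[r - half: r + half + 1, c - half: c + half + 1]
            params, ok = _fit_spot(win, psf_sigma_px, fit_sigma)
            if not ok:
                n_failed += 1
                continue
            amp, x0, y0, sigma, _ = params
            x_px, y_px = c - half + x0, r - half + y0
            integrated = 2.0 * math.pi * amp * sigma**2
            photons = (
                float(counts_to_photons(integrated, calibration, nominal_em))
                if calibration is not None else integrated
            )
            rows.append({
                "frame": t, "x_px": x_px, "y_px": y_px,
                "x_um": x_px * pixel_size, "y_um": y_px * pixel_size,
                "photons": photons, "sigma_px": sigma,
            })
    df = pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "x_um", "y_um",
                                     "photons", "sigma_px"])
    df.attrs["n_failed"] = n_failed
    return df


def link(localizations: pd.DataFrame, max_displacement: float) -> pd.DataFrame:
    """Connect localizations into trajectories (gate in µm).

    Returns a copy with a ``track_id`` column.  Localizations in the same
    frame always belong to different tracks; a displacement beyond the
    gate terminates the track.
    """
    df = localizations.sort_values("frame", kind="stable").reset_index(drop=True)
    if len(df) == 0:
        df = df.copy()
        df["track_id"] = pd.Series(dtype=int)
        return df
    ids = link_frames(df["frame"].to_numpy().astype(int),
                      df[["x_um", "y_um"]].to_numpy(), max_displacement)
    df = df.copy()
    df["track_id"] = ids
    return df


def trajectories(linked: pd.DataFrame, min_steps: int = 1) -> dict[int, np.ndarray]:
    """Per-track (n, 2) position arrays in µm, ordered by frame."""
    out = {}
    for tid, grp in linked.groupby("track_id"):
        pos = grp.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        if len(pos) - 1 >= min_steps:
            out[int(tid)] = pos
    return out


def fit_msd(
    positions: np.ndarray,
    frame_time: float = 0.040,
    max_lag_frames: int = 5,
    min_steps: int = 6,
    r2_min: float = 0.7,
) -> MSDFit:
    """Blur-corrected diffusion fit of one trajectory.

    The time-averaged MSD at lags 1..5 frames (40–200 ms by default) is
    regressed on (τ − Δt/3): the slope is 4·D_app and the intercept 4σ².
    A negative intercept keeps D_app but flags σ as undefined.  Tracks
    shorter than ``min_steps`` steps or fits with R² below ``r2_min`` are
    rejected with a reason.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n_steps = len(positions) - 1
    if n_steps < min_steps:
        return MSDFit(np.nan, np.nan, False, np.nan, n_steps, False,
                      reason=f"track has {n_steps} steps < {min_steps}")
    n_lags = min(max_lag_frames, n_steps)
    lags = np.arange(1, n_lags + 1)
    msd = np.array([
        np.mean(np.sum((positions[k:] - positions[:-k]) ** 2, axis=1))
        for k in lags
    ])
    tau = lags * frame_time
    x = tau - frame_time / 3.0
    slope, intercept = np.polyfit(x, msd, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((msd - pred) ** 2))
    ss_tot = float(np.sum((msd - msd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_app = slope / 4.0
    sigma_defined = intercept >= 0
    sigma = math.sqrt(intercept / 4.0) if sigma_defined else float("nan")
    accepted = r2 >= r2_min
    return MSDFit(
        D_app=float(d_app), sigma=sigma, sigma_defined=bool(sigma_defined),
        r_squared=float(r2), n_steps=n_steps, accepted=bool(accepted),
        reason="" if accepted else f"R²={r2:.3f} < {r2_min}",
        lags_s=tau, msd=msd,
    )


def fit_msd_table(
    linked: pd.DataFrame,
    frame_time: float = 0.040,
    **kwargs,
) -> pd.DataFrame:
    """MSD fits for every track in a linked localization table."""
    rows = []
    for tid, pos in trajectories(linked).items():
        fit = fit_msd(pos, frame_time=frame_time, **kwargs)
        rows.append({
            "track_id": tid, "D_app": fit.D_app, "sigma_um": fit.sigma,
            "r_squared": fit.r_squared, "n_steps": fit.n_steps,
            "accepted": fit.accepted, "reason": fit.reason,
        })
    return pd.DataFrame(rows)


def fit_mixture(
    log10_D: np.ndarray,
    k: int = 2,
    seed: int | None = 0,
    n_init: int = 10,
) -> DiffusionMixture:
    """Two-state Gaussian mixture of per-track log₁₀ diffusion coefficients.

    EM with k-means initialization and ``n_init`` seeded restarts.
    Components are ordered slow → fast; ``merged`` marks a pair whose
    means are closer than their pooled spread (effectively one state).
    """
    values = np.asarray(log10_D, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 50:
        warnings.warn(f"only {len(values)} values; mixture fit may be unstable")
    if np.ptp(values) == 0:
        v = float(values[0]) if len(values) else float("nan")
        return DiffusionMixture((v, v), (0.0, 0.0), (1.0, 0.0),
                                merged=True, degenerate=True)
    gm = GaussianMixture(n_components=k, n_init=n_init, init_params="kmeans",
                         random_state=seed)
    gm.fit(values[:, None])
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(c)) for c in gm.covariances_.ravel()[order])
    weights = tuple(float(w) for w in gm.weights_[order])
    # a single mode split in two leaves the component means within their
    # pooled spread; genuinely distinct mobility states sit far apart
    merged = abs(means[1] - means[0]) < (sds[0] + sds[1])
    return DiffusionMixture(means=means, sds=sds, weights=weights, merged=merged)


def build_heatmap(
    localizations: pd.DataFrame,
    mask: CellMask,
    bins: int = 40,
) -> np.ndarray:
    """Normalized, symmetrized localization density on the unit cell.

    Localizations are assigned to cells through the mask, mapped into the
    normalized [−1, 1]² cell frame, histogrammed, symmetrized by
    averaging the four axis reflections, and normalized to total 1.
    """
    if len(localizations) == 0:
        raise ValueError("no localizations to map")
    pts = localizations[["x_px", "y_px"]].to_numpy()
    idx = np.rint(pts).astype(int)
    ny, nx = mask.labels.shape
    valid = (idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
    labels = np.zeros(len(pts), dtype=int)
    labels[valid] = mask.labels[idx[valid, 1], idx[valid, 0]]
    coords = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        shape = cell_axes(mask, int(lab))
        norm, ok = normalize_cell_coordinates(mask, int(lab),
                                              pts[labels == lab], shape)
        coords.append(norm[ok])
    if not coords:
        raise ValueError("no localizations fall inside any cell")
    allc = np.vstack(coords)
    hist, _, _ = np.histogram2d(allc[:, 0], allc[:, 1], bins=bins,
                                range=[[-1, 1], [-1, 1]])
    sym = (hist + hist[::-1, :] + hist[:, ::-1] + hist[::-1, ::-1]) / 4.0
    total = sym.sum()
    if total == 0:
        raise ValueError("empty heat map")
    return sym / total
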