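"""Synthetic snapshot rendering: cells, emitters, and camera frames.

Scenes are composed of spherocylindrical cells containing either discrete
point emitters (single-molecule imaging) or a uniform cytoplasmic photon
density (bulk fluorescence), rendered through a 2D Gaussian PSF and the
EMCCD camera model.  Every generator returns its ground truth alongside
the rendered image.

Coordinate convention: pixel (row j, col i) has its center at
(x, y) = (i, j) * pixel_size µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from ..camera import CameraModel, simulate_camera
from ..constants import MOLECULES_PER_UM3_PER_UM
from ..geometry import CellGeometry, build_cell
from ..io import ImageStack

__all__ = [
    "EmitterEnsemble",
    "SnapshotTruth",
    "populate_cell",
    "add_gaussian_spot",
    "render_photon_map",
    "render_snapshot",
    "CellPopulation",
    "simulate_cell_population",
]

DEFAULT_PIXEL_SIZE = 0.066  # µm per pixel

# Per-frame photon output of a single fluorophore: Gamma with mode 90
# (shape 3, scale 45 -> mean 135).
PHOTON_GAMMA_SHAPE = 3.0
PHOTON_GAMMA_SCALE = 45.0


@dataclass
class EmitterEnsemble:
    """Point emitters inside one or more cells.

    positions : (N, 2) µm; phase : 'dense' | 'dilute' per emitter;
    photons : expected photons per frame per emitter; cell_index maps each
    emitter to its cell in the scene list.
    """

    positions: np.ndarray
    phase: np.ndarray
    photons: np.ndarray
    cell_index: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.phase = np.asarray(self.phase)
        self.photons = np.asarray(self.photons, dtype=float)
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        n = len(self.positions)
        if not (len(self.phase) == len(self.photons) == len(self.cell_index) == n):
            raise ValueError("all per-emitter arrays must have equal length")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SnapshotTruth:
    cells: list[CellGeometry]
    positions: np.ndarray
    photons: np.ndarray
    phase: np.ndarray
    cell_index: np.ndarray
    total_photons: float
    seed: int | None = None


def populate_cell(
    cell: CellGeometry,
    n_dilute: int,
    n_dense: int = 0,
    focus_center: tuple[float, float] | None = None,
    focus_sigma: float = 0.1,
    photons: float | tuple[float, float] = (PHOTON_GAMMA_SHAPE, PHOTON_GAMMA_SCALE),
    rng: np.random.Generator | int | None = None,
    cell_index: int = 0,
) -> EmitterEnsemble:
    """Place emitters in a cell: uniform dilute phase + optional dense focus.

    ``photons`` is either a fixed expected per-frame output or a
    ``(shape, scale)`` Gamma pair each emitter draws its output from.
    The dense focus defaults to the cell pole on the +x side of the axis.
    """
    rng = np.random.default_rng(rng)
    parts, phases = [], []
    if n_dilute:
        parts.append(cell.sample_uniform(n_dilute, rng))
        phases.extend(["dilute"] * n_dilute)
    if n_dense:
        if focus_center is None:
            local = np.array([cell.half_axis, 0.0])
            focus_center = tuple(cell._to_world(local)[0])
        pts = np.empty((0, 2))
        while len(pts) < n_dense:
            cand = rng.normal(focus_center, focus_sigma, size=(2 * n_dense, 2))
            pts = np.vstack([pts, cand[cell.contains(cand)]])
        parts.append(pts[:n_dense])
        phases.extend(["dense"] * n_dense)
    positions = np.vstack(parts) if parts else np.empty((0, 2))
    n = len(positions)
    if isinstance(photons, tuple):
        out = rng.gamma(photons[0], photons[1], size=n)
    else:
        out = np.full(n, float(photons))
    return EmitterEnsemble(
        positions=positions,
        phase=np.array(phases),
        photons=out,
        cell_index=np.full(n, cell_index),
    )


def add_gaussian_spot(
    photon_map: np.ndarray,
    x_px: float,
    y_px: float,
    sigma_px: float,
    photons: float,
) -> None:
    """Accumulate a pixel-integrated 2D Gaussian spot in place.

    The expected photons in each pixel are the exact integral of the
    Gaussian over the pixel footprint (difference of error functions), so
    noiseless rendering conserves photons to machine precision.
    """
    ny, nx = photon_map.shape
    half = int(math.ceil(6 * sigma_px)) + 1
    x0, y0 = int(round(x_px)), int(round(y_px))
    xs = np.arange(max(0, x0 - half), min(nx, x0 + half + 1))
    ys = np.arange(max(0, y0 - half), min(ny, y0 + half + 1))
    if len(xs) == 0 or len(ys) == 0:
        return
    s = sigma_px * math.sqrt(2.0)
    fx = 0.5 * (special.erf((xs + 0.5 - x_px) / s) - special.erf((xs - 0.5 - x_px) / s))
    fy = 0.5 * (special.erf((ys + 0.5 - y_px) / s) - special.erf((ys - 0.5 - y_px) / s))
    photon_map[np.ix_(ys, xs)] += photons * np.outer(fy, fx)


def render_photon_map(
    shape: tuple[int, int],
    cells: list[CellGeometry],
    emitters: EmitterEnsemble | None,
    psf_sigma: float,
    pixel_size: float,
    cytoplasm_photon_density: float | np.ndarray | None = None,
) -> np.ndarray:
    """Expected-photon image for a scene (no camera, no noise).

    ``cytoplasm_photon_density`` is photons per µm² of silhouette per
    frame, scalar or one value per cell; it renders the cells as smooth
    filled rods (used for bulk-fluorescence scenes where drawing every
    molecule would be pointless).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    photon_map = np.zeros(shape, dtype=float)
    sigma_px = psf_sigma / pixel_size
    if cytoplasm_photon_density is not None:
        dens = np.broadcast_to(np.asarray(cytoplasm_photon_density, dtype=float),
                               (len(cells),))
        sil = np.zeros(shape, dtype=float)
        for cell, d in zip(cells, dens):
            sil += d * cell.silhouette(shape, pixel_size) * pixel_size**2
        photon_map += ndimage.gaussian_filter(sil, sigma_px)
    if emitters is not None and len(emitters):
        inside = np.zeros(len(emitters), dtype=bool)
        for cell in cells:
            inside |= cell.contains(emitters.positions)
        if not inside.all():
            raise ValueError(
                f"{(~inside).sum()} emitter(s) lie outside every cell"
            )
        for (x, y), p in zip(emitters.positions, emitters.photons):
            add_gaussian_spot(photon_map, x / pixel_size, y / pixel_size,
                              sigma_px, p)
    return photon_map


def render_snapshot(
    cells: list[CellGeometry],
    emitters: EmitterEnsemble | None = None,
    psf_sigma: float = 0.1,
    camera: CameraModel | None = None,
    nominal_em: float = 0.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] | None = None,
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
    cytoplasm_photon_density: float | np.ndarray | None = None,
) -> tuple[ImageStack, SnapshotTruth]:
    """Render one camera frame of a cell scene with full ground truth."""
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    if shape is None:
        span = max(
            (abs(c.center[0]) + c.length for c in cells), default=2.0
        )
        n = int(math.ceil(2 * span / pixel_size))
        shape = (n, n)
    photon_map = render_photon_map(shape, cells, emitters, psf_sigma,
                                   pixel_size, cytoplasm_photon_density)
    counts = simulate_camera(photon_map, camera, nominal_em, rng, noise=noise)
    stack = ImageStack(
        data=counts,
        pixel_size=pixel_size,
        channel="synthetic",
        camera={
            "bias_counts": camera.bias_counts,
            "conversion_gain": camera.conversion_gain,
            "em_factor": camera.em_factor,
            "nominal_em": nominal_em,
        },
    )
    if emitters is None or len(emitters) == 0:
        truth = SnapshotTruth(cells, np.empty((0, 2)), np.empty(0),
                              np.empty(0, dtype=object), np.empty(0, dtype=int),
                              float(photon_map.sum()))
    else:
        truth = SnapshotTruth(cells, emitters.positions, emitters.photons,
                              emitters.phase, emitters.cell_index,
                              float(photon_map.sum()))
    return stack, truth


@dataclass
class CellPopulation:
    """A rendered multi-cell (or per-cell) scene with ground truth."""

    stacks: list[ImageStack]
    masks: list[np.ndarray]              # ground-truth label images
    cells: list[CellGeometry]
    truth: pd.DataFrame                  # per-cell: label, has_focus, n_molecules, ...
    pixel_size: float
    camera: CameraModel
    nominal_em: float = 0.0


def simulate_cell_population(
    n_cells: int,
    rng: np.random.Generator | int | None = None,
    concentration_uM: float = 100.0,
    focus_fraction: float = 0.0,
    focus_excess_molecules: float = 0.0,
    length_range: tuple[float, float] = (2.5, 4.0),
    width_range: tuple[float, float] = (0.9, 1.1),
    photons_per_molecule_mean: float = PHOTON_GAMMA_SHAPE * PHOTON_GAMMA_SCALE,
    photons_per_molecule_sd: float | None = None,
    n_frames: int = 1,
    psf_sigma: float = 0.1,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    camera: CameraModel | None = None,
    nominal_em: float = 0.0,
    noise: bool = True,
    roi_margin_um: float = 0.8,
) -> CellPopulation:
    """Bulk-fluorescence scenes: one small image per cell, with truth.

    Each cell holds ``round(concentration_uM × 602.214 × volume)``
    molecules whose summed per-frame photon output is drawn from a normal
    approximation of the per-molecule Gamma distribution (drawing ~10⁵
    individual spots per cell would change nothing measurable).  A focus,
    when present, concentrates ``focus_excess_molecules`` extra molecules
    at one pole as a diffraction-limited spot.
    """
    rng = np.random.default_rng(rng)
    camera = camera or CameraModel()
    if photons_per_molecule_sd is None:
        photons_per_molecule_sd = math.sqrt(PHOTON_GAMMA_SHAPE) * PHOTON_GAMMA_SCALE
    stacks, masks, cells, rows = [], [], [], []
    for label in range(1, n_cells + 1):
        length = rng.uniform(*length_range)
        width = rng.uniform(*width_range)
        margin = roi_margin_um
        nx = int(math.ceil((length + 2 * margin) / pixel_size))
        ny = int(math.ceil((width + 2 * margin) / pixel_size))
        center = ((length / 2 + margin), (width / 2 + margin))
        cell = build_cell(length, width, 0.0, center)
        n_mol = int(round(concentration_uM * MOLECULES_PER_UM3_PER_UM * cell.volume))
        has_focus = bool(rng.random() < focus_fraction)
        n_focus = int(focus_excess_molecules) if has_focus else 0
        frames = []
        for _ in range(n_frames):
            total = rng.normal(n_mol * photons_per_molecule_mean,
                               photons_per_molecule_sd * math.sqrt(max(n_mol, 1)))
            total = max(total, 0.0)
            area = cell.silhouette((ny, nx), pixel_size).sum() * pixel_size**2
            pmap = render_photon_map(
                (ny, nx), [cell], None, psf_sigma, pixel_size,
                cytoplasm_photon_density=total / area,
            )
            if n_focus:
                pole = cell._to_world(np.array([cell.half_axis * 0.8, 0.0]))[0]
                add_gaussian_spot(pmap, pole[0] / pixel_size, pole[1] / pixel_size,
                                  psf_sigma / pixel_size,
                                  n_focus * photons_per_molecule_mean)
            frames.append(simulate_camera(pmap, camera, nominal_em, rng, noise=noise))
        data = frames[0] if n_frames == 1 else np.stack(frames)
        stacks.append(ImageStack(data=data, pixel_size=pixel_size))
        masks.append(cell.silhouette((ny, nx), pixel_size).astype(np.int32) * label)
        cells.append(cell)
        rows.append({
            "label": label,
            "length_um": length,
            "width_um": width,
            "volume_um3": cell.volume,
            "n_molecules": n_mol + n_focus,
            "concentration_uM": (n_mol + n_focus)
            / (MOLECULES_PER_UM3_PER_UM * cell.volume),
            "has_focus": has_focus,
        })
    return CellPopulation(
        stacks=stacks, masks=masks, cells=cells,
        truth=pd.DataFrame(rows), pixel_size=pixel_size,
        camera=camera, nominal_em=nominal_em,
    )
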