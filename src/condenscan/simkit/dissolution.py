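"""Time-lapse generator for focus-dissolution (reversibility) assays.

A single cell lineage is followed through growth and division while its
total fluorescent-protein content stays fixed ("generational dilution":
expression is stopped once the focus has formed).  Two material states
are emulated:

* ``aggregate`` — the focus is an insoluble particle: it keeps its
  molecule content for the whole movie regardless of concentration.
* ``condensate`` — molecules repartition every frame between a dense
  polar focus and the dilute cytoplasm: the focus holds the excess above
  the saturation concentration ``c_sat`` and dissolves once growth
  dilutes the cell below it.  After a division the daughter concentration
  can rise back above ``c_sat`` (asymmetric partitioning), re-forming a
  focus.

The followed cell is rendered with its focus pole anchored at a fixed
image position, so a persisting focus moves less than a pixel between
frames.  Frame interval defaults to 15 min, the cadence of the
generational-dilution experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..camera import CameraModel, simulate_camera
from ..constants import MOLECULES_PER_UM3_PER_UM
from ..geometry import build_cell, spherocylinder_volume
from ..io import ImageStack
from .snapshots import add_gaussian_spot, render_photon_map

__all__ = ["DissolutionMovie", "simulate_dissolution_series"]


@dataclass
class DissolutionMovie:
    stack: ImageStack
    truth: pd.DataFrame          # per-frame bookkeeping
    mode: str
    c_sat_uM: float
    lifespan_frames: int         # length of the first focus episode
    censored: bool               # focus episode still running at movie end
    focus_xy_px: tuple[float, float]
    frame_interval: float


def simulate_dissolution_series(
    mode: str,
    c_sat_uM: float = 40.0,
    initial_concentration_uM: float = 80.0,
    birth_length_um: float = 2.2,
    width_um: float = 1.0,
    doubling_frames: float = 10.0,
    n_frames: int = 40,
    frame_interval: float = 900.0,
    division_rule: dict | None = None,
    photons_per_molecule_frame: float = 2.0,
    psf_sigma: float = 0.12,
    pixel_size: float = 0.066,
    camera: CameraModel | None = None,
    nominal_em: float = 0.0,
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> DissolutionMovie:
    """Simulate one dissolution movie with full per-frame ground truth.

    ``division_rule``: ``{"type": "binomial"}`` (default) partitions the
    dilute molecules binomially with the daughter volume fraction;
    ``{"type": "deterministic", "molecule_fraction": f}`` hands the
    followed daughter exactly that fraction (volumes always halve).
    Dense-phase molecules stay with the focus-bearing daughter.
    """
    if mode not in ("aggregate", "condensate"):
        raise ValueError(f"unknown mode {mode!r}; use 'aggregate' or 'condensate'")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    rule = division_rule or {"type": "binomial"}
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)

    margin = 0.8  # µm of dark border around the largest cell
    nx = int(math.ceil((2 * birth_length_um + 2 * margin) / pixel_size))
    ny = int(math.ceil((width_um + 2 * margin) / pixel_size))
    anchor_x = (nx - 1) * pixel_size - margin   # +x pole tip, fixed
    cy = (ny - 1) * pixel_size / 2.0
    r = width_um / 2.0
    focus_xy_um = (anchor_x - r, cy)            # pole-cap center

    length = birth_length_um
    vol = spherocylinder_volume(length, width_um)
    n_total = int(round(initial_concentration_uM * MOLECULES_PER_UM3_PER_UM * vol))
    csat_mol = lambda v: c_sat_uM * MOLECULES_PER_UM3_PER_UM * v
    dense0 = max(0, int(round(n_total - csat_mol(vol))))

    frames, rows = [], []
    dense_agg = dense0
    for t in range(n_frames):
        if mode == "aggregate":
            dense = dense_agg
        else:
            dense = max(0, int(round(n_total - csat_mol(vol))))
        dilute = n_total - dense
        cell = build_cell(length, width_um, 0.0,
                          center=(anchor_x - length / 2.0, cy))
        area = cell.silhouette((ny, nx), pixel_size).sum() * pixel_size**2
        pmap = render_photon_map(
            (ny, nx), [cell], None, psf_sigma, pixel_size,
            cytoplasm_photon_density=dilute * photons_per_molecule_frame / area,
        )
        if dense > 0:
            add_gaussian_spot(pmap, focus_xy_um[0] / pixel_size,
                              focus_xy_um[1] / pixel_size,
                              psf_sigma / pixel_size,
                              dense * photons_per_molecule_frame)
        frames.append(simulate_camera(pmap, camera, nominal_em, rng, noise=noise))
        rows.append({
            "frame": t,
            "length_um": length,
            "volume_um3": vol,
            "n_total": n_total,
            "n_dense": dense,
            "concentration_uM": n_total / (MOLECULES_PER_UM3_PER_UM * vol),
            "focus_present": dense > 0,
        })

        # grow, then divide when the cell has doubled
        length *= 2.0 ** (1.0 / doubling_frames)
        if length >= 2.0 * birth_length_um:
            length /= 2.0
            if mode == "aggregate":
                dilute_now = n_total - dense_agg
            else:
                dilute_now = n_total - max(
                    0, int(round(n_total - csat_mol(spherocylinder_volume(length * 2, width_um))))
                )
                dilute_now = max(dilute_now, 0)
            dense_kept = n_total - dilute_now
            if rule["type"] == "binomial":
                kept = rng.binomial(dilute_now, 0.5)
            elif rule["type"] == "deterministic":
                kept = int(round(dilute_now * rule.get("molecule_fraction", 0.5)))
            else:
                raise ValueError(f"unknown division rule {rule['type']!r}")
            n_total = dense_kept + kept
        vol = spherocylinder_volume(length, width_um)

    truth = pd.DataFrame(rows)
    present = truth["focus_present"].to_numpy()
    if present[0]:
        first_gone = np.argmin(present) if not present.all() else len(present)
        lifespan_frames = int(first_gone)
    else:
        lifespan_frames = 0
    censored = bool(present.all())
    stack = ImageStack(
        data=np.stack(frames),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel="dissolution",
        meta={"mode": mode, "c_sat_uM": c_sat_uM},
    )
    return DissolutionMovie(
        stack=stack, truth=truth, mode=mode, c_sat_uM=c_sat_uM,
        lifespan_frames=lifespan_frames, censored=censored,
        focus_xy_px=(focus_xy_um[0] / pixel_size, focus_xy_um[1] / pixel_size),
        frame_interval=frame_interval,
    )
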