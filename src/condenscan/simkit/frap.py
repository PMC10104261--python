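"""Synthetic FRAP (fluorescence recovery after photobleaching) movies.

A single cell with a polar focus is imaged; at ``bleach_frame`` the focus
ROI is photobleached to a residual fraction, after which the focus signal
recovers exponentially towards ``mobile_fraction`` of its pre-bleach
level.  ``mobile_fraction = 0`` emulates an insoluble aggregate (no
molecular exchange, no recovery); ``mobile_fraction = 1`` a fully
exchanging condensate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..camera import CameraModel, simulate_camera
from ..geometry import build_cell
from ..io import ImageStack
from .snapshots import add_gaussian_spot, render_photon_map

__all__ = ["FrapMovie", "simulate_frap_series"]


@dataclass
class FrapMovie:
    stack: ImageStack
    bleach_frame: int
    bleach_roi: tuple[slice, slice]
    background_roi: tuple[slice, slice]
    mobile_fraction: float
    recovery_rate: float
    focus_xy_px: tuple[float, float]


def simulate_frap_series(
    mobile_fraction: float,
    recovery_rate: float = 0.5,
    n_pre: int = 5,
    n_post: int = 30,
    frame_interval: float = 1.0,
    focus_photons: float = 20000.0,
    cytoplasm_photons: float = 6000.0,
    bleach_residual: float = 0.02,
    length_um: float = 3.0,
    width_um: float = 1.0,
    psf_sigma: float = 0.12,
    pixel_size: float = 0.066,
    camera: CameraModel | None = None,
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> FrapMovie:
    """Render a FRAP movie; frame ``n_pre`` is the first post-bleach frame."""
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    margin = 0.7
    nx = int(math.ceil((length_um + 2 * margin) / pixel_size))
    ny = int(math.ceil((width_um + 2 * margin) / pixel_size))
    cell = build_cell(length_um, width_um, 0.0,
                      center=(length_um / 2 + margin, width_um / 2 + margin))
    pole = cell._to_world(np.array([cell.half_axis, 0.0]))[0]
    fx, fy = pole[0] / pixel_size, pole[1] / pixel_size
    area = cell.silhouette((ny, nx), pixel_size).sum() * pixel_size**2

    frames = []
    n_frames = n_pre + n_post
    for t in range(n_frames):
        if t < n_pre:
            focus = focus_photons
        else:
            dt = (t - n_pre) * frame_interval
            bleached = focus_photons * bleach_residual
            plateau = bleached + mobile_fraction * (focus_photons - bleached)
            focus = plateau - (plateau - bleached) * math.exp(-recovery_rate * dt)
        pmap = render_photon_map(
            (ny, nx), [cell], None, psf_sigma, pixel_size,
            cytoplasm_photon_density=cytoplasm_photons / area,
        )
        add_gaussian_spot(pmap, fx, fy, psf_sigma / pixel_size, focus)
        frames.append(simulate_camera(pmap, camera, 0.0, rng, noise=noise))

    half = max(3, int(round(0.25 / pixel_size)))
    bleach_roi = (slice(int(fy) - half, int(fy) + half + 1),
                  slice(int(fx) - half, int(fx) + half + 1))
    background_roi = (slice(0, 8), slice(0, 8))
    stack = ImageStack(
        data=np.stack(frames), pixel_size=pixel_size,
        frame_interval=frame_interval, channel="frap",
    )
    return FrapMovie(
        stack=stack, bleach_frame=n_pre, bleach_roi=bleach_roi,
        background_roi=background_roi, mobile_fraction=mobile_fraction,
        recovery_rate=recovery_rate, focus_xy_px=(fx, fy),
    )
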