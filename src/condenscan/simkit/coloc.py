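"""Two-channel chaperone-colocalization pattern generator.

Channel 1 is a reference focus (a condensate or aggregate marker);
channel 2 is the chaperone signal arranged in one of the patterns seen
for the small heat-shock protein IbpA:

* ``rosette`` — a ring around the reference focus (chaperone coating an
  insoluble aggregate); fitted FWHM larger than the reference.
* ``punctate`` — a tight spot inside the reference focus (chaperone
  penetrating a viscous condensate); fitted FWHM smaller.
* ``amorphous`` — an irregular blob of about the reference size.
* ``identical`` — channel 2 is a copy of channel 1 (control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..camera import CameraModel, simulate_camera
from ..io import ImageStack
from .snapshots import add_gaussian_spot

__all__ = ["ColocScene", "simulate_coloc_pattern"]

PATTERNS = ("rosette", "punctate", "amorphous", "identical")


@dataclass
class ColocScene:
    stack: ImageStack            # data shaped (2, Y, X): [reference, chaperone]
    pattern: str
    centers_px: np.ndarray       # (n_foci, 2) as (x, y)
    ref_sigma_px: float


def _ring(shape: tuple[int, int], x0: float, y0: float, radius_px: float,
          sigma_px: float, photons: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    r = np.hypot(xx - x0, yy - y0)
    prof = np.exp(-((r - radius_px) ** 2) / (2 * sigma_px**2))
    s = prof.sum()
    return photons * prof / s if s > 0 else prof


def simulate_coloc_pattern(
    pattern: str,
    n_foci: int = 1,
    shape: tuple[int, int] = (41, 41),
    ref_sigma_px: float = 2.0,
    ref_photons: float = 20000.0,
    chap_photons: float = 6000.0,
    ring_radius_px: float = 4.0,
    ring_sigma_px: float = 1.3,
    punct_sigma_px: float = 1.0,
    amorphous_grain_px: float = 1.5,
    pixel_size: float = 0.066,
    camera: CameraModel | None = None,
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> ColocScene:
    """Render a two-channel scene with ``n_foci`` patterned foci.

    The default geometry (ring radius twice the reference spot sigma,
    inner punctum half of it) keeps every pattern inside the 23×23 px
    analysis ROI at 0.066 µm/px.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    roi_half = 11
    need = ring_radius_px + 3 * ring_sigma_px if pattern == "rosette" else 4 * ref_sigma_px
    if need > roi_half:
        raise ValueError("pattern geometry does not fit the 23×23 analysis ROI")
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    ny, nx = shape
    margin = roi_half + 2
    if nx < 2 * margin + 1 or ny < 2 * margin + 1:
        raise ValueError("image too small for the requested ROI margin")

    ref_map = np.zeros(shape)
    chap_map = np.zeros(shape)
    centers = []
    for _ in range(n_foci):
        x0 = rng.uniform(margin, nx - 1 - margin)
        y0 = rng.uniform(margin, ny - 1 - margin)
        centers.append((x0, y0))
        add_gaussian_spot(ref_map, x0, y0, ref_sigma_px, ref_photons)
        if pattern == "identical":
            add_gaussian_spot(chap_map, x0, y0, ref_sigma_px, ref_photons)
        elif pattern == "punctate":
            add_gaussian_spot(chap_map, x0, y0, punct_sigma_px, chap_photons)
        elif pattern == "rosette":
            chap_map += _ring(shape, x0, y0, ring_radius_px, ring_sigma_px,
                              chap_photons)
        elif pattern == "amorphous":
            blob = np.zeros(shape)
            add_gaussian_spot(blob, x0, y0, ref_sigma_px, chap_photons)
            grain = rng.lognormal(0.0, 0.35, size=shape)
            from scipy import ndimage
            grain = ndimage.gaussian_filter(grain, amorphous_grain_px)
            blob *= grain
            blob *= chap_photons / blob.sum()
            chap_map += blob

    ref = simulate_camera(ref_map, camera, 0.0, rng, noise=noise)
    chap = simulate_camera(chap_map, camera, 0.0, rng, noise=noise)
    stack = ImageStack(
        data=np.stack([ref, chap]), pixel_size=pixel_size,
        channel="reference+chaperone", meta={"pattern": pattern},
    )
    return ColocScene(stack=stack, pattern=pattern,
                      centers_px=np.array(centers), ref_sigma_px=ref_sigma_px)
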