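"""Synthetic camera-calibration data sets.

Two classic EMCCD calibration experiments are emulated:

* photon transfer: pairs of flat-field frames at several exposure times
  with no EM gain, plus averaged dark (bias) frames — the mean-versus-
  variance line of these frames has slope equal to the conversion gain;
* EM-gain calibration: one long-exposure frame without EM amplification
  and short-exposure frames at several nominal EM-gain settings — the
  signal-rate ratio at each setting is the output gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..camera import CameraModel, simulate_camera

__all__ = [
    "PhotonTransferData",
    "EmGainData",
    "simulate_photon_transfer",
    "simulate_em_gain_series",
]


@dataclass
class PhotonTransferData:
    exposures_ms: np.ndarray
    frame_pairs: list[tuple[np.ndarray, np.ndarray]]
    bias_frame: np.ndarray          # average of the dark acquisitions
    camera: CameraModel


@dataclass
class EmGainData:
    no_em_image: np.ndarray
    no_em_exposure: float            # s
    em_images: dict[float, np.ndarray]   # nominal gain -> image
    em_exposure: float               # s
    bias: float
    camera: CameraModel


def simulate_photon_transfer(
    camera: CameraModel | None = None,
    exposures_ms: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0),
    flux_per_ms: float = 2.0,
    shape: tuple[int, int] = (512, 512),
    n_bias_frames: int = 100,
    rng: np.random.Generator | int | None = None,
) -> PhotonTransferData:
    """Flat-field frame pairs across exposure times, plus a bias average.

    ``flux_per_ms`` is the expected photons per pixel per millisecond of
    exposure (uniform illumination, e.g. a white card).
    """
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    bias_stack = np.stack([
        simulate_camera(np.zeros(shape), camera, 0.0, rng)
        for _ in range(n_bias_frames)
    ])
    pairs = []
    for exp in exposures_ms:
        photon_map = np.full(shape, flux_per_ms * exp)
        a = simulate_camera(photon_map, camera, 0.0, rng)
        b = simulate_camera(photon_map, camera, 0.0, rng)
        pairs.append((a, b))
    return PhotonTransferData(
        exposures_ms=np.asarray(exposures_ms, dtype=float),
        frame_pairs=pairs,
        bias_frame=bias_stack.mean(axis=0),
        camera=camera,
    )


def simulate_em_gain_series(
    camera: CameraModel | None = None,
    nominal_gains: tuple[float, ...] = (5.0, 50.0, 150.0, 300.0, 600.0),
    flux_per_s: float = 2000.0,
    no_em_exposure: float = 1.0,
    em_exposure: float = 0.010,
    shape: tuple[int, int] = (256, 256),
    rng: np.random.Generator | int | None = None,
) -> EmGainData:
    """Long-exposure no-EM frame plus short-exposure frames across gains."""
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    no_em = simulate_camera(np.full(shape, flux_per_s * no_em_exposure),
                            camera, 0.0, rng)
    em_images = {
        g: simulate_camera(np.full(shape, flux_per_s * em_exposure), camera, g, rng)
        for g in nominal_gains
    }
    return EmGainData(
        no_em_image=no_em,
        no_em_exposure=no_em_exposure,
        em_images=em_images,
        em_exposure=em_exposure,
        bias=camera.bias_counts,
        camera=camera,
    )
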