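"""Spherocylinder cell geometry.

Rod-shaped bacteria are modeled as a 2D/3D spherocylinder: a cylinder of
diameter ``width`` capped by hemispheres, with pole-to-pole ``length``.
All lengths are in micrometres.  The in-plane silhouette is the set of
points within ``width / 2`` of the central axis segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellGeometry", "spherocylinder_volume", "build_cell"]


def spherocylinder_volume(length: float, width: float) -> float:
    """Volume (µm³) of a cylinder with hemispherical caps.

    ``length`` is pole-to-pole, so the cylindrical section has length
    ``length - width``.  Requires ``length >= width > 0``.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if length < width:
        raise ValueError(
            f"pole-to-pole length ({length}) must be >= width ({width})"
        )
    r = width / 2.0
    return math.pi * r * r * (length - 2 * r) + (4.0 / 3.0) * math.pi * r**3


@dataclass(frozen=True)
class CellGeometry:
    """A single rod-shaped cell in the image plane.

    Attributes
    ----------
    center : (x, y) µm — midpoint of the central axis.
    length : µm, pole-to-pole.
    width : µm, cell diameter (= 2r).
    orientation : radians, angle of the long axis w.r.t. the x axis.
    volume : µm³, spherocylinder closed form (derived).
    """

    center: tuple[float, float]
    length: float
    width: float
    orientation: float = 0.0
    volume: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume", spherocylinder_volume(self.length, self.width))

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def half_axis(self) -> float:
        """Half-length of the central axis segment (pole centers)."""
        return (self.length - self.width) / 2.0

    def _to_local(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        return p @ rot.T

    def _to_world(self, local: np.ndarray) -> np.ndarray:
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return np.atleast_2d(local) @ rot.T + np.asarray(self.center)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (µm) to the silhouette boundary; negative inside."""
        local = self._to_local(points)
        dx = np.maximum(np.abs(local[:, 0]) - self.half_axis, 0.0)
        return np.hypot(dx, local[:, 1]) - self.radius

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self.signed_distance(points) <= tol

    def reflect_inside(self, points: np.ndarray, max_iter: int = 8) -> np.ndarray:
        """Specular reflection of points across the silhouette boundary.

        Repeated until every point is inside (a step rarely exits by more
        than a fraction of the radius, so one pass almost always suffices).
        """
        local = self._to_local(points).copy()
        a, r = self.half_axis, self.radius
        for _ in range(max_iter):
            cx = np.clip(local[:, 0], -a, a)
            d = np.hypot(local[:, 0] - cx, local[:, 1])
            out = d > r
            if not out.any():
                break
            nx = (local[out, 0] - cx[out]) / d[out]
            ny = local[out, 1] / d[out]
            over = d[out] - r
            local[out, 0] -= 2 * over * nx
            local[out, 1] -= 2 * over * ny
        else:  # pathological: clamp onto the boundary
            cx = np.clip(local[:, 0], -a, a)
            d = np.hypot(local[:, 0] - cx, local[:, 1])
            out = d > r
            scale = r / d[out]
            local[out, 0] = cx[out] + (local[out, 0] - cx[out]) * scale
            local[out, 1] *= scale
        return self._to_world(local)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points (µm) inside the silhouette (rejection)."""
        hx = self.length / 2.0
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(2 * (n - len(out)), 16)
            local = rng.uniform([-hx, -self.radius], [hx, self.radius], size=(m, 2))
            cand = self._to_world(local)
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]

    def silhouette(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean raster of the silhouette on a pixel grid.

        Pixel (row j, col i) has its center at (i, j) * pixel_size µm.
        """
        ny, nx = shape
        xs = np.arange(nx) * pixel_size
        ys = np.arange(ny) * pixel_size
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        return self.contains(pts).reshape(shape)


def build_cell(
    length: float,
    width: float,
    orientation: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> CellGeometry:
    """Construct a :class:`CellGeometry`; raises on invalid geometry."""
    return CellGeometry(center=tuple(center), length=length, width=width,
                        orientation=orientation)
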