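"""Imaging geometry for a point light source at the center of projection.

The camera is an ideal pinhole at the world origin looking down +Z, with the
point light source at the same origin.  Image-plane coordinates ``(x, y)``
are physical millimetres on the sensor, origin on the optical axis, x to the
right and y downward.  Two per-pixel coefficient maps recur throughout the
pipeline:

* ``Q = f / sqrt(x^2 + y^2 + f^2)`` -- the cosine of the angle between the
  viewing ray and the optical axis (perspective coefficient).
* ``V = f^2 / (x^2 + y^2 + f^2)^(3/2) = Q^3 / f`` -- the irradiance
  counterpart used by the pointwise depth equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CameraModel"]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with a physical sensor extent.

    Parameters
    ----------
    focal_length_mm : float
        Focal length ``f`` in mm; must be positive.
    image_extent_mm : tuple of float
        Physical (width, height) of the image plane in mm.
    pixel_dims : tuple of int
        (n_cols, n_rows) of the pixel grid.
    """

    focal_length_mm: float
    image_extent_mm: tuple[float, float] = (9.0, 9.0)
    pixel_dims: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be positive")
        w, h = self.image_extent_mm
        nc, nr = self.pixel_dims
        if w <= 0 or h <= 0:
            raise ValueError("image extent must be positive")
        if int(nc) != nc or int(nr) != nr or nc < 1 or nr < 1:
            raise ValueError("pixel_dims must be positive integers")

    # -- derived geometry ---------------------------------------------------

    @property
    def f(self) -> float:
        return float(self.focal_length_mm)

    @property
    def pixel_pitch_mm(self) -> tuple[float, float]:
        """(dx, dy) physical size of one pixel in mm."""
        w, h = self.image_extent_mm
        nc, nr = self.pixel_dims
        return (w / nc, h / nr)

    def pixel_to_mm(self, i, j):
        """Image-plane mm coordinates of the center of pixel column ``i``, row ``j``.

        ``i`` indexes columns (x direction), ``j`` rows (y direction); both
        0-based.  Accepts scalars or arrays.
        """
        i = np.asarray(i)
        j = np.asarray(j)
        nc, nr = self.pixel_dims
        if np.any(i < 0) or np.any(i >= nc) or np.any(j < 0) or np.any(j >= nr):
            raise IndexError("pixel index out of range")
        dx, dy = self.pixel_pitch_mm
        w, h = self.image_extent_mm
        x = -w / 2.0 + (i + 0.5) * dx
        y = -h / 2.0 + (j + 0.5) * dy
        if x.ndim == 0:
            return float(x), float(y)
        return x, y

    def mm_to_pixel(self, x, y):
        """Inverse of :meth:`pixel_to_mm` (continuous, not rounded)."""
        dx, dy = self.pixel_pitch_mm
        w, h = self.image_extent_mm
        return (np.asarray(x) + w / 2.0) / dx - 0.5, (np.asarray(y) + h / 2.0) / dy - 0.5

    def grids(self):
        """Full ``(x, y)`` mm coordinate grids, shape (n_rows, n_cols)."""
        nc, nr = self.pixel_dims
        i = np.arange(nc)
        j = np.arange(nr)
        xi, yj = self.pixel_to_mm(i, np.zeros_like(i))[0], self.pixel_to_mm(np.zeros_like(j), j)[1]
        return np.meshgrid(xi, yj)

    def q_map(self) -> np.ndarray:
        """Perspective coefficient Q(x, y) on the pixel grid."""
        x, y = self.grids()
        return self.f / np.sqrt(x * x + y * y + self.f**2)

    def v_map(self) -> np.ndarray:
        """Irradiance coefficient V(x, y) = Q^3 / f on the pixel grid."""
        x, y = self.grids()
        return self.f**2 / (x * x + y * y + self.f**2) ** 1.5

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "focal_length_mm": self.focal_length_mm,
            "image_extent_mm": list(self.image_extent_mm),
            "pixel_dims": list(self.pixel_dims),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            focal_length_mm=d["focal_length_mm"],
            image_extent_mm=tuple(d["image_extent_mm"]),
            pixel_dims=tuple(d["pixel_dims"]),
        )
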