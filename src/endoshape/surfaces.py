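"""Parametric ground-truth surfaces viewed through the pinhole camera.

World coordinates are (X, Y, Z) in mm with the camera and light at the
origin and Z the depth axis.  The viewing ray of an image point ``(x, y)``
is the line through the origin and ``(x, y, f)``; a point at depth Z on this
ray sits at ``(x Z / f, y Z / f, Z)``.

Surface gradients ``(p, q) = (dZ/dX, dZ/dY)`` are world-coordinate slopes of
the depth function, dimensionless.  Near the limb of a smooth convex body
they diverge; such points are flagged invalid past a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereSurface",
    "CosineSurface",
    "HeightfieldSurface",
    "surface_from_dict",
    "LARGE_GRADIENT_DEFAULT",
]

#: gradients with |p| or |q| above this are treated as limb points
LARGE_GRADIENT_DEFAULT = 10.0


@dataclass(frozen=True)
class SphereSurface:
    """Sphere of radius R centered at (X0, Y0, Z0), viewed from the origin."""

    center: tuple[float, float, float] = (0.0, 0.0, 15.0)
    radius: float = 5.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def depth_along_ray(self, camera, x, y):
        """Depth Z of the near ray-sphere intersection; NaN where the ray misses.

        The ray direction is (x, y, f) (unnormalized); solving
        ``|t * d - c|^2 = R^2`` for the smaller positive root and converting
        the ray parameter to depth.
        """
        f = camera.f
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy, cz = self.center
        # quadratic a t^2 - 2 b t + c0 = 0 in the unnormalized ray parameter
        a = x * x + y * y + f * f
        b = x * cx + y * cy + f * cz
        c0 = cx * cx + cy * cy + cz * cz - self.radius**2
        disc = b * b - a * c0
        with np.errstate(invalid="ignore"):
            t = (b - np.sqrt(disc)) / a  # near root
        Z = t * f
        Z = np.where((disc >= 0) & (t > 0), Z, np.nan)
        if Z.ndim == 0:
            return float(Z)
        return Z

    def gradient_at(self, X, Y, Z):
        """Analytic (p, q) at a surface point; NaN at/behind the equator."""
        cx, cy, cz = self.center
        dz = np.asarray(Z, dtype=float) - cz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = -(np.asarray(X, dtype=float) - cx) / dz
            q = -(np.asarray(Y, dtype=float) - cy) / dz
        bad = dz >= 0  # limb or far hemisphere: Z is not a graph there
        p = np.where(bad, np.nan, p)
        q = np.where(bad, np.nan, q)
        return p, q

    def to_dict(self):
        return {"kind": "sphere", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class CosineSurface:
    """Cosine-corrugated height field Z(X, Y) = Z0 - A cos(2 pi rho / wavelength).

    ``rho`` is the radial world distance ``sqrt(X^2 + Y^2)`` when
    ``radial=True`` (a radially symmetric bump pattern, the default), or the
    X coordinate alone for a one-dimensional corrugation.
    """

    base_depth: float = 12.0
    wavelength: float = 4.0
    amplitude: float = 1.0
    radial: bool = True

    def __post_init__(self):
        if self.wavelength <= 0 or self.base_depth <= 0:
            raise ValueError("wavelength and base_depth must be positive")

    def height(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rho = np.sqrt(X * X + Y * Y) if self.radial else X
        return self.base_depth - self.amplitude * np.cos(2.0 * np.pi * rho / self.wavelength)

    def depth_along_ray(self, camera, x, y):
        """Depth where the viewing ray meets the height field.

        A point at depth Z on the ray of (x, y) has world radius
        ``rho = Z * sqrt(x^2+y^2) / f``, so Z solves a scalar fixed-point
        equation.  The nearest root inside ``[Z0 - A, Z0 + A]`` is located by
        a vectorized bracketing scan followed by bisection, which remains
        robust for grazing rays where plain fixed-point iteration stalls.
        """
        f = camera.f
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        scalar = x.ndim == 0
        x, y = np.atleast_1d(x), np.atleast_1d(y)

        def g(Z):
            Xw = x * Z / f
            Yw = y * Z / f
            return Z - self.height(Xw, Yw)

        z_near = self.base_depth - self.amplitude - 1e-9
        z_far = self.base_depth + self.amplitude + 1e-9
        n_scan = 512
        zs = np.linspace(z_near, z_far, n_scan)
        # scan from the near end for the first sign change of g
        lo = np.full(x.shape, z_near)
        hi = np.full(x.shape, z_far)
        found = np.zeros(x.shape, dtype=bool)
        g_prev = g(np.full(x.shape, zs[0]))
        for zk in zs[1:]:
            g_cur = g(np.full(x.shape, zk))
            new = (~found) & (g_prev * g_cur <= 0)
            lo = np.where(new, zk - (zs[1] - zs[0]), lo)
            hi = np.where(new, zk, hi)
            found |= new
            g_prev = g_cur
        # bisection refine on [lo, hi]
        g_lo = g(lo)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            g_mid = g(mid)
            left = g_lo * g_mid <= 0
            hi = np.where(left, mid, hi)
            lo = np.where(left, lo, mid)
            g_lo = np.where(left, g_lo, g_mid)
        Z = np.where(found, 0.5 * (lo + hi), np.nan)
        if scalar:
            return float(Z[0])
        return Z

    def gradient_at(self, X, Y, Z=None):
        """Analytic (p, q) of the height field at world (X, Y)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        k = 2.0 * np.pi / self.wavelength
        if self.radial:
            rho = np.sqrt(X * X + Y * Y)
            dZdrho = self.amplitude * k * np.sin(k * rho)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(rho > 0, dZdrho * X / rho, 0.0)
                q = np.where(rho > 0, dZdrho * Y / rho, 0.0)
        else:
            p = self.amplitude * k * np.sin(k * X)
            q = np.zeros_like(X)
        return p, q

    def to_dict(self):
        return {
            "kind": "cosine",
            "base_depth": self.base_depth,
            "wavelength": self.wavelength,
            "amplitude": self.amplitude,
            "radial": self.radial,
        }


@dataclass(frozen=True)
class HeightfieldSurface:
    """Explicit height field given as a table Z(X, Y) on a regular world grid."""

    x_coords: np.ndarray
    y_coords: np.ndarray
    z_table: np.ndarray

    def height(self, X, Y):
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (np.asarray(self.y_coords), np.asarray(self.x_coords)),
            np.asarray(self.z_table),
            bounds_error=False,
            fill_value=np.nan,
        )
        pts = np.stack([np.asarray(Y, dtype=float), np.asarray(X, dtype=float)], axis=-1)
        return interp(pts)

    def depth_along_ray(self, camera, x, y):
        """Fixed-point iteration Z <- h(x Z / f, y Z / f)."""
        f = camera.f
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        Z = np.full(np.broadcast(x, y).shape, float(np.nanmean(self.z_table)))
        for _ in range(100):
            Znew = self.height(x * Z / f, y * Z / f)
            if np.nanmax(np.abs(Znew - Z)) < 1e-9:
                Z = Znew
                break
            Z = Znew
        return Z

    def gradient_at(self, X, Y, Z=None):
        """Central-difference gradients of the tabulated height field."""
        dzdy, dzdx = np.gradient(
            np.asarray(self.z_table),
            np.asarray(self.y_coords),
            np.asarray(self.x_coords),
        )
        fx = HeightfieldSurface(self.x_coords, self.y_coords, dzdx)
        fy = HeightfieldSurface(self.x_coords, self.y_coords, dzdy)
        return fx.height(X, Y), fy.height(X, Y)

    def to_dict(self):
        return {
            "kind": "heightfield",
            "x_coords": np.asarray(self.x_coords).tolist(),
            "y_coords": np.asarray(self.y_coords).tolist(),
            "z_table": np.asarray(self.z_table).tolist(),
        }


def surface_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "sphere":
        return SphereSurface(center=tuple(d["center"]), radius=d["radius"])
    if kind == "cosine":
        return CosineSurface(
            base_depth=d["base_depth"],
            wavelength=d["wavelength"],
            amplitude=d["amplitude"],
            radial=d.get("radial", True),
        )
    if kind == "heightfield":
        return HeightfieldSurface(
            x_coords=np.asarray(d["x_coords"]),
            y_coords=np.asarray(d["y_coords"]),
            z_table=np.asarray(d["z_table"]),
        )
    raise ValueError(f"unknown surface kind: {kind!r}")
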