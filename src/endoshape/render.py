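"""Lambertian image synthesis under a point light at the lens center.

Image irradiance of a Lambertian surface lit by an inverse-square point
source coincident with the center of projection is

    E = C (s . n) / r^2

with reflectance parameter ``C``, unit direction ``s`` from the surface
point to the source, unit surface normal ``n`` and source distance ``r``.
Expanded in the depth map and its world gradients (p, q) this becomes the
per-pixel forward model

    E = C (-p x - q y + f) f^2 / ((x^2 + y^2 + f^2)^{3/2} Z^2 sqrt(p^2+q^2+1))

which the pointwise depth equation inverts exactly.  The solver consumes the
normalized intensity ``I = E / C`` so that reflectance enters only at the
final depth-recovery step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .surfaces import LARGE_GRADIENT_DEFAULT

__all__ = ["RadianceImage", "GroundTruthBundle", "lambertian_irradiance", "render"]


@dataclass
class RadianceImage:
    """Float irradiance raster with its reflectance parameter and mask."""

    E: np.ndarray
    C: float
    mask: np.ndarray

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.E.shape != self.mask.shape:
            raise ValueError("E and mask shapes differ")
        if self.C <= 0:
            raise ValueError("reflectance parameter C must be positive")
        if np.any(self.E[self.mask] < 0):
            raise ValueError("negative irradiance on valid pixels")

    @property
    def normalized(self) -> np.ndarray:
        """Reflectance-free intensity I = E / C (zero on invalid pixels)."""
        return np.where(self.mask, self.E / self.C, 0.0)


@dataclass
class GroundTruthBundle:
    """A rendered scene together with its ground-truth depth and gradients."""

    radiance: RadianceImage
    depth: np.ndarray  # true Z in mm, NaN outside mask
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray  # valid (surface visible) pixels
    limb_mask: np.ndarray  # valid AND gradients below the limb threshold
    surface: object
    camera: CameraModel


def lambertian_irradiance(p, q, Z, x, y, f, C):
    """Forward irradiance model; returns (E, valid).

    Back-facing samples (negative ``-px - qy + f``) are clamped to E = 0 and
    reported invalid.  ``Z`` must be positive wherever evaluated.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    Z = np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(Z[np.isfinite(Z)] <= 0):
        raise ValueError("depth must be positive")
    cosine = -p * x - q * y + f
    V = f**2 / (x * x + y * y + f**2) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        E = C * cosine * V / (Z * Z * np.sqrt(p * p + q * q + 1.0))
    valid = np.isfinite(E) & (cosine >= 0)
    E = np.where(valid, E, 0.0)
    return E, valid


def render(
    surface,
    camera: CameraModel,
    C: float = 100.0,
    large_gradient: float = LARGE_GRADIENT_DEFAULT,
) -> GroundTruthBundle:
    """Ray-cast a surface and synthesize its Lambertian irradiance image.

    Returns the image bundled with ground-truth depth and analytic world
    gradients.  ``limb_mask`` additionally excludes pixels whose true |p| or
    |q| exceeds ``large_gradient`` (the silhouette neighbourhood where
    gradients diverge).
    """
    x, y = camera.grids()
    f = camera.f
    Z = np.asarray(surface.depth_along_ray(camera, x, y), dtype=float)
    visible = np.isfinite(Z) & (Z > 0)
    if not visible.any():
        warnings.warn("surface entirely outside the field of view")
        empty = np.zeros_like(x)
        nanmap = np.full_like(x, np.nan)
        return GroundTruthBundle(
            RadianceImage(empty, C, visible), nanmap, nanmap, nanmap,
            visible, visible.copy(), surface, camera,
        )
    Xw = x * Z / f
    Yw = y * Z / f
    p, q = surface.gradient_at(Xw, Yw, Z)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    grad_ok = np.isfinite(p) & np.isfinite(q)
    E, front = lambertian_irradiance(
        np.where(grad_ok, p, 0.0), np.where(grad_ok, q, 0.0), np.where(visible, Z, 1.0), x, y, f, C
    )
    mask = visible & grad_ok & front
    E = np.where(mask, E, 0.0)
    limb = mask & (np.abs(p) <= large_gradient) & (np.abs(q) <= large_gradient)
    Z = np.where(mask, Z, np.nan)
    p = np.where(mask, p, np.nan)
    q = np.where(mask, q, np.nan)
    return GroundTruthBundle(
        radiance=RadianceImage(E, C, mask),
        depth=Z,
        p=p,
        q=q,
        mask=mask,
        limb_mask=limb,
        surface=surface,
        camera=camera,
    )
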