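"""World-coordinate surface gradients from depth maps, and training-pair sampling.

A depth map on the image grid is differentiated by forward differences
(backward at the last valid row/column) and the image-plane derivatives are
converted to world gradients (p, q) = (dZ/dX, dZ/dY).  Under perspective the
world point of a pixel is (x Z / f, y Z / f, Z), and eliminating the
parametrization gives the closed-form chain rule

    p = f Z_x / (Z + x Z_x + y Z_y),   q = f Z_y / (Z + x Z_x + y Z_y)

(``Z_x``, ``Z_y`` are derivatives with respect to the image-plane mm
coordinates).  Two simpler conversions are kept for relative-scale depth
maps, whose values are not metric distances and make the exact denominator
meaningless: the planar approximation ``p = (f / Z) Z_x`` and the raw
image-plane derivative ``p = Z_x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import CameraModel
from .surfaces import LARGE_GRADIENT_DEFAULT

__all__ = ["GradientField", "gradients_from_depth", "sample_training_pairs"]

_PROVENANCES = ("true", "vbw", "nn-corrected")


@dataclass
class GradientField:
    """Per-pixel world gradients with validity mask and provenance tag."""

    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    provenance: str

    def __post_init__(self):
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.p.shape == self.q.shape == self.mask.shape):
            raise ValueError("p, q, mask shapes differ")


def _forward_diff(Z, mask, axis, pitch):
    """Forward difference, falling back to backward at trailing edges."""
    Zf = np.roll(Z, -1, axis=axis)
    mf = np.roll(mask, -1, axis=axis)
    Zb = np.roll(Z, 1, axis=axis)
    mb = np.roll(mask, 1, axis=axis)
    sl = [slice(None)] * Z.ndim
    sl[axis] = -1
    mf[tuple(sl)] = False
    sl[axis] = 0
    mb[tuple(sl)] = False
    d = np.where(mask & mf, (Zf - Z) / pitch, np.nan)
    use_b = mask & ~mf & mb
    d = np.where(use_b, (Z - Zb) / pitch, d)
    ok = mask & (mf | mb)
    return d, ok


def gradients_from_depth(
    Z,
    camera: CameraModel,
    mask=None,
    mode: str = "exact",
    provenance: str = "true",
    large_gradient: float = LARGE_GRADIENT_DEFAULT,
) -> GradientField:
    """Differentiate a depth map into a world-gradient field.

    mode : 'exact' (perspective chain rule), 'planar' (p = f Z_x / Z) or
        'image' (raw image-plane derivative).  Use 'exact' for metric depth;
        relative-scale maps (e.g. the VBW output) should use 'planar' or
        'image', where the exact denominator ``Z + x Z_x + y Z_y`` is not a
        metric quantity and may vanish.
    large_gradient : pixels whose |p| or |q| exceeds this are masked
        (set to ``numpy.inf`` to disable).
    """
    Z = np.asarray(Z, dtype=float)
    mask = np.isfinite(Z) if mask is None else (np.asarray(mask, bool) & np.isfinite(Z))
    dx, dy = camera.pixel_pitch_mm
    Zx, okx = _forward_diff(Z, mask, axis=1, pitch=dx)
    Zy, oky = _forward_diff(Z, mask, axis=0, pitch=dy)
    ok = okx & oky
    Zx = np.where(ok, Zx, 0.0)
    Zy = np.where(ok, Zy, 0.0)
    x, y = camera.grids()
    f = camera.f
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "exact":
            den = Z + x * Zx + y * Zy
            p = f * Zx / den
            q = f * Zy / den
        elif mode == "planar":
            p = f * Zx / Z
            q = f * Zy / Z
        elif mode == "image":
            p = Zx
            q = Zy
        else:
            raise ValueError(f"unknown mode {mode!r}")
    good = ok & np.isfinite(p) & np.isfinite(q)
    good &= (np.abs(np.where(good, p, 0.0)) <= large_gradient) & (
        np.abs(np.where(good, q, 0.0)) <= large_gradient
    )
    p = np.where(good, p, np.nan)
    q = np.where(good, q, np.nan)
    return GradientField(p=p, q=q, mask=good, provenance=provenance)


def sample_training_pairs(
    grad_vbw: GradientField,
    grad_true: GradientField,
    max_abs: float = LARGE_GRADIENT_DEFAULT,
    stride: int = 4,
    count: int | None = None,
    seed: int = 0,
):
    """Paired (p, q) samples mapping solver gradients to true gradients.

    Valid pixels are those valid in both fields with |p_true| and |q_true|
    at most ``max_abs`` (the limb exclusion).  By default every
    ``stride``-th pixel in both grid directions is taken; passing ``count``
    instead draws that many pixels uniformly without replacement with the
    given seed.

    Returns ``(X, Y, idx)``: (N, 2) solver-gradient inputs, (N, 2) true
    targets, and the flat pixel indices sampled.
    """
    if grad_vbw.p.shape != grad_true.p.shape:
        raise ValueError("gradient fields have different shapes")
    valid = (
        grad_vbw.mask
        & grad_true.mask
        & (np.abs(grad_true.p) <= max_abs)
        & (np.abs(grad_true.q) <= max_abs)
    )
    if count is None:
        take = np.zeros_like(valid)
        take[::stride, ::stride] = True
        sel = valid & take
        idx = np.flatnonzero(sel)
    else:
        idx_all = np.flatnonzero(valid)
        if idx_all.size == 0:
            raise ValueError("no valid pixels survive the gradient filter")
        rng = np.random.default_rng(seed)
        count = min(count, idx_all.size)
        idx = np.sort(rng.choice(idx_all, size=count, replace=False))
    if idx.size == 0:
        raise ValueError("no valid pixels survive the gradient filter")
    X = np.column_stack([grad_vbw.p.ravel()[idx], grad_vbw.q.ravel()[idx]])
    Y = np.column_stack([grad_true.p.ravel()[idx], grad_true.q.ravel()[idx]])
    return X, Y, idx
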