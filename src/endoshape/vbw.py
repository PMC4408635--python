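"""Perspective shape-from-shading by explicit Hamilton-Jacobi relaxation.

The solver implements the VBW (Vogel-Breuss-Weickert) scheme for a
Lambertian surface lit by an inverse-square point source at the center of
projection.  Starting from the closed-form initial value

    Z_default = -0.5 * log(I f^2)

each sweep applies the explicit time-marching update

    Z <- Z + dt * exp(-2 Z) - dt * (I f^2 / Q) * sqrt(H)

where ``(m, n)`` are the minimum-magnitude one-sided depth differences in
the x and y image directions and, in the standard grouping of the underlying
Hamiltonian,

    H = f^2 (m^2 + n^2) + (x m + y n)^2 + Q^2.

The iteration runs until the largest per-pixel change in one sweep falls
below a tolerance.  The converged variable is a *relative-scale* shape: it
is the logarithm of the ray distance in focal-length units, so its values
and its gradients are systematically far smaller than the metric depth and
slopes of the scene.  (:func:`metric_depth` exposes the exponential map back
to millimetres for diagnostic use.)  The downstream gradient-correction
network exists precisely to map gradients of this relative output onto true
metric gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel
from .render import RadianceImage

__all__ = [
    "VBWConfig",
    "VBWResult",
    "VBWModel",
    "initial_depth",
    "select_min_gradient",
    "vbw_sweep",
    "solve_vbw",
    "metric_depth",
]

try:  # optional JIT acceleration
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class VBWConfig:
    """Settings of the explicit relaxation scheme.

    dt : explicit time step (halved automatically if the sweep diverges)
    tol : convergence threshold on max per-pixel |dZ| per sweep
    max_iters : sweep cap
    grouping : 'standard' uses the published Hamiltonian
        f^2 (m^2 + n^2) + (x m + y n)^2 + Q^2; 'literal' uses the
        alternative reading f^2 (m^2 x^2 + n^2 y^2) + (x m + y n)^2 + Q^2.
    scheme : 'jacobi' (simultaneous, deterministic default) or
        'gauss_seidel' (in-place, alternating sweep directions; faster).
    """

    dt: float = 1e-4
    tol: float = 1e-6
    max_iters: int = 100_000
    grouping: str = "standard"
    scheme: str = "jacobi"
    use_numba: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.tol <= 0 or self.max_iters < 1:
            raise ValueError("dt, tol must be positive and max_iters >= 1")
        if self.grouping not in ("standard", "literal"):
            raise ValueError("grouping must be 'standard' or 'literal'")
        if self.scheme not in ("jacobi", "gauss_seidel"):
            raise ValueError("scheme must be 'jacobi' or 'gauss_seidel'")


def initial_depth(I: np.ndarray, f: float, mask: np.ndarray | None = None):
    """Closed-form initial depth Z_default = -0.5 log(I f^2).

    Pixels with non-positive intensity inside the mask are invalidated with
    a warning.  Returns ``(Z, mask)``.
    """
    I = np.asarray(I, dtype=float)
    mask = np.ones_like(I, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    bad = mask & ~(I > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} valid pixels with non-positive intensity invalidated")
        mask = mask & (I > 0)
    Z = np.full(I.shape, np.nan)
    Z[mask] = -0.5 * np.log(I[mask] * f * f)
    return Z, mask


def _one_sided(Z: np.ndarray, mask: np.ndarray, axis: int, pitch: float):
    """Forward/backward differences along ``axis`` with validity flags."""
    nan = np.nan
    Zf = np.roll(Z, -1, axis=axis)
    Zb = np.roll(Z, 1, axis=axis)
    mf = np.roll(mask, -1, axis=axis)
    mb = np.roll(mask, 1, axis=axis)
    # roll wraps around; kill the wrapped edge
    edge_f = np.zeros_like(mask)
    edge_b = np.zeros_like(mask)
    sl = [slice(None)] * Z.ndim
    sl[axis] = -1
    edge_f[tuple(sl)] = True
    sl[axis] = 0
    edge_b[tuple(sl)] = True
    have_f = mask & mf & ~edge_f
    have_b = mask & mb & ~edge_b
    df = np.where(have_f, (Zf - Z) / pitch, nan)
    db = np.where(have_b, (Z - Zb) / pitch, nan)
    return df, db, have_f, have_b


def _minmod(df, db, have_f, have_b):
    """Minimum-magnitude admissible one-sided difference.

    Both neighbours valid: 0 if the two differences bracket a local extremum
    (opposite signs), else the smaller in magnitude.  One neighbour: that
    difference.  None: 0.
    """
    both = have_f & have_b
    same_sign = df * db > 0
    pick_f = np.abs(df) <= np.abs(db)
    out = np.zeros_like(df)
    out = np.where(both & same_sign & pick_f, df, out)
    out = np.where(both & same_sign & ~pick_f, db, out)
    out = np.where(have_f & ~have_b, df, out)
    out = np.where(have_b & ~have_f, db, out)
    return np.where(np.isfinite(out), out, 0.0)


def select_min_gradient(Z: np.ndarray, mask: np.ndarray, camera: CameraModel):
    """Upwind minimum-gradient fields (m, n) in mm per mm of image plane.

    ``m`` differences along image x (columns), ``n`` along image y (rows).
    Isolated pixels get (0, 0).
    """
    Z = np.asarray(Z, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    dx, dy = camera.pixel_pitch_mm
    df, db, hf, hb = _one_sided(Z, mask, axis=1, pitch=dx)
    m = _minmod(df, db, hf, hb)
    df, db, hf, hb = _one_sided(Z, mask, axis=0, pitch=dy)
    n = _minmod(df, db, hf, hb)
    m[~mask] = 0.0
    n[~mask] = 0.0
    return m, n


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _sweep_jit(Z, mask, If2_over_Q, x, y, f, Q2, dx, dy, dt, literal, Znew):  # pragma: no cover
        nr, nc = Z.shape
        for j in range(nr):
            for i in range(nc):
                if not mask[j, i]:
                    Znew[j, i] = Z[j, i]
                    continue
                z0 = Z[j, i]
                # x direction
                m = 0.0
                hf = i + 1 < nc and mask[j, i + 1]
                hb = i - 1 >= 0 and mask[j, i - 1]
                if hf and hb:
                    df = (Z[j, i + 1] - z0) / dx
                    db = (z0 - Z[j, i - 1]) / dx
                    if df * db > 0.0:
                        m = df if abs(df) <= abs(db) else db
                elif hf:
                    m = (Z[j, i + 1] - z0) / dx
                elif hb:
                    m = (z0 - Z[j, i - 1]) / dx
                # y direction
                n = 0.0
                hf = j + 1 < nr and mask[j + 1, i]
                hb = j - 1 >= 0 and mask[j - 1, i]
                if hf and hb:
                    df = (Z[j + 1, i] - z0) / dy
                    db = (z0 - Z[j - 1, i]) / dy
                    if df * db > 0.0:
                        n = df if abs(df) <= abs(db) else db
                elif hf:
                    n = (Z[j + 1, i] - z0) / dy
                elif hb:
                    n = (z0 - Z[j - 1, i]) / dy
                xi = x[j, i]
                yi = y[j, i]
                if literal:
                    H = f * f * (m * m * xi * xi + n * n * yi * yi) + (xi * m + yi * n) ** 2 + Q2[j, i]
                else:
                    H = f * f * (m * m + n * n) + (xi * m + yi * n) ** 2 + Q2[j, i]
                Znew[j, i] = z0 + dt * np.exp(-2.0 * z0) - dt * If2_over_Q[j, i] * np.sqrt(H)

    @numba.njit(cache=True, fastmath=True)
    def _sweep_gs_jit(Z, mask, If2_over_Q, x, y, f, Q2, dx, dy, dt, literal, direction):  # pragma: no cover
        """In-place Gauss-Seidel pass; ``direction`` in 0..3 selects the
        corner the sweep starts from.  Returns max |dZ| of the pass."""
        nr, nc = Z.shape
        jr = range(nr) if direction < 2 else range(nr - 1, -1, -1)
        res = 0.0
        for j in jr:
            ir = range(nc) if direction % 2 == 0 else range(nc - 1, -1, -1)
            for i in ir:
                if not mask[j, i]:
                    continue
                z0 = Z[j, i]
                m = 0.0
                hf = i + 1 < nc and mask[j, i + 1]
                hb = i - 1 >= 0 and mask[j, i - 1]
                if hf and hb:
                    df = (Z[j, i + 1] - z0) / dx
                    db = (z0 - Z[j, i - 1]) / dx
                    if df * db > 0.0:
                        m = df if abs(df) <= abs(db) else db
                elif hf:
                    m = (Z[j, i + 1] - z0) / dx
                elif hb:
                    m = (z0 - Z[j, i - 1]) / dx
                n = 0.0
                hf = j + 1 < nr and mask[j + 1, i]
                hb = j - 1 >= 0 and mask[j - 1, i]
                if hf and hb:
                    df = (Z[j + 1, i] - z0) / dy
                    db = (z0 - Z[j - 1, i]) / dy
                    if df * db > 0.0:
                        n = df if abs(df) <= abs(db) else db
                elif hf:
                    n = (Z[j + 1, i] - z0) / dy
                elif hb:
                    n = (z0 - Z[j - 1, i]) / dy
                xi = x[j, i]
                yi = y[j, i]
                if literal:
                    H = f * f * (m * m * xi * xi + n * n * yi * yi) + (xi * m + yi * n) ** 2 + Q2[j, i]
                else:
                    H = f * f * (m * m + n * n) + (xi * m + yi * n) ** 2 + Q2[j, i]
                znew = z0 + dt * np.exp(-2.0 * z0) - dt * If2_over_Q[j, i] * np.sqrt(H)
                d = abs(znew - z0)
                if d > res:
                    res = d
                Z[j, i] = znew
        return res


@dataclass
class VBWResult:
    """Converged (or best) relative depth with iteration diagnostics."""

    depth: np.ndarray
    mask: np.ndarray
    camera: CameraModel
    iterations: int
    final_max_update: float
    converged: bool
    dt_used: float
    frozen_pixels: int
    config: VBWConfig
    residual_history: np.ndarray = field(default=None)

    def metric_depth(self) -> np.ndarray:
        """Exponential map of the relative output to millimetres (diagnostic)."""
        return metric_depth(self.depth, self.camera, self.mask)

    def summary(self) -> str:
        lines = [
            "VBW perspective shape-from-shading",
            "==================================",
            f"grid             : {self.depth.shape[1]} x {self.depth.shape[0]}",
            f"valid pixels     : {int(self.mask.sum())}",
            f"scheme           : {self.config.scheme} ({self.config.grouping} grouping)",
            f"dt               : {self.dt_used:g} (initial {self.config.dt:g})",
            f"iterations       : {self.iterations}",
            f"final max |dZ|   : {self.final_max_update:.3e} (tol {self.config.tol:g})",
            f"converged        : {self.converged}",
            f"frozen pixels    : {self.frozen_pixels}",
        ]
        zv = self.depth[self.mask]
        if zv.size:
            lines.append(f"depth range      : [{zv.min():.4f}, {zv.max():.4f}] (relative scale)")
        return "\n".join(lines)


class VBWModel:
    """Relaxation model for one radiance image.

    Parameters
    ----------
    image : RadianceImage or ndarray
        Observed irradiance.  An ndarray is taken to be already-normalized
        intensity I; a :class:`RadianceImage` is normalized by its C.
    camera : CameraModel
    config : VBWConfig, optional
    """

    def __init__(self, image, camera: CameraModel, config: VBWConfig | None = None, mask=None):
        self.camera = camera
        self.config = config or VBWConfig()
        if isinstance(image, RadianceImage):
            self.I = image.normalized
            self.mask = image.mask.copy() if mask is None else np.asarray(mask, bool)
        else:
            self.I = np.asarray(image, dtype=float)
            self.mask = (
                np.asarray(mask, bool) if mask is not None else np.isfinite(self.I) & (self.I > 0)
            )
        if self.I.shape != tuple(reversed(camera.pixel_dims)):
            raise ValueError("image shape does not match camera pixel_dims")

    def fit(self, callback=None) -> VBWResult:
        cfg = self.config
        cam = self.camera
        f = cam.f
        x, y = cam.grids()
        Q = cam.q_map()
        Q2 = Q * Q
        dx, dy = cam.pixel_pitch_mm
        Z, mask = initial_depth(self.I, f, self.mask)
        If2_over_Q = np.where(mask, self.I * f * f / Q, 0.0)
        Zw = np.where(mask, Z, 0.0)  # work on finite values everywhere
        dt = cfg.dt
        literal = cfg.grouping == "literal"
        use_jit = cfg.use_numba and _HAVE_NUMBA
        gauss_seidel = cfg.scheme == "gauss_seidel"
        if gauss_seidel and not _HAVE_NUMBA:
            raise RuntimeError("the gauss_seidel scheme requires numba; use scheme='jacobi'")
        mask_c = np.ascontiguousarray(mask)
        frozen_total = 0
        res_hist = []
        it = 0
        converged = False
        Znew = np.empty_like(Zw)
        best_res = np.inf
        while it < cfg.max_iters:
            if gauss_seidel:
                res = _sweep_gs_jit(
                    Zw, mask_c, If2_over_Q, x, y, f, Q2, dx, dy, dt, literal, it % 4
                )
                bad = mask & ~np.isfinite(Zw)
                n_bad = int(bad.sum())
                if n_bad:
                    raise RuntimeError(
                        f"VBW Gauss-Seidel sweep diverged at iteration {it}: "
                        f"{n_bad} non-finite pixels"
                    )
                res_hist.append(res)
                it += 1
                if callback is not None and it % 1000 == 0:
                    callback(it, res)
                if res <= cfg.tol:
                    converged = True
                    break
                continue
            if use_jit:
                _sweep_jit(Zw, mask_c, If2_over_Q, x, y, f, Q2, dx, dy, dt, literal, Znew)
            else:
                m, n = select_min_gradient(Zw, mask_c, cam)
                if literal:
                    H = f * f * (m * m * x * x + n * n * y * y) + (x * m + y * n) ** 2 + Q2
                else:
                    H = f * f * (m * m + n * n) + (x * m + y * n) ** 2 + Q2
                with np.errstate(over="ignore", invalid="ignore"):
                    Znew = Zw + dt * np.exp(-2.0 * Zw) - dt * If2_over_Q * np.sqrt(H)
            bad = mask & ~np.isfinite(Znew)
            n_bad = int(bad.sum())
            if n_bad:
                if n_bad > 0.01 * mask.sum():
                    raise RuntimeError(
                        f"VBW sweep diverged: {n_bad} non-finite pixels at iteration {it}"
                    )
                Znew[bad] = Zw[bad]
                frozen_total += n_bad
            delta = np.abs(Znew - Zw)[mask]
            res = float(delta.max()) if delta.size else 0.0
            res_hist.append(res)
            if not np.isfinite(res) or (it > 10 and res > 10.0 * best_res):
                dt *= 0.5  # divergence guard: restart step size
                continue
            best_res = min(best_res, res)
            Zw, Znew = Znew, Zw
            it += 1
            if callback is not None and it % 1000 == 0:
                callback(it, res)
            if res <= cfg.tol:
                converged = True
                break
        Zout = np.where(mask, Zw, np.nan)
        return VBWResult(
            depth=Zout,
            mask=mask,
            camera=cam,
            iterations=it,
            final_max_update=res_hist[-1] if res_hist else 0.0,
            converged=converged,
            dt_used=dt,
            frozen_pixels=frozen_total,
            config=cfg,
            residual_history=np.asarray(res_hist),
        )


def vbw_sweep(Z, I, camera: CameraModel, cfg: VBWConfig, mask=None):
    """One full-grid Jacobi update (functional form used by the tests)."""
    Z = np.asarray(Z, dtype=float)
    I = np.asarray(I, dtype=float)
    mask = np.isfinite(Z) if mask is None else np.asarray(mask, bool)
    f = camera.f
    x, y = camera.grids()
    Q = camera.q_map()
    m, n = select_min_gradient(np.where(mask, Z, 0.0), mask, camera)
    if cfg.grouping == "literal":
        H = f * f * (m * m * x * x + n * n * y * y) + (x * m + y * n) ** 2 + Q * Q
    else:
        H = f * f * (m * m + n * n) + (x * m + y * n) ** 2 + Q * Q
    with np.errstate(over="ignore", invalid="ignore"):
        Znew = Z + cfg.dt * np.exp(-2.0 * Z) - cfg.dt * (I * f * f / Q) * np.sqrt(H)
    return np.where(mask, Znew, Z)


def solve_vbw(image, camera: CameraModel, cfg: VBWConfig | None = None, mask=None) -> VBWResult:
    """Initial depth plus repeated sweeps until convergence (see VBWModel)."""
    return VBWModel(image, camera, cfg, mask=mask).fit()


def metric_depth(Z_rel: np.ndarray, camera: CameraModel, mask=None) -> np.ndarray:
    """Map the solver's relative (log ray-distance) output to mm depth.

    The relaxation variable equals log(r / f) with r the light-to-surface
    distance, so metric depth along the optical axis is Z = Q * f * exp(v).
    """
    Q = camera.q_map()
    out = camera.f * Q * np.exp(np.asarray(Z_rel, dtype=float))
    if mask is not None:
        out = np.where(np.asarray(mask, bool), out, np.nan)
    return out
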