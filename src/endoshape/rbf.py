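"""Radial-basis-function network correcting solver gradients to metric ones.

The relative-scale solver systematically compresses surface gradients.  A
small Gaussian RBF network learns the pixel-wise map from solver gradients
``(p, q)`` to the true gradients on a synthetic sphere, which exposes the
full range of orientations; the learned map is then applied to any other
scene, since it acts on local gradients rather than on global shape.

Training follows the classic incremental-center design: one Gaussian unit is
added per epoch at the training sample with the largest current error, and
the linear output layer (plus bias) is refit by least squares.  Training
stops when the mean squared error reaches the goal or at the epoch cap.
With a global width and exact refits the training error is non-increasing
in the number of units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .gradients import GradientField

__all__ = [
    "RBFTrainingConfig",
    "RBFGradientModel",
    "RBFResults",
    "train_rbf",
    "correct_gradients",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass
class RBFTrainingConfig:
    """Error goal is on the per-sample MSE summed over the two outputs."""

    error_goal: float = 0.1
    max_epochs: int = 500
    width: float | None = None  # None: median pairwise input distance rule
    seed: int = 0

    def __post_init__(self):
        if self.error_goal <= 0 or self.max_epochs < 1:
            raise ValueError("error_goal must be positive, max_epochs >= 1")


def _median_width(X: np.ndarray, seed: int) -> float:
    """Global Gaussian width: median pairwise distance of <=500 inputs."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    sub = X if n <= 500 else X[np.sort(rng.choice(n, 500, replace=False))]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(d2[np.triu_indices(sub.shape[0], k=1)])
    w = float(np.median(d))
    if w <= 0:
        raise ValueError("degenerate training inputs (zero median spacing)")
    return w


def _design(X: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """N x (k+1) design matrix: Gaussian activations plus a bias column."""
    if centers.size:
        d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        phi = np.exp(-0.5 * d2 / width**2)
    else:
        phi = np.empty((X.shape[0], 0))
    return np.hstack([phi, np.ones((X.shape[0], 1))])


@dataclass
class RBFResults:
    """Trained corrector: centers, global width, linear output layer."""

    centers: np.ndarray  # (k, 2)
    width: float
    weights: np.ndarray  # (k + 1, 2), last row is the bias
    epochs: int
    final_error: float
    converged: bool
    error_goal: float
    max_epochs: int
    seed: int
    coverage_radius: float  # max distance of a training input to its nearest center
    error_history: np.ndarray = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _design(X, self.centers, self.width) @ self.weights

    def nearest_center_distance(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.centers.size:
            return np.full(X.shape[0], np.inf)
        d2 = np.sum((X[:, None, :] - self.centers[None, :, :]) ** 2, axis=-1)
        return np.sqrt(d2.min(axis=1))

    def summary(self) -> str:
        return "\n".join(
            [
                "RBF gradient corrector",
                "======================",
                f"hidden units   : {self.centers.shape[0]}",
                f"global width   : {self.width:.6g}",
                f"epochs run     : {self.epochs} (cap {self.max_epochs})",
                f"final MSE      : {self.final_error:.6g} (goal {self.error_goal:g})",
                f"reached goal   : {self.converged}",
            ]
        )


class RBFGradientModel:
    """Regression model from solver gradients to true gradients.

    Parameters
    ----------
    X : (N, 2) array of solver-estimated (p, q) inputs.
    Y : (N, 2) array of true (p, q) targets.
    config : RBFTrainingConfig, optional.
    """

    def __init__(self, X, Y, config: RBFTrainingConfig | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y have different lengths")
        if self.X.shape[0] < 10:
            raise ValueError("need at least 10 training pairs")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("non-finite training values")
        if np.allclose(self.X, self.X[0]):
            raise ValueError("degenerate training data: all inputs identical")
        self.config = config or RBFTrainingConfig()

    def fit(self) -> RBFResults:
        cfg = self.config
        X, Y = self.X, self.Y
        n = X.shape[0]
        width = cfg.width if cfg.width is not None else _median_width(X, cfg.seed)

        centers_idx: list[int] = []
        # least-squares refits via an incrementally grown QR factorization of
        # the design matrix (bias column first); numerically stable, and the
        # training error is then non-increasing in the number of units
        Phi = np.ones((n, 1))
        Qf, R = np.linalg.qr(Phi)
        W_int = scipy.linalg.solve_triangular(R, Qf.T @ Y)
        pred = Phi @ W_int
        err_hist = []
        mse = float(np.mean(np.sum((pred - Y) ** 2, axis=1)))
        epochs = 0
        for _ in range(cfg.max_epochs):
            if mse <= cfg.error_goal:
                break
            per_sample = np.sum((pred - Y) ** 2, axis=1)
            per_sample[centers_idx] = -np.inf  # each sample may host one unit
            ci = int(np.argmax(per_sample))
            centers_idx.append(ci)
            col = np.exp(-0.5 * np.sum((X - X[ci]) ** 2, axis=1) / width**2)
            Qf, R = scipy.linalg.qr_insert(Qf, R, col, Qf.shape[1], which="col")
            diag = np.abs(np.diag(R))
            if diag.min() < 1e-12 * diag.max():
                # nearly dependent unit: ridge-regularized solve for this refit
                W_int = np.linalg.lstsq(R, Qf.T @ Y, rcond=1e-12)[0]
            else:
                W_int = scipy.linalg.solve_triangular(R, Qf.T @ Y)
            Phi = np.hstack([Phi, col[:, None]])
            pred = Phi @ W_int
            mse = float(np.mean(np.sum((pred - Y) ** 2, axis=1)))
            err_hist.append(mse)
            epochs += 1
        # reorder weights: unit rows first, bias last (the public layout)
        W = np.vstack([W_int[1:], W_int[:1]])
        centers = X[centers_idx] if centers_idx else np.empty((0, 2))
        if centers.size:
            d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
            coverage = float(np.sqrt(d2.min(axis=1)).max())
        else:
            coverage = float("inf")
        return RBFResults(
            centers=np.asarray(centers, dtype=float),
            width=width,
            weights=np.asarray(W, dtype=float),
            epochs=epochs,
            final_error=mse,
            converged=mse <= cfg.error_goal,
            error_goal=cfg.error_goal,
            max_epochs=cfg.max_epochs,
            seed=cfg.seed,
            coverage_radius=coverage,
            error_history=np.asarray(err_hist),
        )


def train_rbf(pairs, cfg: RBFTrainingConfig | None = None) -> RBFResults:
    """Functional wrapper: ``pairs`` is the (X, Y) tuple of training arrays."""
    X, Y = pairs[0], pairs[1]
    return RBFGradientModel(X, Y, cfg).fit()


def correct_gradients(model: RBFResults, grads: GradientField) -> GradientField:
    """Apply the corrector pixel-wise to a solver gradient field.

    The returned field carries provenance ``nn-corrected`` and an
    ``extrapolated`` boolean raster marking pixels whose input lies farther
    than three coverage radii from every training center (corrected anyway,
    but not supported by training data).
    """
    if grads.provenance != "vbw":
        raise ValueError("correct_gradients expects a solver ('vbw') gradient field")
    mask = grads.mask
    X = np.column_stack([grads.p[mask], grads.q[mask]])
    out = model.predict(X)
    p = np.full(grads.p.shape, np.nan)
    q = np.full(grads.q.shape, np.nan)
    p[mask] = out[:, 0]
    q[mask] = out[:, 1]
    corrected = GradientField(p=p, q=q, mask=mask.copy(), provenance="nn-corrected")
    extrap = np.zeros(grads.p.shape, dtype=bool)
    if np.isfinite(model.coverage_radius):
        extrap[mask] = model.nearest_center_distance(X) > 3.0 * model.coverage_radius
    corrected.extrapolated = extrap
    return corrected


def save_model(model: RBFResults, path) -> None:
    """Lossless JSON serialization of a trained corrector."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "centers": model.centers.tolist(),
        "width": model.width,
        "weights": model.weights.tolist(),
        "epochs": model.epochs,
        "final_error": model.final_error,
        "converged": model.converged,
        "error_goal": model.error_goal,
        "max_epochs": model.max_epochs,
        "seed": model.seed,
        "coverage_radius": model.coverage_radius,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> RBFResults:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"cannot read RBF model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported RBF model format version: {version!r}")
    return RBFResults(
        centers=np.asarray(payload["centers"], dtype=float).reshape(-1, 2),
        width=float(payload["width"]),
        weights=np.asarray(payload["weights"], dtype=float),
        epochs=int(payload["epochs"]),
        final_error=float(payload["final_error"]),
        converged=bool(payload["converged"]),
        error_goal=float(payload["error_goal"]),
        max_epochs=int(payload["max_epochs"]),
        seed=int(payload["seed"]),
        coverage_radius=float(payload["coverage_radius"]),
    )
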