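"""End-to-end simulation experiments and error metrics.

The benchmark protocol trains the gradient corrector on one synthetic sphere
and evaluates generalization on a different scene:

* train scene: sphere, radius 5 mm, center (0, 0, 15), reflectance 100,
  256 x 256 pixels over a 9 x 9 mm image plane, focal length 10 mm;
* test scene A: sphere, radius 3 mm, same center, reflectance 50,
  360 x 360 pixels;
* test scene B: cosine-corrugated surface at base depth 12 mm, wavelength
  4 mm, amplitude 1 mm, reflectance 120, 360 x 360 pixels.

For each test scene the experiment reports mean absolute errors of the
gradient components and of depth (mm), once for the raw relative-scale
solver output and once for the proposed pipeline (solver -> RBF gradient
correction -> pointwise absolute depth).  Errors are averaged over the
intersection of all validity masks with the limb exclusion of the ground
truth; the pixel count is part of every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .camera import CameraModel
from .gradients import GradientField, gradients_from_depth, sample_training_pairs
from .rbf import RBFTrainingConfig, RBFGradientModel, RBFResults, correct_gradients
from .reconstruct import depth_from_gradients
from .render import GroundTruthBundle, render
from .surfaces import CosineSurface, SphereSurface, surface_from_dict, LARGE_GRADIENT_DEFAULT
from .vbw import VBWConfig, VBWModel

__all__ = [
    "ErrorReport",
    "ExperimentConfig",
    "ExperimentResult",
    "mean_errors",
    "run_experiment",
    "sphere_experiment_config",
    "cosine_experiment_config",
]


@dataclass
class ErrorReport:
    """Mean absolute errors of one method on one scene."""

    method: str  # 'vbw' | 'proposed'
    scene: str
    mean_abs_p: float
    mean_abs_q: float
    mean_abs_z_mm: float
    n_pixels: int

    def __post_init__(self):
        if self.n_pixels <= 0:
            raise ValueError("empty evaluation mask")


def mean_errors(
    est_Z: np.ndarray,
    est_grads: GradientField,
    truth: GroundTruthBundle,
    method: str = "",
    scene: str = "",
    extra_mask: np.ndarray | None = None,
) -> ErrorReport:
    """Mean |dp|, |dq|, |dZ| over the intersection of validity masks.

    The evaluation region is: truth valid, truth below the limb-gradient
    threshold, estimate valid (finite depth and valid gradients), and any
    caller-supplied extra mask.
    """
    est_Z = np.asarray(est_Z, dtype=float)
    mask = truth.limb_mask & est_grads.mask & np.isfinite(est_Z)
    if extra_mask is not None:
        mask = mask & np.asarray(extra_mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask intersection in mean_errors")
    return ErrorReport(
        method=method,
        scene=scene,
        mean_abs_p=float(np.mean(np.abs(est_grads.p[mask] - truth.p[mask]))),
        mean_abs_q=float(np.mean(np.abs(est_grads.q[mask] - truth.q[mask]))),
        mean_abs_z_mm=float(np.mean(np.abs(est_Z[mask] - truth.depth[mask]))),
        n_pixels=n,
    )


@dataclass
class ExperimentConfig:
    """Everything needed to run one train-on-sphere / test-on-scene experiment."""

    test_surface: object = field(default_factory=lambda: SphereSurface((0, 0, 15.0), 3.0))
    test_C: float = 50.0
    test_dims: tuple[int, int] = (360, 360)
    scene_name: str = "sphere"
    train_surface: object = field(default_factory=lambda: SphereSurface((0, 0, 15.0), 5.0))
    train_C: float = 100.0
    train_dims: tuple[int, int] = (256, 256)
    focal_length_mm: float = 10.0
    image_extent_mm: tuple[float, float] = (9.0, 9.0)
    vbw: VBWConfig = field(default_factory=VBWConfig)
    rbf: RBFTrainingConfig = field(default_factory=RBFTrainingConfig)
    sample_stride: int = 4
    max_abs_gradient: float = LARGE_GRADIENT_DEFAULT
    vbw_gradient_mode: str = "planar"
    seed: int = 0

    def train_camera(self) -> CameraModel:
        return CameraModel(self.focal_length_mm, self.image_extent_mm, self.train_dims)

    def test_camera(self) -> CameraModel:
        return CameraModel(self.focal_length_mm, self.image_extent_mm, self.test_dims)

    def to_dict(self) -> dict:
        return {
            "test_surface": self.test_surface.to_dict(),
            "test_C": self.test_C,
            "test_dims": list(self.test_dims),
            "scene_name": self.scene_name,
            "train_surface": self.train_surface.to_dict(),
            "train_C": self.train_C,
            "train_dims": list(self.train_dims),
            "focal_length_mm": self.focal_length_mm,
            "image_extent_mm": list(self.image_extent_mm),
            "vbw": asdict(self.vbw),
            "rbf": asdict(self.rbf),
            "sample_stride": self.sample_stride,
            "max_abs_gradient": self.max_abs_gradient,
            "vbw_gradient_mode": self.vbw_gradient_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        kw["test_surface"] = surface_from_dict(kw["test_surface"])
        kw["train_surface"] = surface_from_dict(kw["train_surface"])
        kw["test_dims"] = tuple(kw["test_dims"])
        kw["train_dims"] = tuple(kw["train_dims"])
        kw["image_extent_mm"] = tuple(kw["image_extent_mm"])
        kw["vbw"] = VBWConfig(**kw["vbw"])
        kw["rbf"] = RBFTrainingConfig(**kw["rbf"])
        return cls(**kw)


@dataclass
class ExperimentResult:
    """Reports plus every intermediate artifact of one experiment run."""

    config: ExperimentConfig
    report_vbw: ErrorReport
    report_proposed: ErrorReport
    corrector: RBFResults
    train_bundle: GroundTruthBundle
    test_bundle: GroundTruthBundle
    vbw_train: object
    vbw_test: object
    grads_vbw: GradientField
    grads_corrected: GradientField
    depth_proposed: object

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "method": r.method,
                "mean_p": r.mean_abs_p,
                "mean_q": r.mean_abs_q,
                "mean_Z_mm": r.mean_abs_z_mm,
                "n_pixels": r.n_pixels,
            }
            for r in (self.report_vbw, self.report_proposed)
        ]
        return pd.DataFrame(rows, index=["VBW", "Proposed"])

    def summary(self) -> str:
        tbl = self.table()
        ratio = self.report_vbw.mean_abs_z_mm / max(self.report_proposed.mean_abs_z_mm, 1e-300)
        return (
            f"Scene: {self.config.scene_name}\n"
            f"Mean absolute errors over {self.report_vbw.n_pixels} pixels\n"
            f"{tbl.to_string(float_format=lambda v: f'{v:.4f}')}\n"
            f"Depth error reduction: {ratio:.1f}x\n"
            f"Corrector: {self.corrector.epochs} epochs, final MSE "
            f"{self.corrector.final_error:.4g}"
        )


def _fit_corrector(cfg: ExperimentConfig):
    """Render the training sphere, run the solver, fit the corrector."""
    cam = cfg.train_camera()
    bundle = render(cfg.train_surface, cam, C=cfg.train_C, large_gradient=cfg.max_abs_gradient)
    sol = VBWModel(bundle.radiance, cam, cfg.vbw).fit()
    g_vbw = gradients_from_depth(
        sol.depth, cam, mask=sol.mask, mode=cfg.vbw_gradient_mode, provenance="vbw"
    )
    g_true = GradientField(bundle.p, bundle.q, bundle.mask, provenance="true")
    X, Y, _ = sample_training_pairs(
        g_vbw, g_true, max_abs=cfg.max_abs_gradient, stride=cfg.sample_stride, seed=cfg.seed
    )
    rbf_cfg = RBFTrainingConfig(
        error_goal=cfg.rbf.error_goal,
        max_epochs=cfg.rbf.max_epochs,
        width=cfg.rbf.width,
        seed=cfg.seed,
    )
    corrector = RBFGradientModel(X, Y, rbf_cfg).fit()
    return bundle, sol, corrector


def run_experiment(cfg: ExperimentConfig, corrector: RBFResults | None = None) -> ExperimentResult:
    """Full protocol: train corrector on the sphere, evaluate on the test scene.

    A pre-trained ``corrector`` may be supplied to share the training stage
    between experiments (the published protocol trains once on the sphere).
    """
    if corrector is None:
        train_bundle, vbw_train, corrector = _fit_corrector(cfg)
    else:
        train_bundle = vbw_train = None

    cam = cfg.test_camera()
    test_bundle = render(cfg.test_surface, cam, C=cfg.test_C, large_gradient=cfg.max_abs_gradient)
    vbw_test = VBWModel(test_bundle.radiance, cam, cfg.vbw).fit()
    g_vbw = gradients_from_depth(
        vbw_test.depth, cam, mask=vbw_test.mask, mode=cfg.vbw_gradient_mode, provenance="vbw"
    )
    g_corr = correct_gradients(corrector, g_vbw)
    recon = depth_from_gradients(test_bundle.radiance, g_corr, cam, C=cfg.test_C)

    report_vbw = mean_errors(
        vbw_test.depth, g_vbw, test_bundle, method="vbw", scene=cfg.scene_name,
        extra_mask=g_corr.mask & recon.mask,
    )
    report_prop = mean_errors(
        recon.depth, g_corr, test_bundle, method="proposed", scene=cfg.scene_name,
        extra_mask=g_vbw.mask,
    )
    return ExperimentResult(
        config=cfg,
        report_vbw=report_vbw,
        report_proposed=report_prop,
        corrector=corrector,
        train_bundle=train_bundle,
        test_bundle=test_bundle,
        vbw_train=vbw_train,
        vbw_test=vbw_test,
        grads_vbw=g_vbw,
        grads_corrected=g_corr,
        depth_proposed=recon,
    )


def sphere_experiment_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Sphere generalization benchmark (train R=5/C=100, test R=3/C=50)."""
    return ExperimentConfig(scene_name="sphere", seed=seed, **overrides)


def cosine_experiment_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Cosine-surface benchmark (base depth 12 mm, wavelength 4 mm, amplitude 1 mm, C=120)."""
    return ExperimentConfig(
        test_surface=CosineSurface(base_depth=12.0, wavelength=4.0, amplitude=1.0),
        test_C=120.0,
        scene_name="cosine",
        seed=seed,
        **overrides,
    )
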