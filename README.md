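# endoshape

Absolute-size 3D shape from a single shading image in endoscope geometry.

Assessing a colorectal polyp requires its *metric* size and shape, but a
standard monocular endoscope image carries no scale.  Its imaging geometry
is special, though: the illumination is a point light essentially at the
lens center, so image irradiance of a Lambertian mucosal surface follows
the inverse-square law

    E = C (s·n) / r²  =  C (−px − qy + f) V / (Z² √(p² + q² + 1)),

with reflectance `C`, focal length `f`, image coordinates `(x, y)` in mm,
world surface gradients `(p, q) = (∂Z/∂X, ∂Z/∂Y)`, and
`V = f²/(x²+y²+f²)^{3/2}`.  Because the source distance enters the
irradiance, this equation fixes absolute depth — *if* the gradients are
known.

The package implements a three-stage pipeline for users of this geometry
(endoscopic imaging researchers, and anyone doing near-light photometric
shape recovery):

1. **Hamilton–Jacobi shape-from-shading** (`VBWModel`): explicit upwind
   relaxation of the perspective/point-source irradiance equation from the
   closed-form initial value `Z_default = −0.5 ln(I f²)`.  Its converged
   variable is log ray-distance — a correct *relative* shape whose values
   and gradients are far smaller than metric truth.
2. **RBF gradient correction** (`RBFGradientModel`): a Gaussian
   radial-basis-function network trained on a synthetic Lambertian sphere
   (which exposes every surface orientation) learns the pixel-wise map from
   solver gradients to true metric gradients, then generalizes to unseen
   scenes.
3. **Pointwise absolute depth** (`depth_from_gradients`): the exact
   algebraic inversion `Z = √(C V (−px−qy+f) / (E √(p²+q²+1)))` turns the
   corrected gradients and the observed irradiance into depth in mm —
   no gradient-field integration involved.

Synthetic scenes (spheres, cosine-corrugated surfaces, height fields), the
Lambertian renderer with ground-truth bundles, and the benchmark
experiments are first-class parts of the package.

## Worked example

Train the corrector on a 5 mm sphere and recover an unseen 3 mm sphere
(96×96 for speed; the benchmark uses 256²/360²):

```python
import numpy as np
from endoshape import (
    CameraModel, SphereSurface, render, VBWModel, VBWConfig,
    gradients_from_depth, GradientField, sample_training_pairs,
    RBFGradientModel, RBFTrainingConfig, correct_gradients,
    depth_from_gradients, mean_errors,
)

cam = CameraModel(focal_length_mm=10.0, image_extent_mm=(9, 9), pixel_dims=(96, 96))
train = render(SphereSurface(center=(0, 0, 15.0), radius=5.0), cam, C=100.0)
sol = VBWModel(train.radiance, cam, VBWConfig()).fit()
print(sol.summary())

g_vbw = gradients_from_depth(sol.depth, cam, mask=sol.mask, mode="planar", provenance="vbw")
g_true = GradientField(train.p, train.q, train.mask, "true")
X, Y, _ = sample_training_pairs(g_vbw, g_true, stride=4, seed=0)
rbf = RBFGradientModel(X, Y, RBFTrainingConfig()).fit()

test = render(SphereSurface(center=(0, 0, 15.0), radius=3.0), cam, C=50.0)
sol_t = VBWModel(test.radiance, cam, VBWConfig()).fit()
g_t = gradients_from_depth(sol_t.depth, cam, mask=sol_t.mask, mode="planar", provenance="vbw")
g_c = correct_gradients(rbf, g_t)
rec = depth_from_gradients(test.radiance, g_c, cam, C=50.0)
```

Output (abridged):

```
VBW perspective shape-from-shading
==================================
grid             : 96 x 96
iterations       : 16943
converged        : True
depth range      : [0.0002, 0.4225] (relative scale)

raw solver : mean|dp| = 2.352, mean|dZ| = 12.38 mm
proposed   : mean|dp| = 0.359, mean|dZ| = 1.89 mm
depth range: [11.58, 25.26] mm (truth [12, ~14.7])
```

Reading this: the solver's relative output sits around 0.0–0.4 — a correct
shape but ~12 mm from metric depth, with strongly biased gradients.  After
RBF correction the gradient error drops ~7-fold, and the pointwise
inversion places the reconstruction on the true 12–15 mm scale from a
single image.  The residual depth error concentrates at steep-slant pixels
near the silhouette, where irradiance is grazing and depth is
hypersensitive to gradient error (hence the 25 mm outlier at the mask
edge).

A command-line interface mirrors the library
(`endoshape synthesize / vbw / gradients / rbf-train / rbf-apply / recover /
simulate`); rasters travel as grayscale PFM files with JSON sidecars.

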