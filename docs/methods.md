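# Methods

## Problem and imaging model

The package recovers metric 3D shape from a single grayscale image taken in
the geometry of a medical endoscope: a pinhole camera at the world origin
with a point light source at the same origin, perspective projection, and a
Lambertian target (real endoscope frames must be converted to a uniform
Lambertian grayscale image beforehand; that preprocessing is outside this
package's scope).  Image-plane coordinates `(x, y)` are physical mm; `f` is
the focal length.  Two per-pixel coefficients recur: the perspective cosine
`Q = f/sqrt(x² + y² + f²)` and `V = Q³/f`.

The forward model for image irradiance is the inverse-square Lambertian law
`E = C (s·n)/r²`, which, expanded in the depth map `Z(x, y)` and its world
gradients `(p, q) = (∂Z/∂X, ∂Z/∂Y)`, reads

    E = C (−px − qy + f) V / (Z² sqrt(p² + q² + 1)).        (forward model)

The renderer evaluates exactly this expression on ray-cast ground truth;
a property suite checks it against the vector form `C (s·n)/r²` built from
explicit geometry.  Images are kept in float irradiance — quantization is an
optional export step, so solver accuracy is not limited by bit depth.

## The Hamilton–Jacobi solver and what "relative scale" means

The shape-from-shading stage is an explicit relaxation of the
perspective/point-source Hamilton–Jacobi equation.  With normalized
intensity `I = E/C` it starts from `Z_default = −0.5 ln(I f²)` and iterates

    Z ← Z + Δt e^{−2Z} − Δt (I f²/Q) sqrt(f²(m² + n²) + (xm + yn)² + Q²),

where `(m, n)` are minimum-magnitude one-sided differences (a minmod
selection: zero when forward and backward differences bracket a local
extremum).  One can show the stationary equation of this update, under the
substitution `v = ln(r/f)` with `r` the light-to-surface distance, is
*exactly equivalent* to the forward model above.  The converged variable is
therefore log ray-distance in focal-length units, not metric depth: for a
scene at `Z ≈ 12–15 mm` and `f = 10 mm` it lies around `0.2–0.4`.  This is
the precise sense in which the solver output is a relative shape whose
values and gradients are systematically far smaller than the metric truth.
`metric_depth()` exposes the exponential map `Z = Q f e^v` for diagnostics;
the correction pipeline deliberately does **not** use it (see below).

Numerical choices:

* `Δt = 1e-4` by default (the scheme is an explicit time-marching
  relaxation; the step is halved automatically if a sweep diverges).  The
  CFL bound for the benchmark scenes is ≈ 1e-3, so the default is safely
  inside it.
* Convergence is declared when the largest per-pixel change in a sweep falls
  below `tol = 1e-6`, with a cap of 1e5 sweeps.  On the benchmark spheres
  this is reached after ~15–30k sweeps; on the cosine scene the Jacobi
  iteration plateaus near 1.4e-4 and stops at the cap with the
  non-converged flag set (the plateau is localized at the corrugation's
  curvature sign changes and does not visibly affect downstream results).
* Jacobi (simultaneous) updates are the default for determinism; an
  in-place Gauss–Seidel variant with rotating sweep directions is available
  (`scheme="gauss_seidel"`, requires numba) and relaxes in fewer sweeps.
* Pixels whose update turns non-finite are frozen at their previous value
  and counted; more than 1% frozen aborts with a diagnostic.
* Boundary and mask edges use the available one-sided difference; isolated
  pixels get `(m, n) = (0, 0)`.

The update's radicand grouping follows the published Hamiltonian
`f²(m²+n²) + (xm+yn)² + Q²`; it reduces to the on-axis fixed-point identity
and is the form that makes the stationarity equivalence above exact.  A
typographically plausible alternative grouping `f²(m²x²+n²y²) + …` is kept
behind `VBWConfig(grouping="literal")` for comparison only.

## Gradients from depth maps

`gradients_from_depth` differentiates a depth raster by forward differences
(backward at trailing edges) and converts image-plane derivatives to world
gradients.  For *metric* depth the exact perspective chain rule is used:

    p = f Z_x / (Z + x Z_x + y Z_y),   q = f Z_y / (Z + x Z_x + y Z_y),

obtained by solving the 2×2 system that couples the two image directions
(the world footprint of a pixel step moves in X, Y *and* Z).  With true
rendered depth this reproduces the analytic sphere gradients to first order
in the pixel pitch and keeps the depth round trip consistent.

For the solver's *relative* output the exact rule is meaningless — its
denominator mixes a log-distance value (~0.3) with mm-scale image
coordinates and crosses zero on a ring, producing unbounded gradients.  The
pipeline therefore converts solver maps with the planar approximation
`p = (f/Z) Z_x` (`mode="planar"`), which is smooth and bounded; the raw
image-plane derivative (`mode="image"`) is also available.  This choice was
made by measuring end-to-end benchmark error for all three conversions
(exact: corrected p 0.40 / depth 3.4 mm on the test sphere; planar:
0.28 / 1.9 mm; image: 0.19 / 1.8 mm but with a much weaker raw-vs-corrected
contrast); planar gives the best overall trade-off and is the default.

Gradient fields are masked where |p| or |q| exceeds the large-gradient
threshold (default 10, matching the limb exclusion of the ground truth).

## The RBF corrector

A single-hidden-layer Gaussian RBF network maps solver gradients `(p, q)`
to true gradients, trained on the radius-5 sphere — a scene that exposes
every surface orientation — and applied pixel-wise to any other scene.
Training pairs are every 4th pixel in both grid directions, keeping pairs
whose *true* gradients satisfy |p|, |q| ≤ 10.

Training is the classic incremental-unit design: per epoch, one Gaussian
unit is placed at the sample with the largest current error and the linear
output layer (plus bias) is refit by least squares, implemented with an
incrementally grown QR factorization so the refit is numerically stable and
the training error is non-increasing in the number of units.  Training
stops at a mean-squared-error goal of 0.1 (per sample, summed over the two
output components) or after 500 epochs, both benchmark settings.  The
global width is the median pairwise distance of a 500-point input
subsample.  A width sweep showed that much narrower widths need hundreds of
epochs to reach the goal but generalize strictly worse across scenes;
the median-pairwise rule generalizes best and is kept.  Inputs and outputs
are not standardized (gradients are already order-1 after limb filtering);
users with different thresholds can standardize externally.

Determinism: the width subsample and any random sampling derive from a
single seed (default 0); unit placement is deterministic given data order.
Applying the corrector never changes the mask; inputs farther than three
coverage radii from every training center are corrected but flagged as
extrapolated.

## Absolute depth

The final stage inverts the forward model pixel-wise:

    Z = sqrt( C V (−px − qy + f) / (E sqrt(p² + q² + 1)) ).

This is an exact algebraic inverse — with true gradients it reproduces the
true depth to rounding error, which serves as the primary oracle of the
package.  Reflectance `C` must be known (in simulation it is; for real
images it is a required input — no auto-calibration is attempted).  Pixels
with zero irradiance (shadow/background) or a non-positive radicand
(back-facing gradients) are masked with reason counts, never inpainted.
Depth scales as `sqrt(C)`: mis-specifying reflectance by a factor `k²`
scales the whole reconstruction by `k`.

## Benchmark experiments and what the synthetic data does not show

`run_experiment` reproduces the simulation protocol: train the corrector on
the radius-5 sphere (center (0,0,15) mm, C=100, 256², 9×9 mm, f=10 mm),
then evaluate on the radius-3 sphere (C=50, 360²) and on the radially
corrugated cosine surface (base depth 12 mm, wavelength 4 mm, amplitude
1 mm, C=120, 360²).  Whether the corrugation is radial or axis-aligned is
not determined by the published description; radial is the default (it
best resembles a polyp phantom) and the axis-aligned variant is a
parameter.  Errors are mean absolute deviations of p, q and Z over the
intersection of all validity masks with the ground-truth limb exclusion
(|p|,|q| ≤ 10); the pixel count is printed with every report so the
averaging region is explicit.

Observed behaviour at these conditions: the raw solver depth deviates from
metric truth by ~12 mm (it is a relative shape), with planar-converted
gradient error ~2.2; the corrected pipeline reduces gradient error ~8-fold
(to ~0.28 on the unseen sphere) and produces absolute depth with ~1.9 mm
mean error on the sphere and ~1.3 mm on the cosine scene — order-of-scale
absolute size from a single image, with the residual error concentrated at
high-slant pixels where the forward model is nearly grazing and depth is
hypersensitive to gradient error.

The synthetic generator emulates noiseless, perfectly Lambertian,
quantization-free imagery with exactly known C and f.  Passing these
benchmarks therefore demonstrates the internal consistency of the solver,
corrector and inversion — not robustness to sensor noise, specular
residue, color texture, unknown reflectance, or calibration error, all of
which real endoscope frames exhibit.  Cast-shadow and background regions
are masked, not reconstructed.

## Known limitations

* The corrector's input is the gradient pair alone; its map from solver
  gradients to true gradients is scene-dependent in principle (it ignores
  pixel position and intensity), which bounds cross-scene generalization.
* Mean depth error is dominated by the high-slant tail of the evaluation
  mask; median errors are several times smaller.
* The cosine scene's Jacobi iteration stalls just above the convergence
  tolerance (non-converged flag set at the sweep cap).
* No smoothing or integration of the gradient field is performed by design;
  depth errors remain local but are not spatially regularized.
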