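# Methods

## Problem setting

Limited-angle CT acquires line integrals over an angular span shorter than
the 180° a parallel-beam scan needs for exact inversion. The missing views
create a null space: filtered backprojection (FBP) then shows streaks and
"landslide"-type boundary degradation, and algebraic methods converge to a
null-space-contaminated solution. The package's central algorithm, AIHT,
restores the missing information through a sparsity prior: the image is
assumed approximately piecewise constant, so its spline-framelet detail
coefficients are sparse, and iterative hard thresholding drives the
reconstruction toward that set while SART sweeps keep it consistent with
the measured sinogram.

## Acquisition model and projector

* **Geometry.** Parallel beam. Beam geometry does not change the character
  of limited-angle artifacts, and parallel beam keeps the adjoint, the FBP
  weighting and analytic chord-length checks simple. Angles are in
  degrees; 0° sends rays along image rows; angles increase
  counter-clockwise. Detector bins are centered on the rotation axis with
  spacing equal to the pixel spacing; the default detector count
  `ceil(image diagonal) + 1` guarantees full object coverage (truncated
  projections are rejected, not modeled).
* **Discretization.** Joseph's method: for each ray the projector marches
  along the dominant axis and linearly interpolates between the two
  neighboring pixels in the perpendicular direction, weighting by the path
  length per step (`spacing/|cos θ|` or `spacing/|sin θ|`). The weights
  are assembled once per (geometry, image shape) into a cached sparse
  matrix, so the backprojector is the exact transpose and the pair
  satisfies ⟨Zh, y⟩ = ⟨h, Zᵀy⟩ to machine precision — a matched adjoint,
  which the SART convergence behavior relies on.
* **Noise.** Additive i.i.d. Gaussian noise of user-chosen σ on the
  sinogram, seeded; Poisson/count statistics are out of scope.
* **FBP baseline.** Ram-Lak ramp filtering in the frequency domain
  (projections zero-padded to the next power of two), pixel-driven linear
  backprojection, scaled by the angular step in radians.

## Framelet transform

The piecewise-linear B-spline tight framelet uses the three length-3
filters `k0 = [1,2,1]/4`, `k1 = √2[1,0,−1]/4`, `k2 = [−1,2,−1]/4`, which
satisfy the unitary condition |k̂0|² + |k̂1|² + |k̂2|² ≡ 1. The 2D
transform is separable (nine 3×3 kernels), single-level, undecimated, with
periodic boundary extension; synthesis is the exact transpose. Under the
unitary condition this gives perfect reconstruction (AᵀA = I) and energy
preservation to machine precision, so thresholding is the only lossy step
in the loop. Subbands are ordered row-filter-major, (0,0) being the low
pass; only the eight detail subbands are ever thresholded.

## SART

One sweep visits the views in fixed ascending angular order and, within
each view, updates all pixels simultaneously:

    h ← h + g · V_a⁻¹ Z_aᵀ B_a (l_a − Z_a h)

with `B_a` the inverse ray sums and `V_a` the per-view pixel column sums
(both obtained by projecting/backprojecting ones; rays that miss the image
and pixels a view cannot see get weight 0). This is the classical SART
scheme — simultaneous within a view, sequential across views — chosen over
a fully simultaneous (SIRT-style) sweep because it converges roughly an
order of magnitude faster per sweep (full-range 64² head-phantom RMSE
0.0014 vs 0.062 after 100 sweeps) while remaining deterministic, since the
view order is fixed. The trade-off: the weighted residual ‖Zh − l‖_B is
strictly non-increasing per sweep only for moderate relaxation (verified
at g = 0.5); at g = 1 occasional small overshoots occur although the
overall trend, and the RMSE to ground truth, still decrease monotonically
in practice. Relaxation g defaults to 1 and must lie in (0, 2];
initialization is the zero image; an optional non-negativity clip after
each sweep projects onto the physical constraint set.

## AIHT loop

Each outer iteration applies: SART sweep → framelet analysis → hard
threshold on detail subbands → synthesis → optional non-negativity clip.
Hard thresholding is the ℓ0 proximal map; the boundary case |y| = β* maps
to 0 for determinism, and the comparison is on magnitudes (a signed
comparison would annihilate all negative coefficients). The algorithm is
parameterized directly by the threshold β* rather than by a Lagrange
multiplier, because that is the quantity the proximal map consumes.

* **Adaptive threshold (the L-curve rule).** Every `lcurve_every`
  iterations (default 10, bounding cost) the candidate grid (default 12
  points, geometric from 1e−4 to 0.2 — spanning negligible to aggressive
  for unit-range images) is scanned: each candidate is applied to the
  current iterate's coefficients, synthesized, reprojected, and the point
  (log₁₀ ‖Zh_t − l‖₂, log₁₀ #surviving detail coefficients) recorded. The
  corner is the interior candidate with maximum three-point Menger
  curvature; ties and degenerate flat curves resolve to the smallest
  threshold. One global threshold is applied to all eight detail subbands
  by default (per-subband values are supported but there is no principled
  per-subband rule to default to).
* **WF baseline.** The identical loop with a fixed threshold (default
  0.05, a plausible a-priori mid-scale choice for unit-range images —
  deliberately *not* tuned per problem, since the point of adaptivity is
  to remove that tuning).
* **Stopping.** Iteration cap (default 200) plus relative image-change
  tolerance (default 1e−6).
* **Degenerate behavior.** With all thresholds 0 and the clip off, the
  transform stages collapse by perfect reconstruction and the loop
  reproduces plain SART to 1e−10 — a structural sanity check the tests
  assert.

## Quality metrics

RMSE is global over all pixels (M = pixel count; no sliding window, one
number per reconstruction). PSNR uses the reference image's sup-norm as
peak, so it is deliberately asymmetric; identical images give +∞. The two
are strictly anti-monotone for a fixed reference.

## Phantoms

Piecewise-constant phantoms (ellipses/rectangles with additive
intensities on a background, center-point rasterization, no
anti-aliasing) realize the sparsity class the regularizer targets, with
values kept in [0, 1] (clipped with a warning otherwise; no Hounsfield
calibration — the reconstruction experiments are unitless). The
contrast-modified Shepp-Logan table is used so the standard 10-ellipse
head phantom also stays in [0, 1]. The packaged default experiment
phantom is an abdomen-like arrangement of five shapes at 128².
Center-point rasterization makes pixel counts exact but means 2×
downsampling agreement with a coarser rasterization holds on average
(mean |Δ| < 0.1), not pixelwise at edges.

## Spectral-CT cohort generator

No clinical spectral-CT effusion dataset is public, so the diagnostic
statistics are exercised on synthetic cohorts. Each subject carries a
monoenergetic CT-value curve on 40–100 keV (10 keV grid), water(iodine)
and water(calcium) concentrations, effective atomic number, and
mixed-energy CT value, drawn independently per parameter from per-group
normals (no covariance structure — a stated simplification; only group
means/directions are being emulated). Default group conditions (50
hepatic S1 vs. 42 carcinomatous D0 subjects):

| parameter | S1 mean (SD) | D0 mean (SD) | direction |
|---|---|---|---|
| mixed-energy CT (HU) | 8 (4) | 15 (4) | S1 lower |
| curve slope λ (HU/keV) | 1.40 (0.90) | −1.18 (1.00) | S1 descending |
| water(iodine) (mg/mL) | 0.90 (0.45) | 2.10 (0.60) | S1 lower |
| water(calcium) (mg/mL) | 1.10 (0.50) | 2.60 (0.80) | S1 lower |
| effective atomic number | 7.90 (0.25) | 7.50 (0.25) | S1 higher |

The slope convention is the radiology one: λ = (CT(E_low) − CT(E_high)) /
(E_high − E_low) with the low-energy value first, so *descending* curves
have *positive* λ. The slope means/SDs are chosen so the descending
probability in S1 is Φ(1.40/0.90) ≈ 0.94 and the ascending probability in
D0 is Φ(1.18/1.00) ≈ 0.88, the curve-type mix characteristic of the two
effusion etiologies. Curves are synthesized as a two-parameter
exponential-like decay `CT(E) = base + A·e^{−(E−40)/40}` with `A` fixed by
the drawn endpoint slope and `base` anchored to the subject's
mixed-energy CT value. Concentrations are clipped at 0 (they are
physically non-negative), which slightly biases group means when a normal
tail crosses zero; the defaults keep that tail small.

Because the generator only matches directions and curve-type structure —
not any specific patient cohort — the ROC numbers it yields (AUC,
Youden-point sensitivity/specificity of the concentrations) characterize
the machinery and the chosen conditions, not clinical performance. ROC
itself is empirical: trapezoidal AUC (= Mann–Whitney statistic, ties half
credit), operating point by maximum Youden J with ties broken toward
higher sensitivity.

## Problem sizes and numerical choices

The packaged comparison runs at 128² with one view per degree, clean
data, 200 iterations — sizes at which the full experiment completes in
well under a minute per algorithm while the limited-angle effects are
fully developed. Unit tests use 32²–64². Zero row/column sums invert to
0, not ∞; the L-curve guards log(0) with floors (1e−300 on the misfit,
count 1 on sparsity); image-change norms are relative to the previous
iterate with a zero-image guard.

## Known limitations

* Parallel-beam only; no fan/cone beam, no detector truncation, no
  Poisson noise.
* Single-level framelet decomposition; no multiscale threshold schedule.
* The L-curve scan costs one reprojection per grid candidate; for large
  grids on large images, increase `lcurve_every`.
* The fixed-threshold WF baseline is a surrogate for wavelet-frame
  methods generally; a multiplicative-regularization comparator is not
  implemented (no defining equations available).
* The spectral module's synthetic cohorts cannot validate clinical
  claims; they validate the statistics' definitions and the pipeline.
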