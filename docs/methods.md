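# Methods

This note documents the models implemented in `ctperf`, the defaults and why
they were chosen, what the synthetic phantom does and does not emulate, and
the numerical decisions that shape the results.

## The perfusion model

Regional perfusion is estimated as postcontrast HU enhancement on the
precontrast end-inspiratory grid:

    E(x) = I_post(T_post(x)) − [a(x) + b(x) · V_post]

where `T_post` is the deformable registration mapping the precontrast
end-inspiratory scan (fixed) to the postcontrast scan (moving), and
`(a, b)` is the per-voxel straight line of parenchymal HU against total lung
volume, fitted by ordinary least squares to the three precontrast
breath-holds after they are brought onto the end-inspiratory grid through the
registration chain end-expiration → midinspiration → end-inspiration. With
three observations and two parameters the fit has one residual degree of
freedom; exactly collinear inputs are interpolated exactly, so the correction
is unbiased wherever the linearity assumption holds and the alignment is
correct. The target volume `V_post` is the segmented postcontrast lung
volume; a target outside the fitted volume range extrapolates the line,
unclamped, and logs the extrapolation fraction. The end-expiratory scan
reaches the end-inspiratory grid through the *composed* displacement field in
a single interpolation; resampling twice through the chain is measurably
worse (the suite checks this), because each trilinear pass low-passes the
image.

Assumptions worth stating: (i) parenchymal HU is affine in total lung volume
over the sampled inflation range — physically, the air fraction of a voxel's
tissue mixture scales with inflation; (ii) contrast enhancement is static
over the acquisition (no bolus dynamics); (iii) vessels violate the
parenchymal model and are excluded by the analysis mask's −250 HU threshold.

## Lung segmentation

The analysis mask is `HU < −250` (strictly) restricted to lung outlines when
provided, otherwise to interior low-HU connected components: exterior air is
identified as low-HU regions touching the volume boundary, and components
below 5% of the largest are treated as specks. Morphological cleanup
(closing + hole fill) exists behind a flag and is off by default so the
threshold rule stays the contract. Lung volume is voxel count × voxel
volume.

## Deformable registration

A cubic B-spline free-form deformation is optimized coarse to fine.
Defaults (chosen for the 64³ × 3.5 mm phantom geometry; the canonical
clinical schedule for ~1 mm thoracic CT is five levels, factors 16/8/4/2/1
with 80/40/20/10/5 mm grids):

| level | image down-sampling | control spacing | iterations |
|------:|--------------------:|----------------:|-----------:|
| 0 | 4× | 112 mm | 300 |
| 1 | 2× | 56 mm | 200 |
| 2 | 1× | 28 mm | 150 |
| 3 | 1× | 14 mm | 100 |

* **Similarity.** Negated normalized cross correlation (NCC) or negated
  mutual information (MI), sampled on the merged fixed/moving lung mask
  dilated by 2 voxels. The pipeline default follows the acquisition design:
  NCC for the pre/post end-inspiratory pair, MI for the precontrast inflation
  chain. MI uses 48 bins (a measurable improvement over 32 on the phantom;
  32 remains a config option) with hard binning of the fixed image and
  linear partial-volume weighting of the moving image inside the optimizer;
  the public `similarity_mi` defaults to hard binning for both so that
  MI(X, X) equals the marginal entropy exactly.
* **Regularisation.** The bending energy is the per-sample mean of the
  summed squared second derivatives of the displacement, computed exactly
  from the B-spline basis (affine displacements cost exactly zero). Spatial
  derivatives are taken per *voxel length* of the fixed image rather than
  per mm: this nondimensionalisation makes the standard weight of 0.05
  transfer across image resolutions and, at 3.5 mm voxels, gives the penalty
  enough authority to reject wiggly deformations that match the images as
  well as the true one. With a per-mm normalisation the same weight was two
  orders of magnitude too weak to do so.
* **Optimizer.** L-BFGS-B with fully analytic gradients (closed form for
  NCC; the partial-volume histogram derivative for MI; exact basis
  derivatives for bending). Two safeguards matter in practice. First, the
  optimizer samples the moving image with clamped (edge-value)
  extrapolation: a constant out-of-volume fill is discontinuous exactly at
  the grid edge and both breaks line searches and offers a spurious uniform
  region to map into. The public `warp` keeps the declared −1000 HU fill.
  Second, each level's coefficients are box-bounded around their
  initialisation — 0.75 × grid spacing at the coarsest level (capture
  range), 0.4 × spacing at refinement levels — which stabilises line
  searches on smooth synthetic images and keeps per-level updates inside the
  classic B-spline diffeomorphism bound. The finest pyramid level is
  smoothed with a 1-voxel Gaussian, which suppresses noise chasing and keeps
  the trilinear intensity model consistent with its central-difference
  gradient.
* **Determinism.** No stochastic sampling anywhere: a given (fixed, moving,
  mask, config) is bit-reproducible.
* **Diagnostics.** The Jacobian determinant of `I + ∇d` is computed with
  central differences (one-sided at the boundary); voxels with determinant
  ≤ 0 inside the mask are counted as singularities (folding). Landmark TRE
  is evaluated on the fixed grid: each fixed landmark is mapped by the
  transform and compared with its reference moving-frame position; the
  report counts TREs exceeding the largest per-axis voxel dimension.

## Perfusion analysis

* **Heterogeneity**: coefficient of variation (SD/mean) of masked
  enhancement. Sample SD (n−1) is the default convention everywhere; the
  population convention is available via `ddof=0`. CoV is invariant under
  positive scaling but not under additive shifts — appropriate because HU
  enhancement has a physical zero.
* **Gravitational gradient**: the masked lung's extent along the
  ventral-dorsal axis (between extreme masked voxel centres) is split into
  five equal-thickness coronal slabs; voxels are assigned by centre. Slab
  mean enhancements are regressed on the relative slab-centre distance
  (k + 0.5)/5, and the slope is tested against zero with the regression
  t-test on n − 2 = 3 degrees of freedom (read as the standard test for a
  regression coefficient).
* **Group comparison**: classical pooled-variance two-sample two-tailed
  t-test by default; Welch available. Degenerate inputs are defined:
  identical constant groups give t = 0, p = 1; perfectly separated constant
  groups give the p → 0 limit, flagged.

Note that the slab estimator does not recover a raw "HU per relative
distance" parameter even with perfect data: slab means are
cross-section-weighted averages, so the estimator's expectation depends on
the lung geometry. `phantom.expected_slab_gradient` computes that
expectation for the phantom by fine quadrature over the continuous
parenchyma geometry, independent of the imaging pipeline.

## The phantom

The generator emulates a prone canine-like thorax: two ellipsoidal lung
lobes (defaults normalised to the cohort's normal-group mean volumes —
1356/1865/2067 cm³ precontrast, 2072 cm³ postcontrast) inside a soft-tissue
body, a six-segment vessel tree (+50 HU blood, +300 HU after contrast), and
parenchymal HU built from a tissue/air mixture whose tissue fraction is
*affine in total lung volume by construction* — the correction's modelling
assumption holds exactly, so deviations measured downstream are attributable
to registration, interpolation, and noise. Key properties:

* **Deformations** are anisotropic scalings about a point near the lung apex
  (diaphragm-dominated, `sz = det^0.5`) plus low-frequency (≥160 mm)
  sinusoidal perturbations whose modes are divergence-free, so lung volumes
  stay on target; amplitudes are bounded well below the invertibility limit,
  and the exact forward/inverse maps are evaluable at arbitrary points
  (fixed-point inversion to 1e-9 mm). Landmarks are sampled in material
  coordinates and mapped exactly.
* **Band-limited rendering.** All material edges (lung surface, body
  surface, vessels) are compactly-supported quintic smoothstep blends in
  material coordinates. Hard edges point-sampled on 3.5 mm grids alias
  differently on every scan grid and poison intensity-based registration;
  blending fixes that while preserving exact per-voxel linearity in volume
  (blend weights depend only on the material point). The lung edge blend is
  shifted once so the −250 HU segmentation crossing sits on the geometric
  surface at the mid inflation level, keeping segmented volumes within ~1.5%
  of targets at every level.
* **Texture.** Parenchymal tissue fraction carries smooth large-scale
  variation (±10%, 120–180 mm) plus fine sub-lobar texture (±12%, 36–62 mm,
  ≈ ±17 HU at end-inspiration) standing in for the vessel/septal structure
  registration locks onto in real lungs. Scan noise is Gaussian, 5 HU SD by
  default, independent per scan.
* **Enhancement** is a ventral-to-dorsal linear gradient about a 35 HU
  baseline (slope −24 HU per unit relative distance, so the dependent
  ventral side of the prone animal is better perfused), optionally
  attenuated inside spherical perfusion defects for diseased-lung variants.
* **Truth masks.** The "pure parenchyma" mask requires the whole trilinear
  interpolation stencil to be clear of every blend: only there does the
  truth enhancement equal the expectation of a resampled scan, so
  truth-recovery errors are meaningful. Analysis-stage oracles are evaluated
  on this mask; with 3.5 mm voxels the thresholded analysis mask necessarily
  keeps perivascular partial-volume voxels whose blended vessel enhancement
  is genuine signal in the map but not part of the parenchymal estimand.

What the phantom does **not** emulate — and what passing tests therefore do
not show about real data: beam-hardening streaks from dense contrast (a major
source of negative enhancement and registration error in practice), cardiac
motion, airway trees, bolus time–density dynamics, scanner-specific noise
texture and reconstruction kernels, and sliding motion at the pleura. Its
deformations are smooth and band-limited, so registration accuracy on the
phantom is an upper bound relative to real respiratory mechanics.

## Validation summary (what the suite computes)

The test suite reproduces the bundled cohort tables exactly (volume
differences, group means, pooled t-test), and on phantoms verifies: mean
landmark TRE below the voxel dimension with zero negative-Jacobian voxels
for the perfusion registration across seeds and deformation amplitudes up to
8 mm; machine-precision recovery of the voxel-wise HU model from noiseless
collinear inputs; end-to-end enhancement error within a few HU (and the
correction strictly beating no correction whenever the end-inspiratory
volumes differ by ≥5%); higher CoV for defect phantoms; and slab-gradient
recovery within a few percent of its analytic expectation with R² > 0.99.
Problem sizes: 64³ voxels at 3.5 mm, 50–200 landmarks per evaluation, four
registration runs per accuracy study.

## Known limitations

* Registration defaults are tuned for the phantom's geometry and noise; real
  thoracic CT needs the finer clinical schedule and may need masking
  adjustments near the mediastinum.
* The HU correction replaces HU at *all* analysis-mask voxels, including
  those where the three-scan correspondence is imperfect; alignment-gap
  flagging is limited to the model mask itself.
* MI's histogram binning makes it slightly less precise than NCC on
  same-modality pairs here; the pipeline keeps MI for the inflation chain to
  match the published acquisition design it implements.
* The cohort tables are summary statistics; no raw canine images ship with
  the package, so cross-checks against the original scans are out of reach.
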