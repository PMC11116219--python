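# Methods

`cranioshape` builds a statistical shape model (SSM) directly on binary voxel
occupancy grids of complete skulls and uses it to complete defective skulls
and derive cranial implants. This note documents the model, the numerical
choices, and what the synthetic test bed does and does not show.

## The model

Let `X = {x_1 … x_C}` be a pool of complete binary skull masks and `x_j` a
designated reference member. Each member is registered to `x_j` with a
similarity transform (isotropic scale, rotation, translation) and resampled
onto the reference grid; the non-zero voxels act as dense landmarks, so this
registration/warping step takes the place of the point-correspondence search
a mesh-based point-distribution model would need. With the warped, flattened
shapes stacked as the rows of `X'` (C × N, N = number of reference voxels):

* **Mean shape** `S̄ = (1/C) Σ_i x'_i`, a real-valued field in [0, 1];
  binarized at 0.5 it serves as a population template `S̄(n)`.
* **Variation modes** come from PCA of the rows. With `scores` the C × d₀
  matrix of mean-centered PCA scores, the variation matrix is
  `Φ = scoresᵀ · pinv(X')ᵀ` (Moore–Penrose pseudo-inverse), so that for any
  shape `y'` on the reference grid the projection `λ = Φ (y' − S̄)` recovers
  PCA scores exactly for pool members.
* **Reconstruction** `S = S̄ + Σ_i λ_i Φ_i = S̄ + λ·Φ`. The sum-of-modes and
  matrix (inverse-PCA) forms are the same linear map and agree to float
  round-off; both are implemented and cross-checked.

Because the projection goes through `pinv(X')` rather than the orthonormal
component matrix, self-reconstruction of a pool member is exact only up to a
rank-one correction proportional to `⟨x'_i − S̄, S̄⟩`; in practice member
self-reconstruction DSC exceeds 0.98 at full rank.

**Centering.** Scores are computed on mean-centered rows (the standard PCA
contract) and `Φ` is applied to mean-centered inputs in projection; this is
what makes the projection/reconstruction pair an exact PCA/inverse-PCA
composition.

**Weight rescaling.** Projection weights can be min–max rescaled to [0, 1]
(`(λ_i − min λ)/(max λ − min λ)`; a constant vector maps to zeros with a
warning). The default feeds *raw* weights to reconstruction, which preserves
the exact inverse identity; rescaled weights are available behind a flag.

## Completion

A defective shape `y` is completed in the reference space and returned to
its own grid:

1. register `y` to the reference (or template), giving `Tr`; warp: `y' = Tr(y)`;
2. obtain a complete estimate `S` — either a fixed template (`x_j` or a
   binarized mean `S̄(n)`) or the SSM reconstruction from `λ = Φ(y' − S̄)`,
   binarized at 0.5 (configurable);
3. missing part `y_m = S − y'`, clamped at zero (i.e. `S ∧ ¬y'` on the binary
   grids — the subtraction can never go negative);
4. completed shape `y_c = Tr⁻¹(y_m + y')`; the subject's own voxels are
   kept authoritative in the original space (the warped-back estimate is
   united with the input).

The SSM route always reconstructs the *whole* skull and derives the implant
by subtraction; the implant is never predicted directly, which is what makes
the method independent of the defect pattern.

### Pose refinement (alternating pose and shape)

One-shot registration of a defective mask against a complete reference is
biased: a symmetric similarity metric treats the hole as mismatch and drags
the template into it. Measured on the synthetic benchmark, this costs
roughly 0.05 DSC on the completed skull and up to 0.3 DSC on the extracted
implant for large defects. The completion loop therefore alternates pose and
shape, as active-shape-model fitting does:

1. initial similarity registration and completion as above;
2. re-register the defective mask against the current complete estimate (the
   subject-adapted SSM reconstruction, or the template), with the currently
   estimated missing region — dilated by 3 voxels — **excluded from the
   metric**, warm-started from the current pose;
3. recompute the completion; repeat (3 iterations by default).

Step 2 is defect-robust for two reasons: the fixed image is the subject's own
reconstruction (so there is little genuine mismatch left to bias the fit),
and the one region where the reconstruction is not trustworthy — the fill —
is masked out. Passing an explicit transform disables registration and
refinement, which also provides the exact-oracle path used in tests.

Refinement is also skipped when the initial completion finds less than 3 %
of the input volume missing: the input is then effectively complete, there
is no hole-induced bias to correct, and re-registering (with its rotation
prior, below) would only perturb an already-correct pose. The branch is
safe because the missing fraction is sharply bimodal — essentially zero for
complete inputs versus the defect size otherwise.

The refinement registration estimates a full **affine** pose (12 parameters,
warm-started from the current similarity transform) and projects it to the
closest similarity map by polar decomposition — rotation from the orthogonal
factor, scale as the geometric mean of the singular values. The reason is
subset-coupling: a similarity transform fitted to partially observed data
trades its single isotropic scale off against *which part* of the shape is
observed whenever the residual shape mismatch is anisotropic, so the
estimated pose depends on where the defect is. The affine's extra degrees of
freedom absorb the anisotropic mismatch consistently, and the similarity
read off from it is nearly independent of the missing region (scale spread
across defect patterns drops from ~1 % to ~0.15 % on benchmark phantoms).
The affine estimation also regularizes its antisymmetric part (weight 0.01)
— for nearly rotationally symmetric shapes the rotation is under-determined
along a cost-flat valley, and without a prior each run drifts to a different
point of it. Only the refinement uses these devices; the plain
similarity-registration path is unregularized.

The final completion is always performed with a plain similarity transform;
the affine is an estimation device only.

### Missing-part denoising

The clamped subtraction leaves, besides the genuine defect fill, a
sprinkling of tiny disconnected components wherever the complete estimate
protrudes a single voxel past the warped defective shell — misregistration
dust, not anatomy (measured: hundreds of specks of ≤ tens of voxels next to
a fill three orders of magnitude larger). Connected components of the
missing part smaller than 2 % of the largest one are discarded before the
completed shape is assembled (26-connectivity; configurable, 0 disables).
An exact-pose subtraction produces no dust and passes through unchanged.

## Registration

Masks are registered with a 7-parameter similarity transform
`T(p) = s·R·(p − c) + c + t` about the fixed mask's foreground centroid `c`,
in physical coordinates. The estimation is classical and deterministic:

* **Initialization**: translation = centroid offset; scale = cube root of the
  foreground-volume ratio; identity rotation (or a warm start).
* **Metric**: mean squared difference between Gaussian-smoothed copies of the
  masks (default), evaluated over the fixed grid; a one-sided
  `overlap_fraction` metric (mean fixed-mask value under the warped moving
  foreground) is available for registering defective shapes directly.
  Fixed-grid voxels can be excluded from either metric.
* **Optimizer**: Powell (derivative-free), coarse-to-fine — by default one
  level at shrink factor 2 with σ = 2 mm smoothing (12 Powell iterations,
  parameter tolerance 3·10⁻⁴) and one at full resolution with σ = 1 mm
  (4 iterations). No stochastic sampling anywhere; identical inputs give
  identical transforms.
* **Orientation prior**: rotations beyond 60° incur a soft quadratic
  penalty. Segmentation masks arrive in a standardized patient orientation,
  so such poses are spurious — for nearly symmetric shapes the metric
  otherwise has flipped (~180°) near-optima. Configurable; disabled by
  setting the bound to None.

Gradient-based optimizers (tested during development) are unstable on
thin-shell masks — the SSD landscape in the scale direction is nearly flat
once shells disengage — whereas Powell with the volume-ratio initialization
recovers synthetic similarity transforms to ~0.2 % scale, <1° rotation and
<0.1 voxel translation for poses up to 15° rotation, ±10 % scale and
10-voxel shifts. Binary volumes are warped by linear interpolation of the
occupancy field followed by thresholding at 0.5, which preserves exact voxel
values under lattice-preserving maps and yields smoother surfaces than
nearest-neighbour sampling.

## Implant extraction

The raw subtraction result contains the implant plus residue (template /
subject disagreement, interior structure, thin misregistration shells). The
automatic clean-up is: despeckling → morphological opening (a cubic
structuring element of side r+1 for radius r, which erases structures of
local thickness ≤ r while leaving anything at least r+1 voxels thick —
solids, shell caps — intact; r = 1 by default) → connected components
(26-connectivity by default) → keep the `keep` largest components above a volume floor, ties
broken by smallest linear voxel index for determinism.

The despeckling step is a **hysteresis median**: an input voxel survives if
it lies within one voxel of the median-filtered core. A plain median filter
is strongly erosive on thin shell caps — every re-application shaves the
implant rim further, so a plain-median pipeline cannot be idempotent and
degrades the implant on repeated use. The hysteresis variant removes
isolated speckles (which have no stable core nearby) while sparing rim
voxels attached to solid material. The full pipeline is iterated to a fixed
point (one or two passes in practice), so extraction is idempotent and its
output is always a subset of the smoothed input. Kernel sizes are
case-dependent in the real world; all stages are exposed in
`ExtractionConfig`, and a warning flags ambiguous cases where a discarded
component is comparable in size to a kept one (manual editing territory).

## Metrics

* **DSC** `2|A∩B|/(|A|+|B|)`; two empty masks score 1.
* **Border DSC**: surface Dice at tolerance τ. Surfaces are foreground
  voxels with a background 6-neighbour (array borders count as background);
  a surface voxel matches if it lies within τ mm of the other surface;
  score = (matched_A + matched_B)/(|∂A| + |∂B|). Default τ = one voxel's
  physical size (the largest spacing component), configurable — there is no
  single canonical tolerance for this metric family.
* **HD95**: the 95th percentile of the *pooled* directed surface-distance
  sets A→B and B→A (not the maximum of per-direction percentiles), in mm.
  Distances are exact Euclidean distances between voxel centers
  (spacing-aware distance transform). An empty mask gives infinity with a
  warning.

All three are verified against brute-force all-pairs surface-distance
oracles on random 32³ masks.

## Synthetic phantoms

The generator emulates binary skull masks with hollow ellipsoidal shells:
per-axis radii, shell thickness, orientation, position, and an optional
solid "facial lobe" appendage to mimic the cranium-versus-face imbalance of
real masks. Population variation samples an overall size factor (±8 %) with
per-axis jitter (±2 %), shell thickness (±8 %), rotation (±~10°) and
translation (±3 voxels) around a base spec; all randomness flows from
explicit seeds. Overall size is recoverable by registration; the per-axis
jitter and the thickness spread are genuine non-similarity shape variation
and bound how well two members can ever overlap (two shells of thickness
t₁ < t₂ reach at best Dice 2t₁/(t₁+t₂)), so they are kept moderate enough
that ideally registered members overlap above ~0.90. Defects are spheres, cubes,
multiple disjoint lobes, or border-crossing regions centred on the shell
surface, with the region size solved by bisection so the carved volume
matches a requested fraction of the shape; the ground-truth implant is the
exact set difference.

The default study conditions — used by the test suite and the acceptance
script — are a 20-member training cohort and 10 unseen defective subjects on
64³ unit-spacing grids with defects of 10–30 % of the shell, including
two-defect and border-crossing cases. These sizes exercise every stage at
realistic shape complexity for a smooth cranial vault while keeping a full
run in minutes on one CPU; unit tests use 48³ cohorts of 8.

What passing these tests shows: the linear-algebraic identities, the
registration accuracy under true similarity perturbations, the completion
algebra, defect-insensitivity and extraction robustness all hold end to end.
What it does not show: performance on real skulls. Phantoms are smooth,
convex-ish and topologically identical; real skulls have facial structures
that are much harder to register, real defects have irregular borders, and
real masks carry segmentation noise. On real data the registration residual
(not the model) is the dominant error source, and manual post-processing of
extracted implants may still be required — the QC warning exists for exactly
that case.

## Numerical choices and degenerate inputs

* Arrays are indexed `(x, y, z)`; flattening is row-major over that order,
  fixed everywhere so `Φ` columns stay aligned with voxels. Physical
  position = `origin + index · spacing`; only axis-aligned volumes are
  accepted (non-identity direction matrices are rejected, not resampled).
* The warped-shape matrix is stored float32 (N can reach 512³); all model
  algebra runs in float64.
* `pinv` uses SVD with relative cutoff 1e-10 — safe because rank ≤ C ≪ N.
* The reference member is a free choice; `choose_reference` picks the
  member closest to the population median in overall size (cavity-filled
  volume) and relative wall thickness, because a representative reference
  keeps every other member's residual mismatch small and symmetric. Any
  explicit index works too.
* Reconstruction and warping thresholds default to 0.5 and are configurable.
* All-identical pools produce zero variations with a warning; empty masks
  raise `DegenerateInputError`; mismatched grids raise `GridMismatchError`;
  constant λ rescales to zeros with a warning.

## Known limitations

* Similarity transforms cannot express inter-subject shape differences
  beyond pose and size; the SSM absorbs some of the remainder, but border
  continuity of implants ultimately needs deformable registration or surface
  extrapolation, which are out of scope.
* The linear model on binary grids produces real-valued fields whose
  binarization can thin or thicken structures relative to any one subject.
* Extraction assumes the implant is among the largest connected components
  of the cleaned subtraction; heavily fragmented residue can defeat it (the
  ambiguity warning flags this).
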