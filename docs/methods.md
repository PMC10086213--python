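# Methods

This note documents the models implemented in `sarcoreg`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical choices that matter.

## Coordinate conventions

All geometry lives in world coordinates: RAS axes, millimetres, matching
NIfTI affine semantics. Voxel *centers* carry coordinates — the world
position of index `i` is `origin + direction · (spacing ∘ i)` — so index
(0,0,0) sits at the origin, which makes resampling unambiguous. Transforms
always act on world mm, never on voxel indices, so volumes with different
spacings and 2D sections with arbitrary pixel sizes interoperate. 2D
sections use `(x, y) = (col·pixel_size, row·pixel_size)`.

Rigid transforms are stored as a 4×4 homogeneous matrix in JSON
(`{"matrix": ..., "fixed_space": ..., "moving_space": ...}`) — the minimal
self-describing form. Rotations must be proper (orthonormal within 1e-6,
det = +1); improper matrices are rejected on read.

## Rigid registration

The original workflow aligns the first ex vivo scan to the in vivo scan
manually in a GUI. This package substitutes a deterministic, testable
equivalent with the same transform class (rotation + translation, no
scaling): the closed-form least-squares fit on user-supplied paired
landmarks. Centered point clouds give the cross-covariance `H = SᶜᵀFᶜ`;
with `H = UΣVᵀ`, the proper rotation is `R = V diag(1,1,d) Uᵀ` where
`d = sign(det(VUᵀ))` — if the unconstrained optimum is a reflection, the
smallest singular vector's sign is flipped. Fewer than 3 pairs, or
centered configurations of rank < 2 (collinear points), leave the rotation
underdetermined and are rejected. Intensity-based (mutual-information)
refinement is deliberately out of scope.

With isotropic per-axis landmark noise σ the RMS residual settles near
σ√3 (3D norms, minus the 6 fitted degrees of freedom) and the rotation
error stays well below 2° at 40 landmarks and σ = 0.5 mm.

## Cutting-angle derivation

Let `M` be the composed rotation (in vivo angulation correction, if any,
times the rigid registration rotation). The back-rotation is `M⁻¹ = Mᵀ`,
and the sectioning normal is `n = Mᵀ e_z`. The angle plate realizes this
normal by two planar settings:

* **elevation** θ = ∠(n, e_z) ∈ [0°, 180°): tilt magnitude;
* **azimuth** φ = atan2(n_y, n_x) ∈ [−180°, 180°): tilt direction,
  measured counter-clockwise from +x in the horizontal plane (no
  convention is inherited from the hardware, so this one is fixed here);
* **in-plane** ψ: the residual rotation about `n`, reported because the
  hardware takes three input angles, although planar trimming of the block
  needs only the first two.

The tilt itself is the Rodrigues rotation about the horizontal axis
`(−sin φ, cos φ, 0)` by θ; the full reconstruction is
`spin(n, ψ) · tilt(θ, φ) = Mᵀ`. The central correctness property — tested
over hundreds of random orientations — is that the reconstructed plate
rotation maps `e_z` onto `n` to < 1e-9 rad (measured as the cross-product
norm, since `arccos` of a dot product cannot resolve angles below ~1e-8).
At the θ → 0 gimbal degeneracy the azimuth is reported as 0 and ψ is the
z-rotation extracted from the matrix, removing the ambiguity
deterministically.

Slice planning mirrors the 4 mm measuring-grid localizer: slice centers at
`spacing/2 + k·spacing` from the block face, `floor(extent/spacing)`
slices. Whether the physical grid lines mark slice centers or boundaries
is not specified by the hardware description; centers were chosen, which
makes histology section *k* correspond to MRI slice *k* exactly when the
second ex vivo scan is planned on the same grid (enforced to 1e-6 mm).

## Thin-plate-spline registration

The nonrigid section↔slice step is landmark-driven; the elastic model is
fixed to the 2D thin-plate spline with kernel `U(r) = r² log r` — the
canonical bending-energy-minimizing interpolant, consistent with a
protocol that evaluates accuracy on held-out landmarks. The map is
`f(x) = c + Bx + Σᵢ wᵢ U(‖x − sᵢ‖)` with side conditions
`Σwᵢ = 0, Σwᵢ sᵢ = 0`, solved from the standard bordered system; a ridge
term λ ≥ 0 on the kernel block trades control-point fidelity for
smoothness. λ = 0 (exact interpolation) is the default because the TRE
protocol assumes the registration honors its control landmarks; λ is
exposed for noisy landmark sets. Affine reproduction (zero kernel weights
for affinely related sets) falls out of the side conditions and is tested
to 1e-9.

Image warping uses inverse-mapped resampling: the reverse-direction TPS is
fitted on the swapped control pairs and each target pixel pulls from the
source with bilinear interpolation (`grid-constant` boundary: exact at the
border, 0 outside the field). A true TPS inverse has no closed form; the
swapped fit is deterministic and accurate at the smoothness scale of
section deformations. If the inverse map folds (negative Jacobian
determinant against the dominant orientation) at more than 1% of target
pixels, a warning is recorded in the output's provenance metadata — not
fatal, since fold-overs at cut edges are a real artifact of sections.

## TRE protocol

Per section/slice pair: split the paired landmarks into disjoint
registration and evaluation sets (default fraction 0.5 — symmetric and
information-balanced; the registration set receives the extra point on odd
counts), fit the TPS on the registration set, warp the held-out source
landmarks, record Euclidean distances to their targets, and repeat for 100
independent random splits. Distances are pooled across iterations before
computing the median and IQR (quantiles by linear interpolation, type 7);
per-iteration medians are retained. Disjointness is asserted every
iteration. A failed fit (e.g. a collinear registration subset) aborts that
iteration; more than 10% failures abort the protocol.

Group comparisons mirror the right-skewed character of TRE data:
Kruskal–Wallis across groups, Wilcoxon rank-sum for pairs with Bonferroni
correction (raw p × number of comparisons, capped at 1), significance at
0.05. TRE per tumor volume is reported as mm/mL rounded to 3 decimals.

Two statistical facts about this protocol matter for interpretation:

* A λ = 0 TPS fitted on a *random subset* of landmarks does not reproduce
  a generic TPS deformation at the held-out landmarks (the subset
  interpolant differs from the full-set interpolant); only affine
  deformations are recoverable from every non-collinear subset. The
  phantom therefore offers an affine deformation mode for within-model
  parameter recovery (pooled median < 1e-6 mm at zero noise), while the
  generic smooth-TPS mode measures the protocol's behaviour under
  out-of-span deformation.
* With annotation noise σ per axis, exact interpolation transfers the
  registration-set noise to held-out locations with a
  configuration-dependent variance factor (≈1.5 on average at 20
  controls, larger outside the control hull). The pooled median therefore
  sits a few percent above the idealized Rayleigh closed form
  σ·√(2 ln 4) ≈ 1.665 σ, and a single 40-landmark section scatters ±13%
  around it. Accuracy claims in this package pool 24 independent section
  phantoms (the study being emulated pooled nine section pairs), where the
  pooled median lands within ~5% of the closed form.

## Habitat clustering

Features are the 8 quantitative channels at every tumor-ROI voxel, in
fixed order (ADC, D*, f, fD*, Ktrans, kep, ve, vp); rows with non-finite
values are dropped and counted. "Equal weighting" of channels with wildly
different units is implemented as per-channel z-scoring (sample SD,
parameters retained so centroids can be mapped back to native units);
a zero-variance channel is an error naming the channel. The published
workflow lists v_p among the DCE parameters but reports iAUC in its
results table; the channel set keeps `vp` and accepts `iAUC` as an alias
on read, and the phantom defaults fill that slot with the iAUC values.

Clustering is Lloyd's k-means with k-means++ seeding, k = 4 by default
(matching the four predominant histological patterns; configurable, no
automatic selection), best inertia of 10 restarts, all randomness through
one seed. Spatial coordinates are never features; voxel indices only map
labels back onto the anatomy grid, renumbered 1..k by descending cluster
size for determinism. Per-region statistics are mean ± sample SD per
channel in native units (single-voxel regions get SD 0 and a flag);
comparisons are one-way ANOVA plus pairwise t-tests — Welch by default,
pooled-variance optionally for textbook cross-checks — with
Holm–Bonferroni step-down adjustment and star codes at
0.05/0.01/0.001/0.0001.

A caveat for interpreting centroid recovery on phantoms: k-means centroids
are means of *assigned* voxels. When habitats overlap (the realistic
regime for the published per-region parameters, where partition agreement
with ground truth is ARI ≈ 0.8), a few percent of voxels cross cluster
boundaries and the centroids are biased estimators of the component means
— a bias that does not shrink with voxel count and can reach ~10 standard
errors at ~500 voxels/habitat. Recovery of the generating means to
sampling precision holds for region statistics computed on the *true*
habitat labels, not for k-means centroids.

## Phantom generator

Every generator is a pure function of its seed (byte-identical reruns) and
records enough ground truth to score each downstream stage.

* **In vivo phantom**: a lobulated ellipsoid (default radii 22×16×18 mm in
  a 72×72×64 mm field at 1.5×1.5×2 mm spacing) with smoothed-noise
  internal texture. The ROI iso-level is chosen (order statistic of the
  level field) so the enclosed volume equals the requested ellipsoid
  volume exactly. 30–40 landmarks (default 36, matching the annotation
  protocol being emulated) are placed on interior texture iso-contours.
* **Ex vivo phantom**: the in vivo volume mapped by
  `p → R(s(p − c)) + c + t` with `c` the intensity centroid and
  `s ∈ [0.8, 1]` an optional concentric shrink factor modelling formalin
  shrinkage; landmarks transformed consistently; the transform is the
  recorded truth.
* **Section phantom**: a smooth random TPS deformation (3×3 control grid,
  i.i.d. N(0, amplitude²) displacements, default amplitude 3 mm — the
  scale of the cutting-edge deformations seen on real sections) or a
  random affine of comparable magnitude (within-model mode, see above).
  Paired landmarks are (deformed position + noise, original position);
  annotation noise is isotropic Gaussian per axis on the histology side by
  default (configurable to both sides), at 36–40 uniformly spread
  positions in the central 70% of the slice. Uniform placement is
  deliberate: landmarks clustered along contours produce near-duplicate
  controls that make λ = 0 interpolation ill-conditioned.
* **Map stack**: the ROI is partitioned into contiguous Voronoi habitats
  seeded by farthest-point sampling (well-spread, roughly balanced blobs
  mimicking coherent habitat fields); each voxel's 8 values are drawn
  independently from its habitat's N(mean, sd), defaults being the
  published per-region mean ± SD table. Negative draws are clipped at 0
  and counted — so the generator's true per-cell law is the clipped
  normal, whose closed-form moments are the correct oracle for recovery
  tests (for heavily clipped cells such as region D v_e the raw mean is
  ~2 standard errors away from the clipped law's mean at 500 voxels).
  Channel noise is independent across channels; no covariance is modelled
  because only per-region mean ± SD are reported.

What the phantoms do **not** emulate: MR physics (bias fields, partial
volume, distortion), stain appearance, real annotation behaviour
(landmark placement correlated with anatomy), inter-channel correlations,
and non-rigid fixation artifacts beyond a smooth in-plane deformation.
Passing recovery tests therefore demonstrates correctness of the
algorithms under their stated models, not performance on clinical data.

## Problem sizes and tolerances

Defaults keep the full test suite and the acceptance script in the
seconds-to-minutes range: 48×48×32 in vivo grids, 100-iteration TRE runs,
24 pooled section phantoms for noise-floor estimates, ~2000-voxel ROIs
(~500 voxels/habitat) for clustering recovery. Closed-form constructions
are verified to machine precision (1e-9 … 1e-15); stochastic recoveries to
the bands sampling theory supports (3 SE per cell, 10% on pooled medians).
Angular residuals are measured via cross-product norms rather than
`arccos`, which saturates near 1e-8 rad in double precision.
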