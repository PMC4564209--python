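# Methods

`coralign` implements two intensity-based similarity metrics for 3-D brain
MRI registration — the correlation ratio (CR) driving a multistart
multiresolution affine search, and the local windowed cross-correlation (CC)
driving a simplified symmetric deformable refinement — together with a
seeded phantom generator and the evaluation metrics (MAD, Jaccard) used to
validate them.

## Correlation ratio

Given a reference image `I` and a transformed moving image `J_T = J ∘ T`,
the CR over the overlap region Ω (reference voxels whose mapped coordinates
land inside the moving image's extent) is

    η(J_T | I) = 1 − (1 / (N σ²)) Σ_i N_i σ_i²

with `σ², m` the variance and mean of `J_T` over Ω, and `σ_i², m_i` over the
isointensity set Ω_i — the overlap voxels whose reference intensity falls in
histogram bin `i`.  η lies in [0, 1]: 1 means `J_T` is a deterministic
function of `I`'s bin, 0 means no functional dependence.

The production path mirrors a bin-partitioned reduction: the reference is
binned once per resolution stage (uniform edges over the in-mask min–max;
the maximum intensity goes to the last bin), the voxels are stably sorted by
bin so each bin occupies one contiguous slice of an index array, and the
per-bin partial statistics (N_i, Σ J_T, Σ J_T²) are accumulated by walking
bin slices in any grouping; the result is provably independent of that
partitioning, which the tests assert bit-for-bit for 1/4/13 partitions.  A
direct-grouping brute-force oracle (`correlation_ratio_direct`) provides the
independent second route; the two agree to 1e-10 on random sweeps.

Numerical conventions:

- Bins with `N_i ≤ 1` have zero conditional variance and contribute
  nothing; empty bins are skipped.
- `σ² = 0` (constant `J_T` over Ω) and empty overlap raise; the affine cost
  maps them to a worst-cost sentinel (2.0, above any true cost 1 − η) so the
  search continues.
- η is clipped to [0, 1] against float round-off at the analytic endpoints.
- The stable sort makes results bit-reproducible and order-independent.

## Affine search

FLIRT-style: both images are resampled to 1 mm isotropic (trilinear, edge
clamp), then 2×2×2 block-averaged into an 8/4/2/1 mm pyramid (ceiling
halving; edge blocks truncated; block averaging conserves the global mean
exactly when dimensions divide evenly).  Each stage bins its reference level
with 256/n bins at n mm (32, 64, 128, 256) and builds the sorted index
exactly once; every candidate transform at the stage reuses it (asserted by
an instrumentation counter).

At 8 mm a multistart grid — rotations ±45° in 15° steps per axis,
translations ±16 mm in 8 mm steps, rigid only — seeds the search; the best 3
candidates are locally optimized and refined through the finer stages, with
scales and shears released from 4 mm on according to the configured dof
(6/9/12, default 12).  The local optimizer is a coordinate-wise line search
with step halving: translation steps start at the stage spacing, rotation
steps at 0.01·stage radians, scale/shear at 0.02, halved until floors of
0.05 mm / 5e-4 rad / 1e-3 are reached.  Accepted moves strictly decrease the
cost, so per-stage accepted-cost traces are non-increasing by construction.

Two robustness choices matter on small test volumes, where the 8 mm level
may hold only a few voxels per bin: with many singleton bins η ≈ 1 for *any*
pose, so (a) multistart ties are broken by preferring the smallest motion
(translation norm plus a weighted rotation norm), keeping self-registration
at the identity and the search deterministic, and (b) candidate poses
retaining less than a configurable fraction of the reference in the overlap
(default 0.3) score the worst-cost sentinel, since CR computed over a small
overlap with many bins is spuriously high.  Real brain volumes (≥128 voxels
per axis) have thousands of voxels per bin at 8 mm and are insensitive to
both choices.

Related is the zoom pathology of unnormalized overlap-restricted metrics:
with free scales, shrinking the sampled field of view toward the
homogeneous image interior can raise η above its aligned-pose value (which
is itself below 1 by the bin-quantization residual).  Scales and shears are
therefore bounded to anatomically plausible ranges during search (defaults
0.75–1.35 and ±0.25, configurable); on very small volumes a coarse stage
may still ride a scale bound before the finer stages, where the structure
dominates, pull the estimate back.

Transforms are 4×4 world-coordinate (mm) maps — voxel anisotropy never
leaks into parameters — decomposed as translation · rotation (extrinsic
x-y-z Euler) · shear · scale about the reference-volume center; the
parameter↔matrix round-trip is exact to 1e-9 for positive scales.

## Local cross-correlation

For co-registered `I_T`, `J_T`, the local CC at x is the squared correlation
over the cubic (2r+1)³ window centered at x, `CC = C²/(A·B)`, with A, B, C
assembled from five neighborhood sums (Σ I, Σ J, Σ I², Σ J², Σ I·J).  The
sums are computed by separable running box sums (a prefix sum per axis
turns each window into an entering-minus-departing slab difference), never
by per-voxel loops; `cc_map_direct` recomputes every voxel from scratch as
the oracle, and the two agree to 1e-8 absolute.

- Boundary: edge replication, so n = (2r+1)³ is constant everywhere and the
  A/B/C formulas hold literally at the borders.
- Degenerate (flat) patches: `A·B ≤ eps` with `eps = 1e-12·n` is marked
  invalid with cc = 0 — a flat patch carries no correlation signal.  eps is
  an absolute guard, appropriate for intensities of order unity and above;
  for data scaled far below that, pass an explicit eps.
- Default radius r = 5, hard ceiling 8; CC is symmetric under swapping the
  images and invariant to per-image affine intensity rescaling.

## Symmetric deformable refinement

Two half-way displacement fields φ1, φ2 (mm, on the reference grid; a
warped image samples the source at x + u(x), edge-clamped) carry both
images toward a midpoint.  Each iteration computes the CC map between the
half-warped images and a voxelwise ascent direction from the analytic
derivative of `C²/(AB)` with respect to the center intensity,

    ∂cc/∂J(x) = 2C/(AB) · (Ī − (C/B) J̄),   Ī = I_T − m_I,  J̄ = J_T − m_J,

projected onto the image gradient (and the mirror expression for I).  The
update is Gaussian-smoothed (default 3 mm), scaled so the larger half-step
peaks at `step_vox/2` voxels (default step 0.25 voxel), applied
equal-and-opposite to the two fields, and the totals re-smoothed (default
1.5 mm).  A trial step is accepted only if the mean local CC increases;
rejections halve the step until a floor (0.02 voxel) ends the level.  Mean
CC is grid-dependent, so each pyramid level (default factors 2, 1) owns its
accepted trace; every per-level trace is non-decreasing by construction.

This greedy scheme deliberately replaces time-integrated velocity-field
optimization: the metric (the exact A/B/C local CC) and monotone
improvement are the contract; diffeomorphism is not enforced — the Jacobian
determinant range of the composed warp is reported, not constrained.  The
final reference→moving map composes the fixed-point inverse of φ1 (20
iterations or 1e-3 voxel residual) with φ2.

## Phantoms

Three nested ellipsoids — a bright "scalp/skull" shell (mean 90), a
"cortex"-like body (150) and a dark off-center "ventricle"-like core (45) —
with per-axis distinct semi-axes so rotations are identifiable.  A 1-voxel
Gaussian blur emulates partial-volume averaging at tissue borders (deep
interior voxels keep their exact means); additive Gaussian noise defaults
to 2.1, i.e. 2% of the 105-unit tissue contrast; an optional smooth
multiplicative bias field is available and off by default.  Everything is
driven by one seed and bit-reproducible.

Known motion is applied by resampling through the inverse map, so
registering moved→original recovers the stated parameters; the operation
rejects transforms keeping under 60% overlap.  Known deformations are
Gaussian-filtered white noise rescaled so each component's maximum equals
the target amplitude, with amplitude ≤ smoothness/2 to keep the warp
invertible in practice.

What the phantoms do *not* emulate: MR physics (no sequence model, no
Rician noise floor), gyral/sulcal texture, skull stripping artifacts,
multi-subject anatomical variability.  Passing the recovery suites shows
the optimization and metrics are correct on well-posed smooth-structure
inputs, not that accuracy transfers unchanged to clinical data.

## Problem sizes and experiment settings

The validation experiments use scaled-down volumes chosen as the smallest
grids on which all four pyramid stages remain meaningful: affine recovery
runs on a 64³ phantom (8 mm level 8³) with rigid truth (5, −3, 2) mm plus
7° about z and a 6-dof search; the 12-dof scale-recovery check uses 48³
with a 5% scale change; deformable refinement runs on a 40³ phantom with a
3-voxel-amplitude, 8-voxel-smoothness warp.  The deformable experiments use
CC radius 3 rather than the r = 5 customary for full-size brain volumes: an
11³ window on a 20³ coarse level over-smooths, so the window is scaled with
the scaled-down problem.

## Known limitations

- CR needs several voxels per bin to discriminate; the fixed 256/n bin rule
  assumes brain-sized fields of view at every stage.
- The deformable optimizer is first-order greedy; large deformations
  (amplitude approaching the structure scale) can stall in local optima.
- The cc-map eps guard is absolute, not intensity-relative.
- NIfTI orientation codes beyond spacing/origin are carried through on
  write but ignored in computation; inputs are assumed axis-aligned.
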