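# Methods

This note documents the models, numerical choices and limitations of
`femload` — what the package actually computes, why its defaults are what
they are, and what its synthetic tests do and do not show about real data.

## Inverse-remodelling model

The load history of a bone is represented by n unit load cases with
magnitudes αᵢ acting for mᵢ cycles. The local stimulus is the
cycle-weighted superposition of the per-case strain energy density (SED)
fields, U(x) = Σᵢ (mᵢ/m_tot)·αᵢ²·Uᵢ(x) = Σᵢ sᵢ·Uᵢ(x). The most probable
history minimises Σ_x [Ũ − U(x)]² subject to sᵢ ≥ 0, with the remodelling
equilibrium stimulus Ũ = 0.02 MPa by default. Assuming equal cycle counts
for all cases, αᵢ = √(n·sᵢ).

Consequences used throughout the package and its tests:

* **Stimulus scaling law.** Replacing Ũ by k·Ũ scales the optimal s by k
  exactly (the objective is linear in Ũ), hence α by √k, leaving all
  direction outputs unchanged.
* **Modulus scaling law.** Scaling every elastic modulus by k scales all
  SED fields by 1/k, hence s by k and α by √k, directions unchanged.
* **CoV scale invariance.** The coefficient of variation (population
  SD/mean, in %) of the stimulus field is invariant under positive
  rescaling, so the "uniformly scaled" initial CoV does not depend on the
  uniform level; sᵢ = 1/n is used.

The optimisation is solved with the Lawson–Hanson active-set
non-negative least squares algorithm (scipy.optimize.nnls), which is
deterministic. When unit-load patches overlap (many load cases), the
design matrix becomes rank-deficient and the solution non-unique; the
result then carries a `degenerate` flag but no remedy is applied — users
should reduce the number of load cases. The objective is evaluated over
bone elements only (remodelling applies to bone, not to the cartilage
stand-in); the region of interest can additionally retreat a configurable
distance from the lateral/distal boundaries to avoid boundary artefacts.
Peak-vector ties are broken by the lowest load-case index. Whether the
CoV of the source data used population or sample SD is not documented;
population SD was chosen for `compute_cov` (group summaries elsewhere use
sample SD, which reproduces the packaged table's printed SD row).

## Voxel finite elements

One 8-node trilinear hexahedron per labelled voxel, full 2×2×2 Gauss
integration of a single reference stiffness matrix scaled per element by
its modulus; mm–N–MPa units (10 GPa is stored as 10 000 MPa). The reduced
system (lateral + distal crop faces fully fixed) is assembled into a CSR
matrix whose sparsity pattern is cached per mesh, so modulus-only updates
(remodelling iterations, modulus variations) re-use the symbolic
assembly. Solves use conjugate gradients with a Jacobi preconditioner,
relative residual 1e-6 by default, optional warm starts; elements not
face-connected to a constrained face are removed (they would make the
operator singular) with a warning. ν = 0.5 is rejected.

Per-element SED is the element strain energy divided by the element
volume, ½·uₑᵀKₑuₑ/h³. An element-centroid strain recovery was considered
and rejected: the energy-based definition makes the global work balance
½fᵀu = ∫SED dV hold to solver accuracy on every solve, which is used as a
routine correctness check; a single-point recovery would violate it by a
discretisation-dependent margin. Cartilage SED is computed but flagged
and excluded from the optimisation.

On the uniaxial oracle (uniform traction on a clamped column) the
interior SED matches σ²/2E to ~1e-6 relative once the clamped-base
boundary layer has decayed; the acceptance test uses a 16×16×128 column
(32³ elements) and evaluates the top half for this reason — a cube-shaped
block never converges to the closed form because the Poisson-constrained
base is felt everywhere (St. Venant decay length ≈ section width).

## Image pipeline

Filtering is a Gaussian with σ = 1.6 voxels truncated at 2 voxels
(the "support 2" scanner convention); boundary handling is configurable
(`nearest` default, `wrap` available where strict mass conservation is
wanted). Resampling is block-mean pooling of grey values by an integer
factor *before* thresholding; segmentation uses grey ≥ threshold (the
inclusive rule makes a 0/6000 checkerboard resampled by two — mean
exactly 3000 — segment as bone). Thresholding an already-binary volume at
0.5 is the identity on labels.

The head sphere is an algebraic least-squares fit to surface voxels
within an angular window (default: hemisphere) of the proximal pole,
refined once; the published source does not specify the point selection,
so this is a documented approximation. The vertical axis is an SVD line
fit to distal slice centroids over a configurable shaft section (40 mm
default, scaled down for synthetic domains); obliquely cut end slices
(area < 80 % of the section median) are excluded because their centroids
are off-axis. The neck midpoint is found by sliding a slab (width
max(h, R/10)) along a search axis from the head centre, initially aimed
at the whole-bone centroid and refined twice towards the previous waist;
the smallest (3-point-smoothed) cross-section must be an interior
minimum, otherwise an error names the failure. The axes follow
ap = vert × neck, ml = ap × vert (right-handed, orthonormal to 1e-9).

The cartilage layer fills background voxels in the radial band
[R − t, R + t] over the articular region. "Articular" means directions
within 125° of the proximal pole and at least 45° away from the
neck-attachment direction — bone legitimately extends beyond the outer
sphere towards the neck and shaft, so the "no bone penetrates the
articular surface" check (which otherwise raises, advising a thicker
layer) is restricted to that region.

## Unit loads

The load patch is the set of exposed outer cartilage surface nodes whose
direction from the head centre lies within half the cone opening angle
(40° full angle by default, read as apex angle — this reproduces the
~224 mm² printed patch area for a ~24.3 mm articular sphere) of the load
direction. Three nodal force distributions are provided: equal magnitudes
along inward surface normals (reference), equal vectors parallel to the
load direction, and a Hertzian profile √(1 − (r/a)²) with contact radius
a = R_articular·sin(half angle). In all modes nodal magnitudes are
rescaled so the resultant is exactly the configured 1000 N; patches
clipped by the articular boundary are reported (achieved direction and
deviation) and warned about beyond 5°. Patch areas are estimated by
projecting exposed voxel faces onto the sphere normal, which converges to
the smooth cap area despite the staircase surface. Compressive sense:
nodal forces push into the head (along −d); reported joint load vectors
are presented along +d.

## Synthetic data

**Forward remodelling generator.** The validation data of the original
method (real scans, measured loads) cannot be shipped, so specimens are
*manufactured* with a known load history: an intermediate-density model
E(x) = E₀·ρ³ on a mini joint (hemispherical cap of radius L/4 on a
cylindrical pedestal, default 48³ voxels of 0.5 mm), stimulus
S = U/ρ under the cycle-weighted true load mix, update
ρ ← clip(ρ + 0.2·(S − S*)/S*, 0.25, 1) until the mean density change per
step falls below 1.5e-3 (explicit failure after 80 iterations — an
oversized step is the documented way to provoke it), then binarisation at
ρ ≥ 0.5. The density floor of 0.25 keeps the elastic operator
well-conditioned (contrast 64 after cubing) — it plays the role of the
near-void density used in density-based adaptation studies. Adaptation
runs on an element lattice at twice the voxel pitch and the converged
structure is rendered at the full voxel grid; the inverse pipeline's own
×2 block-mean resampling recovers that lattice, mirroring the
scan-then-resample flow of high-resolution CT workflows. The target
stimulus defaults to the inverse model's Ũ (0.02 MPa) and the default
true load (1000 N at 20° through the standard 40° cone) was chosen so the
adapted load column reaches equilibrium at mid-to-full density
(σ ≈ √(2EŨ) = 20 MPa over ~50 mm²) — a regime where binarisation
preserves the load path.

What recovery tests show: with matched Ũ, the pipeline assigns the
largest α to the generating direction in 20/20 seeded repeats and
recovers the generating magnitude within a few percent (30 % is the
asserted bound). What they do not show: performance on real trabecular
microarchitecture, multi-activity load histories, or biological
confounders (the generator is purely mechanical, isotropic, and
noise-free below the grayscale stage).

**Grayscale rendering** maps a binary structure to two grey levels
(defaults 6000/1000, bracketing the 3000 threshold), followed by optional
Gaussian blur and seeded additive Gaussian noise — partial-volume and
beam-hardening physics are out of scope.

**Load traces** are half-sine force cycles with a fixed frontal-plane
direction per activity and optional Gaussian subject-level magnitude
jitter (SD in N, default 0). The default six activities peak at 2.7 kN
near 18° (walking) and span inclinations 3.7°–66.6°, emulating the
published instrumented-prosthesis summary figures. Samples with
negligible magnitude are excluded from inclination ranges (their
direction is undefined).

**Fixture.** The published per-specimen α/CoV table ships as a versioned
CSV inside the package; its printed Mean/SD rows are kept alongside the
ten records and reproduced by computation in the tests.

## Statistics

Group summaries use sample SD (n − 1), which reproduces the fixture's
printed SD row from its ten values. The Wilcoxon signed-rank test reports
W = min(T⁺, T⁻) with an exact two-sided p (n ≤ 25) by default; a normal
approximation without continuity correction is available behind a flag
because published p-values for this design are often the approximate
ones (the packaged CoV pairs give exact p ≈ 0.00195 vs approximate
p ≈ 0.005). Both are exposed; neither is treated as the "true" value.

## Problem sizes and defaults in tests

The test-suite and acceptance runs use 40³–48³-voxel synthetic domains
(20³–24³ FE elements after resampling), 32³-element FE verification
problems, 20 recovery seeds and the full 19-run sensitivity design; these
sizes were chosen as the smallest at which every geometric and mechanical
feature of the pipeline (sphere fit, cone patches, boundary fixation,
load-path formation) is genuinely exercised.

## Known limitations

* The anatomical frame construction approximates the unpublished details
  of the original neck-axis procedure; it is validated against synthetic
  femora with known ground truth, not against expert landmarking.
* Uniform/Hertzian circular patches idealise the true (possibly
  horseshoe-shaped) contact pressure; bone-to-bone contact is not
  modelled.
* Load-cycle counts are fixed equal across cases; distinct mᵢ cannot be
  estimated from a single equilibrium snapshot.
* The sensitivity harness supports synthetic desk-scale specimens;
  specimen-specific published sensitivity magnitudes from real scans are
  not reproducible without the scan data.
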