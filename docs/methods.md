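# Methods

Conventions, algorithms and default parameters of the `lorefine` package.

## Geometry conventions

- **Euler angles.** ZYZ convention, degrees: `R = Rz(ψ) · Ry(θ) · Rz(φ)`.
  `euler_matrix(φ, θ, ψ)` maps model coordinates to the projection frame;
  projection integrates along the rotated z axis. A positive in-plane shift
  `(x, y)` moves the object toward +x, +y in the image.
- **Projection direction.** The pair `(φ, θ)`; `direction_to_vector` gives
  the unit viewing vector. `span_angle` is the great-circle angle between
  two directions (arc-cosine of the dot product, so spans below ≈ 1e-6° are
  indistinguishable in double precision — tests and coincidence logic treat
  this as the resolution floor).
- **Quasi-uniform direction sets.** `generate_direction_set(s)` tiles the
  sphere with ≈ 41253/s² directions (equal-area rings), so any direction has
  a set member within ~1.5·s.
- **Parallel transport of ψ.** When a candidate direction differs from the
  preliminary one, the preliminary in-plane angle is carried over by
  `transported_psi`: the preliminary rotation matrix is composed with the
  minimal (geodesic) rotation taking the old viewing vector onto the new
  one, and ψ is read back from the composed matrix. For directions on one
  meridian this reduces to ψ_i = ψ₀ (same meridian) or
  ψ_i = φ₀ + ψ₀ − φ_i (antipodal meridian). Transport is rejected for
  antipodal direction pairs, where it is undefined.

## Scoring

The objective everywhere is the cross-correlation coefficient

CCC(f₁, f₂) = Σ (f₁−⟨f₁⟩)(f₂−⟨f₂⟩) / sqrt(Σ (f₁−⟨f₁⟩)² · Σ (f₂−⟨f₂⟩)²),

optionally weighted by a 2-D mask (weighted means and sums; the mask is
applied to both images symmetrically). For a two-module complex the
experimental image f₁ = f₁ᵃ + f₁ᵇ and the simulated image f₂ = f₂ᵃ + f₂ᵇ
decompose the numerator into four covariance terms
(`ccc_numerator_terms`): the target–target term is what the module-wise
search maximizes, and the cross term between the experimental target and
the simulated non-target is the interference a good target mask suppresses.
`ccc_target` optionally subtracts k × (simulated non-target) from the
experimental image first, with k fitted by least squares or fixed.

During refinement the score of a candidate is the masked CCC between the
experimental image and the **composite** projection: target module at the
candidate parameters plus the remainder of the model at the preliminary
parameters. Scoring is band-limited to 16 Å by default and masked with a
36-pixel circular mask centred on the particle's preliminary shift; both are
radial Fourier multipliers / static masks and therefore commute with the
in-plane rotations and integer shifts used by the grid scan.

## Local search

The search neighbourhood (`SearchRange`) around the preliminary parameters:

- directions within a cone of α₀ = 10° drawn from a global quasi-uniform
  set of 2° spacing (the preliminary direction is always a member),
- in-plane angle on a transported grid ψ ± t₁·d₁ with d₁ = 2°, t₁ = 3,
- shifts on a square grid x, y ± t₂·d₂ with d₂ = 1 px, t₂ = 4.

The ψ half-extent t₁ = 3 (±6°) is chosen as ≈ 3.6 standard deviations of
the 1.67° module-rotation distribution the benchmark draws from, so the
in-plane error of essentially every particle lies inside the grid while the
grid stays small.

Two strategies explore the grid:

- **simultaneous** — exhaustive scan of all angles × all shifts
  (`n_angles · n_shifts` evaluations).
- **separate** — stage 1 draws `n_trial_angles` (default 10) random angle
  triples from the grid, exhausts the shift grid for each, refines each
  argmax to sub-pixel precision by parabolic interpolation and averages the
  per-trial optima component-wise; stage 2 exhausts the angle grid at that
  fixed shift. One guard evaluation at the preliminary parameters ensures
  the returned score never falls below the starting point. Total:
  `min(n_trial, n_angles) · n_shifts + n_angles + 1` evaluations —
  typically ~30× fewer than the simultaneous scan at identical extents.

Grid evaluation counts are predicted by `predicted_grid_evaluations` and
recorded per run in `stack.extra["refine_stats"]`.

Ties on the grid are broken deterministically (smallest angular span, then
smallest |Δψ|, then grid order; shifts by smallest magnitude), and the
stage-1 random subset is drawn from a stream keyed by `(rng_seed,
particle_index)`, so runs are exactly reproducible.

## Module refinement and iteration

`refine_module` recentres the model so the target module's centre of density
sits at the box centre (integer-voxel roll, lossless), transforms each
particle's parameters into the recentred frame, optimizes every particle,
reconstructs the module by weighted back projection with the refined
parameters, and rolls the reconstruction back. Because the roll is
circular, voxels within the roll distance of the box faces wrap; the
interior is unaffected. Per-particle failures (degenerate CCC across the
whole grid) are flagged, not fatal; the pass aborts only if more than half
the particles fail.

`refine_all_modules` runs `refine_module` for every module independently
from the same input parameters — each particle ends with one parameter set
per module — and combines each module's own reconstruction region (via its
mask) into an updated model; voxels covered by no mask keep the input
model. With `n_iterations > 1` the combined model and per-module parameters
feed the next round. Iteration quality is reconstruction-limited: on very
small stacks the second iteration aligns against a particle-starved
reconstruction and can regress, while at the benchmark scale (300
particles) it is stable.

`conventional_global_refine` is the whole-complex baseline: exhaustive
matching against a 15° projection library (directions × in-plane angles),
then multi-resolution local rounds alternating a shift pass and an angle
pass with model re-reconstruction between rounds, converging when the mean
parameter change drops below half a step. It is deterministic and uses no
randomness.

## Reconstruction and resolution

`wbp_reconstruct` is classical weighted back projection: each image is
ramp-filtered (|s|, capped at Nyquist) in 2-D Fourier space and smeared
along its viewing axis with the adjoint of the trilinear projector; the sum
is normalized by the particle count. `fsc` correlates two volumes over
integer-radius Fourier shells; `resolution_at_threshold` linearly
interpolates the first crossing of FSC = 0.5 and reports Nyquist with
`crossed=False` when the curve never crosses. Module-wise resolutions are
measured after weighting both volumes with a cosine-tapered
`soft_shape_mask` of the module.

## Synthetic benchmark

- **Phantom.** N = 64, 4 Å/px, two modules of Gaussian blobs separated by a
  plane partition, mass ratio 2:1, deliberately asymmetric. Module masks
  are binary, disjoint, and sum to one inside the molecular region.
- **Per-particle conformation.** Each module is independently rotated about
  its density centroid by an angle drawn from N(0, 1.67°) about a uniformly
  random axis and shifted by a 3-D vector with independent N(0, 1 px)
  components.
- **Orientations.** Global poses uniform over the sphere (φ, ψ uniform,
  cos θ uniform). Particle i uses the seed substream `(rng_seed, i)`, so
  datasets are reproducible and extensible.
- **Degradation.** Gaussian white noise at SNR ∈ {0.25, 0.11, 0.06},
  defined as variance(signal)/variance(noise) over the full image frame.
  In CTF mode images are generated CTF-modulated and consumed after phase
  flipping; scoring applies |CTF| to the simulated side, which matches the
  phase-flipped experimental side up to the (radial) modulus and therefore
  commutes with the in-plane grid operations.

## File formats

- **MRC2014** mode 2 (float32) for volumes, masks and stacks; mode 0/1/2
  readable; pixel size in the cell parameters; `MAP ` stamp enforced.
- **Parameter tables**: self-describing whitespace-separated text with a
  header row (`index phi theta psi x y ...`), degrees and pixels, angles
  normalized to [0, 360) on read, unknown columns preserved.
- **FSC text**: two columns, spatial frequency (cycles/Å) and correlation.
- **Manifest**: JSON with seed, configuration echo, library versions and
  SHA-256 of every output file.

## Numerical notes

- Real-space projection and rotation use trilinear interpolation; its
  accuracy floor (relative errors ~1e-2 for rotation-invariance style
  comparisons at N = 64) bounds what any projection-consistency test can
  demand. The Fourier-slice projector (`FourierProjector`) agrees with the
  real-space operator to the same order and is the default in refinement
  for speed.
- All CCC accumulations are double precision; the conventional baseline's
  coarse library matching uses float32 matrix products, which is why its
  determinism is guaranteed per-platform rather than bit-exact across
  BLAS implementations.
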