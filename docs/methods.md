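# Methods

## Projection model and conventions

All frames are right-handed.  The microscope Z-axis runs along the beam
and Y along the tilt axis; the sample frame coincides with the microscope
frame at zero tilt and has its origin at the centroid of the fitted
fiducials.  Image coordinates `(u, v)` are in pixels with the origin at
the image centre (`(size−1)/2` in 0-based array indices), `u` rightward,
`v` upward.

The per-image rotation is composed as `R = Rz(ψ) Ry(θ) Rx(α)` — the
in-plane rotation ψ acts after the projection, hence outermost; α is an
optional pretilt.  The sign of θ is pinned so that positive tilt rotates
+X toward −Z (`Ry(90°)` maps `(1,0,0)` to `(0,0,−1)`); importers expose a
`negate` flag for stacks recorded with the opposite convention.  The
projection matrix is `M = m P R` with `P` deleting the Z row and `m` an
isotropic magnification.

## Motion surfaces

Sample motion at image `i` is a triad `D_i = (Δx, Δy, Δz)` of polynomial
surfaces in sample coordinates, or equivalently a pair `S_i = (Su, Sv)`
at the image plane with `S_i = M_i D_i` (coefficient-wise
`(Su, Sv)ᵀ_mnl = M_i (Δx, Δy, Δz)ᵀ_mnl`).  Surfaces are polynomials
`Σ P_mnl x^m y^n z^l` over `l ≤ Dz`, `m+n ≤ D−l`.  Only the bivariate
(`Dz = 0`) and trivariate (`Dz = D`) families are supported: these are
the two cases in which the closed-form coefficient count
`(Dz+3)(D+2)(D+1)/6` equals the monomial enumeration, and the two cases
that matter in practice (no/with z-variation of the motion).  Coefficient
order is pinned — z-power outermost, then total xy-degree, then x-power
descending: `P00, P10, P01, P20, P11, P02` for the bivariate quadratic —
and serialised motion files record it explicitly.

Degenerate directions are gauge-fixed rather than left to the solver:
the constant terms of `Su`/`Sv` are indistinguishable from the image
shift `d_i` and are masked to zero by default (an option refits `d_i`
jointly instead); the marker centroid is pinned at the origin;
magnification is never refit in step 2 since the linear polynomial terms
absorb it.

## Two-step fitting

**Step 1** solves the standard bundle adjustment for `r_j`, `d_i` and
optionally ψ/θ/m per image, using Levenberg–Marquardt least squares with
an analytic Jacobian (trust-region reflective near critical determinacy),
warm-started by per-marker linear triangulation.  With no per-image
refinement the problem is linear and the solver reaches the exact global
optimum (verified against a direct linear solve in the tests).
Convergence: relative decrease of the objective below 1e−10 (configurable),
200 iteration budget; non-convergence is flagged in the fit report, and an
under-determined system raises an error naming the deficit.  External
alignments (`.tlt`/`.xf` plus a 3D marker table) can be adopted instead
of refitting.

**Step 2** freezes `r_j`, `M_i`, `d_i` and fits, image by image, the
enabled surface coefficients to the step-1 residuals by linear least
squares — convex and deterministic.  Marker coordinates are normalised by
their largest absolute value before building monomial design matrices
(quadratics of raw ±500 px coordinates are badly conditioned) and the
coefficients rescaled back to pixel units.  Rank deficiency is resolved
minimum-norm via SVD with relative threshold 1e−10; for the 3D triad this
is what zeroes the unobservable beam-parallel component.  Images with too
few observations fall down a logged ladder: full → pure-z-only terms →
pure terms → degree 1 → no motion.  Parameter-reduction masks: *pure
terms* keeps `P_m00, P_0n0, P_00l`; *pure z only* keeps `P_mn0, P_00l`.

Because the zero polynomial is always feasible, the motion-aware residual
never exceeds the step-1 residual.  Note that step 1, when refit on
motion-bearing data, partially absorbs the motion into biased `r_j` and
`d_i` (the fitted "standard residual" is smaller than the residual at the
true geometry); consequently machine-precision parameter recovery on
noise-free data is demonstrated with step 1 adopting the reference
alignment, the workflow also used with external alignments.

## Leave-one-out validation

Each marker in turn is removed, the motion refit (step 2 only by
default; `refit_step1=True` redoes the bundle adjustment per fold), and
the held-out marker's positions predicted at its full-fit coordinates.
The LOO residual is the mean over markers of per-marker mean prediction
errors (a pooled-over-observations variant is available).  Verdict: model
valid when LOO < standard-alignment residual.

## Reconstruction

Motion-compensated WBP works on the raw, unaligned stack: each voxel is
tracked into every image via `M_i x + S_i(x) + d_i` (alignment and motion
folded into one mapping, no intermediate interpolation), sampled
bilinearly from the ramp-filtered image, accumulated, and normalised by
the number of images that actually contained it (no extrapolation beyond
image edges).  Because motion shifts vary across the sample, a voxel's
`v`-coordinate varies within a slice, so the full 2D image is sampled
rather than one detector line per slice.

The ramp filter multiplies each detector row by `2|f|` in the frequency
domain (`f` in cycles/sample; DC maps exactly to zero, Nyquist weight 1),
with optional Hamming apodisation.  Filtering is applied to the
projections *before* backprojection — the conventional WBP order, chosen
over post-weighting reconstructed slices because it commutes cleanly with
the motion-dependent sampling; with zero motion the compensated path
reproduces plain WBP bitwise.  Subtiltseries extraction crops per-image
patches centred on the rounded tracked projection, recording the
sub-pixel remainder and flagging images where the patch leaves the frame.

## Synthetic doming generator

The generator produces the study conditions used throughout the tests.
Defaults (all config-exposed):

- **Scheme**: ±60° at 3° in two branches from −21° (41 images), the
  well-conditioned two-branch scheme typical of dose-symmetric-style
  collection; storage order is angle order, acquisition order recorded.
- **Markers**: 40 beads uniform in a 1000 × 1000 × 120 px slab.
- **Amplitude schedule**: dose decay
  `A(k) = plateau + (A0 − plateau)·exp(−dose_k ln2 / half-life)` with
  half-life 12 e⁻/Å² of the 60 e⁻/Å² total dose, plateau 0.5 px, plus a
  renewed-exposure transient (fraction 0.5) at the start of the second
  branch that decays with dose accumulated inside the branch — each
  branch's motion is largest at its first acquired image, as renewed
  exposure re-excites the sample.
- **Spatial pattern**: a quadratic dome (axial bowl with mild asymmetry,
  in-plane relaxation fraction 0.3, optional linear z-gradient for thick
  samples) projected through each image's geometry, blended with an
  independent per-exposure quadratic (fraction 0.4 by RMS) — deformation
  is not smooth in time, which is exactly why each image is modelled
  independently.  Truth constants are zero; rigid per-image motion lives
  in the true shifts `d_i`.
- **Amplitude semantics**: `A0` is the RMS image-plane motion over the
  marker field at the first acquired image.  The default `A0 = 8 px` is
  calibrated so the default scenario reproduces the residual scale
  typical of real thin-sample tilt series: standard alignment ≈ 1.9 px,
  motion-aware ≈ 0.75 px at 0.5 px localisation noise.
- **Noise**: i.i.d. Gaussian bead-localisation error, σ = 0.5 px;
  optional visibility dropout (every marker kept observable in ≥ 3
  images).  All randomness derives from one integer seed; fixed seed
  gives byte-identical outputs.

By default the truth is expressed directly in the 2D image-plane form —
the part of the motion the projection can ever reveal; a 3D mode exposes
the sample-frame triad to exercise the 2D/3D conversion and the
beam-parallel unobservability.  The renderer draws Gaussian beads (or
point sources, or two large spheres) at the exactly tracked positions.

What the generator does *not* emulate: physical image formation (CTF,
multiple scattering, detector MTF), frame-level movies, non-polynomial
deformation, correlated localisation errors, and bead-detection failures
beyond random dropout.  Passing tests therefore demonstrate the
estimator and reconstruction machinery under the doming model's own
assumptions, not robustness to model violation on real micrographs.

## Numerical choices and problem sizes

Desk-scale defaults keep the whole suite fast: alignment problems are a
few hundred unknowns (dense Jacobians), reconstruction tests use
256²-pixel stacks of 41 images and ≤ 112×112×48-voxel volumes, Monte-Carlo
claims use 10–20 seeded replicates.  Reconstruction chunks voxels
(2×10⁶ per block) to bound memory; outputs are float32 MRC mode 2.
Ties/degeneracies: minimum-norm solutions throughout (SVD, rcond 1e−10);
zero-observation images get zero motion with a warning.

## Known limitations

- Temporal smoothness across adjacent images is deliberately not
  enforced; each image is independent.
- The per-acquisition residual curve of a *refit* standard alignment
  mixes the motion magnitude with tilt-dependent absorption effects; the
  curve against an adopted reference alignment reflects the amplitude
  schedule directly.
- The LOO verdict is a global summary; spatially clustered beads can
  still hide locally unreliable deformation estimates.
- Reconstruction is plain WBP (no SIRT/Fourier inversion, no dose
  weighting, no CTF handling) and is not optimised for production-size
  (4k²) tomograms.
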