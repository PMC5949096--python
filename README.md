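# domealign

Motion-aware fiducial tilt-series alignment and motion-compensated
weighted-backprojection (WBP) reconstruction for electron cryo-tomography
(cryo-ET).

## The problem

During tilt-series acquisition the electron beam domes the vitreous-ice
layer: the sample undergoes a drum-like deformation, largest at the first
exposures and decaying with accumulated dose.  Standard fiducial (gold
bead) alignment assumes a rigid specimen, so this motion shows up as
systematic residuals, suboptimal alignment and blurred tomograms.
`domealign` is for cryo-ET practitioners and method developers who want to
model that deformation explicitly and reconstruct with it compensated.

## The model

Standard alignment fits the single-tilt-axis projection model

```
p_ji = M_i r_j + d_i ,    M_i = m_i P R_i ,    R_i = Rz(ψ_i) Ry(θ_i) Rx(α_i)
```

by nonlinear least squares on `f = Σ_ji ‖q_ji − p_ji‖²`, where `r_j` are
the 3D bead coordinates, `q_ji` the measured bead positions, `d_i` the
image shifts and `P` the projection along the beam.  `domealign` extends
this with per-image polynomial motion surfaces, in either form:

```
p_ji = M_i (r_j + D_i(r_j)) + d_i          (3D sample-frame triad Δx, Δy, Δz)
p_ji = M_i r_j + S_i(r_j) + d_i            (2D image-plane pair  Su, Sv)
```

where each surface is a polynomial `P(x,y,z) = Σ P_mnl x^m y^n z^l` with
`m+n ≤ D−l`, `l ≤ Dz` — bivariate (`Dz = 0`) for thin samples, trivariate
(`Dz = D`) when the motion varies across the thickness.  Quadratic
surfaces (`D = 2`) describe doming well; they cost 18/30 parameters per
image in the 3D form and 12/20 in the equivalent 2D form
(`S_i = M_i D_i`).  The projection makes beam-parallel motion invisible,
so the 3D fit is solved minimum-norm (its fitted vectors are exactly
perpendicular to the beam) and the 2D form is the default.

Fitting is two-step: (1) standard bundle adjustment (or adoption of an
external alignment from `.tlt`/`.xf` files); (2) per-image *linear*
least-squares fit of the surfaces to the step-1 residuals.  A
leave-one-out (LOO) residual — each bead in turn held out of the motion
fit and predicted — validates the deformation model: LOO below the
standard residual means the model generalises; above it flags
overfitting from scarce or poorly distributed beads.  Reconstruction
tracks every voxel through the raw stack with `M_i x + S_i(x) + d_i` and
backprojects ramp-filtered images, yielding motion-compensated tomograms
and subtiltseries.

## Worked example

Simulate a doming tilt-series (41 images, ±60° at 3° in two branches from
−21°, 40 beads, 0.5 px localisation noise), then align with and without
motion modelling:

```
$ domealign simulate --seed 1 --out demo
$ domealign align --tracks demo/tracks.txt --tlt demo/series.tlt --out demo_align --loo
standard mean residual : 2.0029 px
motion   mean residual : 0.7993 px
LOO residual           : 0.9196 px (model valid)
```

The standard alignment leaves a 2.0 px mean residual — the unmodelled
beam-induced motion.  Quadratic bivariate motion surfaces drop it to
0.80 px (essentially the bead localisation noise), and the LOO residual
(0.92 px) is well below the standard residual, so the fitted deformation
field generalises beyond the beads used to fit it.  `demo_align/` also
contains the per-acquisition residual curve (highest at each branch
start, decaying to a plateau with dose), the fitted motion model and a
report with the measurements/unknowns ratio (6.67 here).

Reconstruction:

```
$ domealign reconstruct --stack demo/stack.mrc --align demo_align/alignment.txt \
      --motion demo_align/motion.txt --size 256,256,96 --out tomo.mrc
```

## Layout

- `src/domealign/geometry.py` — projection model and conventions
- `src/domealign/motion.py` — polynomial surfaces, 2D/3D forms, masks
- `src/domealign/alignment.py` — two-step fit, diagnostics
- `src/domealign/crossval.py` — leave-one-out validation
- `src/domealign/recon.py` — motion-compensated WBP, tracking, subtiltseries
- `src/domealign/synthetic.py` — ground-truthed doming simulator
- `src/domealign/io.py` — text formats (`.tlt`, `.xf`, tracks, motion,
  reports) and MRC
- `src/domealign/cli.py` — `domealign` subcommands

See `docs/methods.md` for the modelling details, parameter defaults and
known limitations.
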