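"""Ground-truthed synthetic tilt-series with doming-style motion.

The generator emulates the conditions a motion-aware alignment faces in
practice:

* a two-branch single-axis acquisition scheme (default +/-60 deg at 3 deg,
  both branches starting from -21 deg, 41 images — the best-conditioned
  scheme among the method's usual test cases);
* beam-induced motion whose magnitude decays exponentially with
  accumulated dose, halving every ~12 e-/A^2 and settling on a plateau —
  motion is largest at the first acquired image of each branch;
* a smooth quadratic ("doming-like") spatial motion pattern, fixed per
  scenario, scaled per image by the dose-decayed amplitude.  By default
  the truth is generated directly in the 2D image-plane form (that is what
  alignment can identify); a 3D dome mode generates the sample-frame triad
  and projects it, to exercise the 2D/3D conversion and the beam-parallel
  unobservability;
* i.i.d. Gaussian marker-localisation noise and optional visibility
  dropout.

The amplitude parameter is calibrated at the image plane: ``amplitude0``
is the RMS image-plane motion (pixels) over the marker field at the first
acquired image.  Constant (field-centre) motion terms are identically zero
in the truth — a rigid per-image shift is indistinguishable from ``d_i``
and lives there instead, matching the fitting gauge.

All randomness comes from one integer seed; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentSolution, MarkerTrackSet, solution_from_reference
from .geometry import TiltImageGeometry, TiltSeriesGeometry
from .motion import (
    MotionModel2D,
    MotionModel3D,
    convert_3d_to_2d,
    count_coeffs,
    monomial_exponents,
)

__all__ = [
    "DomingScenario",
    "GroundTruth",
    "make_scenario",
    "simulate_tracks",
    "render_stack",
    "two_branch_scheme",
]

LN2 = float(np.log(2.0))


def two_branch_scheme(
    tilt_min: float = -60.0,
    tilt_max: float = 60.0,
    step: float = 3.0,
    branch_start: float = -21.0,
) -> list[tuple[float, int, int]]:
    """(tilt angle, acquisition index, branch) in stack (angle) order.

    Branch 0 sweeps from ``branch_start`` up to ``tilt_max``; branch 1 then
    sweeps from ``branch_start - step`` down to ``tilt_min``.
    """
    if not (tilt_min <= branch_start <= tilt_max) or step <= 0:
        raise ValueError("invalid tilt scheme")
    up = np.arange(branch_start, tilt_max + 1e-9, step)
    down = np.arange(branch_start - step, tilt_min - 1e-9, -step)
    entries = [(float(a), k, 0) for k, a in enumerate(up)]
    entries += [(float(a), len(up) + k, 1) for k, a in enumerate(down)]
    entries.sort(key=lambda e: e[0])
    return entries


@dataclass
class GroundTruth:
    """Truth bundle returned alongside simulated tracks."""

    markers: np.ndarray
    geometry: TiltSeriesGeometry
    motion2d: MotionModel2D
    motion3d: MotionModel3D | None
    amplitudes: np.ndarray  # per stack-order image, pixels

    def solution(self, tracks: MarkerTrackSet | None = None) -> AlignmentSolution:
        """Reference alignment solution built from the truth."""
        return solution_from_reference(
            self.geometry, self.markers, tracks, motion=self.motion2d
        )


@dataclass
class DomingScenario:
    """Configuration + realised ground truth of one synthetic tilt-series.

    Parameters (all lengths in pixels, doses in e-/A^2):

    n_markers, extent, thickness
        Fiducials uniformly placed in the slab
        [-extent/2, extent/2]^2 x [-thickness/2, thickness/2].
    amplitude0, amplitude_plateau, dose_half_life, total_dose
        Dose decay of the motion amplitude:
        ``A(k) = plateau + (A0 - plateau) * exp(-dose_k * ln2 / half_life)``
        with ``dose_k`` the dose accumulated before acquisition ``k``.
    branch_restart_fraction
        Relative size of the renewed-exposure transient at the start of
        the second branch (decays with dose accumulated inside the
        branch); each branch therefore has its largest motion at its first
        acquired image.
    pattern_jitter
        Fraction (by RMS) of each image's motion drawn as an independent
        per-exposure quadratic rather than the shared dome pattern; the
        sample deformation is not smooth in time, which is why each image
        is modelled independently.
    tilt_min, tilt_max, tilt_step, branch_start
        Two-branch acquisition scheme (see :func:`two_branch_scheme`).
    noise_sigma
        Marker localisation noise, i.i.d. Gaussian per coordinate.
    motion_form
        '2d' (default): truth generated directly at the image plane;
        '3d': a sample-frame dome triad is generated and projected.
    z_gradient
        Relative weight of motion variation across the thickness; nonzero
        makes the truth trivariate (thick-sample emulation).
    lateral_fraction
        In the 3D mode, in-plane dome relaxation relative to the axial bowl.
    shift_sigma
        Std of the true random per-image rigid shifts d_i.
    dropout
        Probability that an individual marker observation is missing.
    """

    n_markers: int = 40
    extent: float = 1000.0
    thickness: float = 120.0
    amplitude0: float = 8.0
    amplitude_plateau: float = 0.5
    dose_half_life: float = 12.0
    total_dose: float = 60.0
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_step: float = 3.0
    branch_start: float = -21.0
    branch_restart_fraction: float = 0.5
    pattern_jitter: float = 0.4
    noise_sigma: float = 0.5
    motion_form: str = "2d"
    z_gradient: float = 0.0
    lateral_fraction: float = 0.3
    shift_sigma: float = 2.0
    dropout: float = 0.0
    seed: int = 0

    # realised fields
    geometry: TiltSeriesGeometry = field(init=False, repr=False)
    markers: np.ndarray = field(init=False, repr=False)
    amplitudes: np.ndarray = field(init=False, repr=False)
    truth: GroundTruth = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_markers < 1 or self.extent <= 0 or self.thickness < 0:
            raise ValueError("invalid scenario dimensions")
        if self.amplitude0 < 0 or self.amplitude_plateau < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.amplitude_plateau > self.amplitude0:
            raise ValueError("plateau amplitude cannot exceed the initial amplitude")
        if self.branch_restart_fraction < 0:
            raise ValueError("branch_restart_fraction must be non-negative")
        if not 0.0 <= self.pattern_jitter <= 1.0:
            raise ValueError("pattern_jitter must be in [0, 1]")
        if self.motion_form not in ("2d", "3d"):
            raise ValueError("motion_form must be '2d' or '3d'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self._build()

    # -- construction -----------------------------------------------------

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def _build(self) -> None:
        scheme = two_branch_scheme(
            self.tilt_min, self.tilt_max, self.tilt_step, self.branch_start
        )
        N = len(scheme)
        dose_per_image = self.total_dose / N
        acq = np.array([k for (_, k, _) in scheme])
        branch = np.array([b for (_, _, b) in scheme])
        dose_before = acq * dose_per_image
        first_acq = {b: acq[branch == b].min() for b in np.unique(branch)}
        dose_in_branch = np.array(
            [(k - first_acq[b]) * dose_per_image for k, b in zip(acq, branch)]
        )
        decay = np.exp(-dose_before * LN2 / self.dose_half_life)
        # renewed-exposure transient at the restart of later branches: the
        # sample settles again after the pause/stage return between branches
        restart = np.where(
            branch > 0,
            self.branch_restart_fraction
            * np.exp(-dose_in_branch * LN2 / self.dose_half_life),
            0.0,
        )
        self.amplitudes = self.amplitude_plateau + (
            self.amplitude0 - self.amplitude_plateau
        ) * (decay + restart)

        rng = self._rng(0)
        half = self.extent / 2.0
        zhalf = max(self.thickness / 2.0, 1e-9)
        self.markers = np.column_stack(
            [
                rng.uniform(-half, half, self.n_markers),
                rng.uniform(-half, half, self.n_markers),
                rng.uniform(-self.thickness / 2.0, self.thickness / 2.0, self.n_markers),
            ]
        )
        shifts = rng.normal(0.0, self.shift_sigma, size=(N, 2))
        images = [
            TiltImageGeometry(
                tilt_angle_deg=a,
                shift=shifts[i],
                acquisition_index=k,
                branch_id=b,
            )
            for i, (a, k, b) in enumerate(scheme)
        ]
        self.geometry = TiltSeriesGeometry(images)

        trivariate = self.z_gradient != 0.0
        D, Dz = 2, (2 if trivariate else 0)
        exps = monomial_exponents(D, Dz)
        n_terms = count_coeffs(D, Dz)
        idx = {e: k for k, e in enumerate(exps)}

        # sample-frame dome pattern in normalised coordinates: axial
        # quadratic bowl plus in-plane relaxation (constant terms belong to
        # the rigid shifts d_i and are identically zero here)
        prng = self._rng(1)
        cx = np.zeros(n_terms)
        cy = np.zeros(n_terms)
        cz = np.zeros(n_terms)
        cz[idx[(2, 0, 0)]] = -1.0
        cz[idx[(0, 2, 0)]] = -1.0
        cz[idx[(1, 1, 0)]] = 0.3 * prng.normal()  # mild dome asymmetry
        cz[idx[(1, 0, 0)]] = 0.3 * prng.normal()
        cz[idx[(0, 1, 0)]] = 0.3 * prng.normal()
        if trivariate:
            cz[idx[(0, 0, 1)]] = self.z_gradient
            cx[idx[(0, 0, 1)]] = 0.5 * self.z_gradient * prng.normal()
            cy[idx[(0, 0, 1)]] = 0.5 * self.z_gradient * prng.normal()
        cx[idx[(1, 0, 0)]] = self.lateral_fraction
        cy[idx[(0, 1, 0)]] = self.lateral_fraction
        cx[idx[(2, 0, 0)]] = 0.3 * self.lateral_fraction * prng.normal()
        cy[idx[(0, 2, 0)]] = 0.3 * self.lateral_fraction * prng.normal()

        # normalised marker coordinates and design matrix
        mk_n = self.markers / np.array([half, half, zhalf])

        def to_pixel_units(c: np.ndarray) -> np.ndarray:
            out = c.copy()
            for k, (m, n, l) in enumerate(exps):
                out[k] /= half ** (m + n) * zhalf**l
            return out

        B = np.stack(
            [
                mk_n[:, 0] ** m * mk_n[:, 1] ** n * mk_n[:, 2] ** l
                for (m, n, l) in exps
            ],
            axis=1,
        )
        from .geometry import projection_matrix

        M = np.stack([projection_matrix(g) for g in self.geometry])  # (N, 2, 3)
        triad = np.stack([cx, cy, cz])  # (3, n_terms)
        if self.motion_form == "2d":
            # truth expressed directly at the image plane: per image, blend
            # the projected dome with an independent per-exposure quadratic
            # (each exposure deforms the sample anew; the motion is not
            # smooth in time), then calibrate the pair so its RMS
            # image-plane motion over the markers equals A_i
            jrng = self._rng(4)
            jf = self.pattern_jitter
            coeffs = np.empty((N, 2, n_terms))
            for i in range(N):
                pat = M[i] @ triad  # (2, n_terms), normalised coords
                jit = jrng.normal(size=(2, n_terms))
                jit[:, idx[(0, 0, 0)]] = 0.0
                if trivariate:
                    for k, (m, n, l) in enumerate(exps):
                        if l > 0:
                            jit[:, k] *= self.z_gradient
                for part in (pat, jit):
                    rms = float(
                        np.sqrt(np.mean(np.sum((B @ part.T) ** 2, axis=1)))
                    )
                    part /= max(rms, 1e-12)
                blend = (1.0 - jf) * pat + jf * jit
                rms = float(np.sqrt(np.mean(np.sum((B @ blend.T) ** 2, axis=1))))
                a = self.amplitudes[i] / max(rms, 1e-12)
                coeffs[i, 0] = to_pixel_units(a * blend[0])
                coeffs[i, 1] = to_pixel_units(a * blend[1])
            motion2d = MotionModel2D(D, Dz, coeffs)
            motion3d = None
        else:
            # truth kept in the sample frame; amplitude calibrated at the
            # image plane of the first acquired image
            proj0 = B @ (M[int(np.argmin(acq))] @ triad).T  # (Nm, 2)
            rms = max(float(np.sqrt(np.mean(np.sum(proj0**2, axis=1)))), 1e-12)
            coeffs3 = np.empty((N, 3, n_terms))
            for i in range(N):
                a = self.amplitudes[i] / rms
                for c in range(3):
                    coeffs3[i, c] = to_pixel_units(a * triad[c])
            motion3d = MotionModel3D(D, Dz, coeffs3)
            motion2d = convert_3d_to_2d(motion3d, self.geometry)

        self.truth = GroundTruth(
            markers=self.markers.copy(),
            geometry=self.geometry,
            motion2d=motion2d,
            motion3d=motion3d,
            amplitudes=self.amplitudes.copy(),
        )

    @property
    def n_images(self) -> int:
        return self.geometry.n_images


def make_scenario(config: dict | None = None, **kwargs) -> DomingScenario:
    """Build a :class:`DomingScenario` from a config mapping and/or kwargs."""
    params = dict(config or {})
    params.update(kwargs)
    return DomingScenario(**params)


def simulate_tracks(s: DomingScenario) -> tuple[MarkerTrackSet, GroundTruth]:
    """Simulate measured marker tracks: ``q = M r + S(r) + d + noise``.

    Gaussian localisation noise (``noise_sigma``) and optional visibility
    dropout use the scenario seed; repeated calls are identical.  Every
    marker is guaranteed to stay observed in at least 3 images.
    """
    truth = s.truth
    sol = truth.solution()
    from .alignment import predict_positions

    clean = predict_positions(sol)  # (Nm, N, 2)
    rng = s._rng(2)
    noisy = clean + rng.normal(0.0, s.noise_sigma, size=clean.shape)
    observed = np.ones(clean.shape[:2], dtype=bool)
    if s.dropout > 0:
        observed = rng.uniform(size=observed.shape) >= s.dropout
        thin = observed.sum(axis=1) < 3
        observed[thin] = True  # keep every marker usable
    tracks = MarkerTrackSet(noisy, observed)
    return tracks, truth


def _gaussian_splat(image: np.ndarray, u: float, v: float, sigma: float, amp: float):
    """Add an integrated 2D Gaussian blob at image coords (u, v), in place."""
    nrows, ncols = image.shape
    u0, v0 = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    ci, ri = u + u0, v + v0
    w = max(2, int(np.ceil(4 * sigma)))
    c_lo, c_hi = int(np.floor(ci)) - w, int(np.floor(ci)) + w + 1
    r_lo, r_hi = int(np.floor(ri)) - w, int(np.floor(ri)) + w + 1
    c_lo, c_hi = max(c_lo, 0), min(c_hi, ncols)
    r_lo, r_hi = max(r_lo, 0), min(r_hi, nrows)
    if c_lo >= c_hi or r_lo >= r_hi:
        return
    cc = np.arange(c_lo, c_hi) - ci
    rr = np.arange(r_lo, r_hi) - ri
    g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma**2))
    image[r_lo:r_hi, c_lo:c_hi] += amp * g


def render_stack(
    s: DomingScenario,
    content: str = "beads",
    image_size: int = 256,
    bead_sigma: float = 2.0,
    noise_sigma_image: float = 0.0,
) -> np.ndarray:
    """Render a dense tilt-series stack of a phantom deformed by the truth.

    ``content``:
      * ``beads`` — Gaussian blobs at the tracked positions of the
        scenario's markers (gold-fiducial analogue);
      * ``points`` — the same positions with a near-delta footprint;
      * ``two_spheres`` — two large blobs at fixed off-centre positions.

    Returns a float32 array of shape (n_images, image_size, image_size) in
    stack order, paired with the truth from :func:`simulate_tracks`.
    Deterministic for a fixed seed.
    """
    if image_size < 8 or image_size > 1024:
        raise ValueError("image_size out of the supported desk-scale range")
    if content == "beads":
        points, sigma = s.markers, bead_sigma
    elif content == "points":
        points, sigma = s.markers, 0.8
    elif content == "two_spheres":
        off = s.extent / 6.0
        points = np.array([[off, off / 2.0, 0.0], [-off, -off / 2.0, 0.0]])
        sigma = 2.0 * bead_sigma
    else:
        raise ValueError(f"unknown content {content!r}")

    from .recon import track_position

    sol = s.truth.solution()
    proj = track_position(points, sol)  # (N, n_points, 2)
    stack = np.zeros((s.n_images, image_size, image_size), dtype=float)
    for i in range(s.n_images):
        for p in range(points.shape[0]):
            _gaussian_splat(stack[i], proj[i, p, 0], proj[i, p, 1], sigma, 1.0)
    if noise_sigma_image > 0:
        rng = s._rng(3)
        stack += rng.normal(0.0, noise_sigma_image, size=stack.shape)
    return stack.astype(np.float32)
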