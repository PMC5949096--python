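"""Two-step motion-aware fiducial alignment.

Step 1 (``standard_align``) is the classical fiducial bundle adjustment:
marker 3D coordinates ``r_j``, per-image shifts ``d_i`` and optionally the
in-plane rotations, tilts and magnifications are fitted by nonlinear least
squares on

    f = sum_ji || q_ji - (M_i r_j + d_i) ||^2 .

Alternatively the step-1 parameters can be adopted from an external
alignment (``import_external_alignment``).

Step 2 (``fit_motion`` / ``fit_motion_3d``) freezes ``r_j``, ``M_i`` and
``d_i`` and fits, independently for each image, polynomial motion surfaces
to the step-1 residuals:

    q_ji = M_i r_j + S_i(r_j) + d_i            (2D image-plane form)
    q_ji = M_i (r_j + D_i(r_j)) + d_i          (3D sample-frame form)

With everything else frozen this is an exact linear least-squares problem
in the polynomial coefficients — convex and deterministic.  The 3D form is
rank-deficient (motion along the beam is invisible to the projection) and
is solved minimum-norm, which zeroes the beam-parallel component.

Gauge fixing: the marker centroid is pinned to the origin; the constant
terms of ``Su``/``Sv`` are degenerate with ``d_i`` and are masked to zero
by default; magnification is never refit in step 2 (the linear polynomial
terms absorb it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    Marker3D,
    TiltImageGeometry,
    TiltSeriesGeometry,
    projection_matrix,
    rotation_matrix,
)
from .motion import (
    MotionModel2D,
    MotionModel3D,
    apply_term_constraint,
    convert_3d_to_2d,
    count_coeffs,
    monomial_basis,
    per_image_param_count,
)

logger = logging.getLogger("domealign")

__all__ = [
    "MarkerTrackSet",
    "AlignmentSolution",
    "FitReport",
    "UnderdeterminedError",
    "predict_positions",
    "objective",
    "standard_align",
    "import_external_alignment",
    "solution_from_reference",
    "fit_motion",
    "fit_motion_3d",
    "residual_vs_acquisition",
    "measurements_to_unknowns_ratio",
]


class UnderdeterminedError(ValueError):
    """Raised when a fit has fewer measurements than free parameters."""


@dataclass
class MarkerTrackSet:
    """Measured fiducial positions ``q_ji`` across a tilt-series.

    ``positions`` has shape (n_markers, n_images, 2) in image-centre-origin
    pixels; ``observed`` is the boolean visibility mask (markers may be
    missing in some images).
    """

    positions: np.ndarray
    observed: np.ndarray
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_markers, n_images, 2)")
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.positions.shape[:2]:
            raise ValueError("observed mask must have shape (n_markers, n_images)")
        if not np.isfinite(self.positions[self.observed]).all():
            raise ValueError("observed positions must be finite")
        if self.marker_ids is None:
            width = max(2, len(str(self.n_markers - 1)))
            self.marker_ids = [f"m{j:0{width}d}" for j in range(self.n_markers)]
        if len(self.marker_ids) != self.n_markers:
            raise ValueError("marker_ids length must equal n_markers")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_images(self) -> int:
        return self.positions.shape[1]

    @property
    def n_observations(self) -> int:
        return int(self.observed.sum())

    def without_marker(self, j: int) -> "MarkerTrackSet":
        keep = np.arange(self.n_markers) != j
        return MarkerTrackSet(
            self.positions[keep],
            self.observed[keep],
            [mid for k, mid in enumerate(self.marker_ids) if keep[k]],
        )


@dataclass
class FitReport:
    n_iterations: int = 0
    converged: bool = True
    measurements_to_unknowns: float = np.nan
    message: str = ""


@dataclass
class AlignmentSolution:
    """Fitted markers, image parameters, optional motion model and residuals."""

    markers: np.ndarray  # (n_markers, 3) sample-frame pixels
    geometry: TiltSeriesGeometry
    motion: MotionModel2D | None = None
    motion3d: MotionModel3D | None = None
    residuals: np.ndarray | None = None  # (n_markers, n_images, 2)
    observed: np.ndarray | None = None
    mean_residual: float = np.nan
    fit_report: FitReport = field(default_factory=FitReport)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float).reshape(-1, 3)

    @property
    def n_markers(self) -> int:
        return self.markers.shape[0]

    def marker(self, j: int) -> Marker3D:
        return Marker3D(self.markers[j])

    def with_residuals(self, tracks: MarkerTrackSet) -> "AlignmentSolution":
        """Return a copy with residuals evaluated against ``tracks``."""
        pred = predict_positions(self)
        res = tracks.positions - pred
        res[~tracks.observed] = np.nan
        norms = np.linalg.norm(res[tracks.observed], axis=-1)
        return _dc_replace(
            self,
            residuals=res,
            observed=tracks.observed.copy(),
            mean_residual=float(norms.mean()) if norms.size else np.nan,
        )


def _projection_matrices(geom: TiltSeriesGeometry) -> np.ndarray:
    return np.stack([projection_matrix(g) for g in geom])


def predict_positions(sol: AlignmentSolution) -> np.ndarray:
    """Model positions ``p_ji = M_i r_j + S_i(r_j) + d_i`` for all (j, i).

    With no motion model this reduces to the standard projection model.
    Returns an (n_markers, n_images, 2) array.
    """
    M = _projection_matrices(sol.geometry)  # (N, 2, 3)
    d = sol.geometry.shifts()  # (N, 2)
    pred = np.einsum("nab,jb->jna", M, sol.markers) + d[None, :, :]
    if sol.motion is not None and not sol.motion.is_zero():
        B = monomial_basis(sol.motion.degree, sol.motion.z_degree, sol.markers)
        # (j, terms) x (N, 2, terms) -> (j, N, 2)
        pred += np.einsum("jt,nat->jna", B, sol.motion.coefficients)
    return pred


def objective(sol: AlignmentSolution, tracks: MarkerTrackSet) -> float:
    """Sum of squared residuals ``f`` over the observed (j, i), pixels^2."""
    if tracks.positions.shape[1] != sol.geometry.n_images:
        raise ValueError("tracks and solution image counts differ")
    if tracks.n_markers != sol.n_markers:
        raise ValueError("tracks and solution marker counts differ")
    diff = tracks.positions - predict_positions(sol)
    return float(np.sum(diff[tracks.observed] ** 2))


# ---------------------------------------------------------------------------
# step 1: standard alignment
# ---------------------------------------------------------------------------

_DEG = np.pi / 180.0


def _d_rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])


def _d_ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


def _ry_th(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _initial_markers(tracks: MarkerTrackSet, geom: TiltSeriesGeometry) -> np.ndarray:
    """Per-marker linear triangulation with d = 0 (good LM starting point)."""
    M = _projection_matrices(geom)
    r0 = np.zeros((tracks.n_markers, 3))
    for j in range(tracks.n_markers):
        idx = np.flatnonzero(tracks.observed[j])
        A = M[idx].reshape(-1, 3)
        b = tracks.positions[j, idx].reshape(-1)
        r0[j] = np.linalg.lstsq(A, b, rcond=None)[0]
    return r0


def standard_align(
    tracks: MarkerTrackSet,
    geom0: TiltSeriesGeometry,
    refine_rotation: bool = False,
    refine_tilt: bool = False,
    refine_magnification: bool = False,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> AlignmentSolution:
    """Fiducial bundle adjustment without motion (step 1).

    Solves for the marker coordinates and per-image shifts (plus any
    requested per-image parameters) by derivative-based nonlinear least
    squares with an analytic Jacobian.  Gauge: the marker centroid is moved
    to the origin after convergence (the equivalent shift is folded into
    ``d_i``); when rotations or magnifications are refined, the image
    nearest 0 deg keeps its input value to pin the global rotation/scale.
    """
    Nm, N = tracks.n_markers, tracks.n_images
    if N != geom0.n_images:
        raise ValueError("tracks and geometry image counts differ")
    n_obs = tracks.n_observations
    ref = int(np.argmin(np.abs(geom0.tilt_angles())))

    n_psi = (N - 1) if refine_rotation else 0
    n_th = N if refine_tilt else 0
    n_mag = (N - 1) if refine_magnification else 0
    n_unknowns = 3 * Nm + 2 * N + n_psi + n_th + n_mag
    # 3 translational gauge dimensions are removed post hoc
    if 2 * n_obs <= n_unknowns - 3:
        raise UnderdeterminedError(
            f"{2 * n_obs} measurements cannot determine {n_unknowns} unknowns "
            f"(deficit {n_unknowns - 3 - 2 * n_obs + 1} after gauge fixing)"
        )

    psi0 = np.array([g.inplane_rotation_deg for g in geom0]) * _DEG
    th0 = geom0.tilt_angles() * _DEG
    al0 = np.array([g.pretilt_deg for g in geom0]) * _DEG
    mag0 = np.array([g.magnification for g in geom0])

    free_psi = [i for i in range(N) if i != ref] if refine_rotation else []
    free_mag = [i for i in range(N) if i != ref] if refine_magnification else []

    obs_j, obs_i = np.nonzero(tracks.observed)
    q = tracks.positions[obs_j, obs_i]  # (n_obs, 2)

    def unpack(x):
        pos = 0
        r = x[pos : pos + 3 * Nm].reshape(Nm, 3)
        pos += 3 * Nm
        d = x[pos : pos + 2 * N].reshape(N, 2)
        pos += 2 * N
        psi = psi0.copy()
        if refine_rotation:
            psi[free_psi] = x[pos : pos + n_psi]
            pos += n_psi
        th = th0.copy()
        if refine_tilt:
            th = x[pos : pos + N]
            pos += N
        mag = mag0.copy()
        if refine_magnification:
            mag[free_mag] = x[pos : pos + n_mag]
            pos += n_mag
        return r, d, psi, th, mag

    P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    def matrices(psi, th):
        cz, sz = np.cos(psi), np.sin(psi)
        cy, sy = np.cos(th), np.sin(th)
        ca, sa = np.cos(al0), np.sin(al0)
        R = np.empty((N, 3, 3))
        for i in range(N):
            Rz = np.array([[cz[i], -sz[i], 0], [sz[i], cz[i], 0], [0, 0, 1.0]])
            Ry = np.array([[cy[i], 0, sy[i]], [0, 1.0, 0], [-sy[i], 0, cy[i]]])
            Rx = np.array([[1.0, 0, 0], [0, ca[i], -sa[i]], [0, sa[i], ca[i]]])
            R[i] = Rz @ Ry @ Rx
        return R

    def residual_fun(x):
        r, d, psi, th, mag = unpack(x)
        R = matrices(psi, th)
        M = mag[:, None, None] * (P @ R)
        pred = np.einsum("kab,kb->ka", M[obs_i], r[obs_j]) + d[obs_i]
        return (pred - q).reshape(-1)

    def jac_fun(x):
        r, d, psi, th, mag = unpack(x)
        R = matrices(psi, th)
        M = mag[:, None, None] * (P @ R)
        K = obs_j.size
        J = np.zeros((2 * K, x.size))
        rows = np.arange(K)
        # d(pred)/d r_j = M_i
        for a in range(2):
            for b in range(3):
                J[2 * rows + a, 3 * obs_j + b] = M[obs_i, a, b]
        # d(pred)/d d_i = I
        off_d = 3 * Nm
        for a in range(2):
            J[2 * rows + a, off_d + 2 * obs_i + a] = 1.0
        pos = off_d + 2 * N
        ca, sa = np.cos(al0), np.sin(al0)
        if refine_rotation:
            for col, i in enumerate(free_psi):
                Ry = _ry_th(th[i])
                Rx = np.array([[1.0, 0, 0], [0, ca[i], -sa[i]], [0, sa[i], ca[i]]])
                dM = mag[i] * (P @ (_d_rz(psi[i]) @ Ry @ Rx))
                sel = rows[obs_i == i]
                dp = r[obs_j[sel]] @ dM.T
                J[2 * sel, pos + col] = dp[:, 0]
                J[2 * sel + 1, pos + col] = dp[:, 1]
            pos += n_psi
        if refine_tilt:
            for i in range(N):
                Rz = np.array([[np.cos(psi[i]), -np.sin(psi[i]), 0],
                               [np.sin(psi[i]), np.cos(psi[i]), 0], [0, 0, 1.0]])
                Rx = np.array([[1.0, 0, 0], [0, ca[i], -sa[i]], [0, sa[i], ca[i]]])
                dM = mag[i] * (P @ (Rz @ _d_ry(th[i]) @ Rx))
                sel = rows[obs_i == i]
                dp = r[obs_j[sel]] @ dM.T
                J[2 * sel, pos + i] = dp[:, 0]
                J[2 * sel + 1, pos + i] = dp[:, 1]
            pos += N
        if refine_magnification:
            for col, i in enumerate(free_mag):
                dM = M[i] / mag[i]
                sel = rows[obs_i == i]
                dp = r[obs_j[sel]] @ dM.T
                J[2 * sel, pos + col] = dp[:, 0]
                J[2 * sel + 1, pos + col] = dp[:, 1]
            pos += n_mag
        return J

    # warm start: triangulate markers at d = 0, then set d to per-image means
    r_init = _initial_markers(tracks, geom0)
    M0 = _projection_matrices(geom0)
    d_init = np.zeros((N, 2))
    for i in range(N):
        jj = np.flatnonzero(tracks.observed[:, i])
        if jj.size:
            d_init[i] = np.mean(
                tracks.positions[jj, i] - r_init[jj] @ M0[i].T, axis=0
            )
    x0 = np.concatenate(
        [r_init.reshape(-1), d_init.reshape(-1)]
        + ([psi0[free_psi]] if refine_rotation else [])
        + ([th0] if refine_tilt else [])
        + ([mag0[free_mag]] if refine_magnification else [])
    )

    # LM needs at least as many residuals as variables; near critical
    # determinacy fall back to the trust-region reflective solver.
    method = "lm" if 2 * n_obs >= x0.size else "trf"
    result = least_squares(
        residual_fun,
        x0,
        jac=jac_fun,
        method=method,
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * max(1, x0.size // 10),
    )
    r, d, psi, th, mag = unpack(result.x)

    # translational gauge: pin the marker centroid at the origin
    centroid = r.mean(axis=0)
    r = r - centroid
    R_fin = matrices(psi, th)
    images = []
    for i, g in enumerate(geom0):
        Mi = mag[i] * (P @ R_fin[i])
        images.append(
            g.replace(
                tilt_angle_deg=th[i] / _DEG,
                inplane_rotation_deg=psi[i] / _DEG,
                magnification=mag[i],
                shift=d[i] + Mi @ centroid,
            )
        )
    geometry = TiltSeriesGeometry(images, geom0.tilt_axis_convention)

    ratio = 2 * n_obs / max(1, n_unknowns - 3)
    report = FitReport(
        n_iterations=result.nfev,
        converged=bool(result.status > 0),
        measurements_to_unknowns=ratio,
        message=result.message,
    )
    if not report.converged:
        logger.warning("standard_align did not converge: %s", result.message)
    sol = AlignmentSolution(r, geometry, fit_report=report)
    return sol.with_residuals(tracks)


def solution_from_reference(
    geom: TiltSeriesGeometry,
    markers: np.ndarray,
    tracks: MarkerTrackSet | None = None,
    motion: MotionModel2D | None = None,
) -> AlignmentSolution:
    """Build a step-1 solution from known (reference) parameters.

    Used when the alignment is adopted from an external program or from a
    simulation's ground truth rather than refit.
    """
    sol = AlignmentSolution(np.asarray(markers, dtype=float), geom, motion=motion)
    if tracks is not None:
        sol = sol.with_residuals(tracks)
    return sol


def import_external_alignment(
    tlt_path, xf_path, marker3d_table, tracks: MarkerTrackSet | None = None
) -> AlignmentSolution:
    """Adopt a step-1 solution from external ``.tlt``/``.xf`` files.

    ``marker3d_table`` is a text table of fitted 3D marker coordinates (see
    :func:`domealign.io.read_markers`).  No optimisation is run.
    """
    from . import io as dio

    tilt = dio.read_tlt(tlt_path)
    images = []
    if xf_path is not None:
        transforms = dio.read_xf(xf_path)
        if len(transforms) != len(tilt):
            raise ValueError(
                f".tlt has {len(tilt)} angles but .xf has {len(transforms)} lines"
            )
    else:
        transforms = [(0.0, 1.0, np.zeros(2))] * len(tilt)
    for i, (theta, (psi, mag, shift)) in enumerate(zip(tilt, transforms)):
        images.append(
            TiltImageGeometry(
                tilt_angle_deg=theta,
                inplane_rotation_deg=psi,
                magnification=mag,
                shift=shift,
                acquisition_index=i,
            )
        )
    markers = (
        dio.read_markers(marker3d_table)
        if not isinstance(marker3d_table, np.ndarray)
        else marker3d_table
    )
    return solution_from_reference(TiltSeriesGeometry(images), markers, tracks)


# ---------------------------------------------------------------------------
# step 2: per-image linear motion fitting
# ---------------------------------------------------------------------------

#: fallback ladder applied per image when measurements are scarce
_FALLBACKS = ("full", "pure_z_only", "pure_terms", "degree_1", "none")


def _fallback_ladder(D, Dz, mask_kind):
    """Yield (D, Dz, mask_kind) candidates of decreasing parameter count."""
    start = _FALLBACKS.index(mask_kind) if mask_kind in _FALLBACKS else 0
    for step in _FALLBACKS[start:]:
        if step == "degree_1":
            if D > 1:
                yield (1, min(Dz, 1) if Dz else 0, "full")
        elif step == "none":
            yield None
        else:
            yield (D, Dz, step)


def _enabled_mask(D, Dz, mask_kind, gauge_fix_constant):
    mask = apply_term_constraint(mask_kind, D, Dz)
    if gauge_fix_constant:
        mask = mask.copy()
        mask[0] = False  # constant term degenerate with d_i
    return mask


def fit_motion(
    sol1: AlignmentSolution,
    tracks: MarkerTrackSet,
    D: int = 2,
    Dz: int = 0,
    mask_kind: str = "full",
    gauge_fix_constant: bool = True,
    refit_shifts: bool = False,
) -> AlignmentSolution:
    """Fit the 2D image-plane motion polynomials to the step-1 residuals.

    Per image ``i`` this solves, holding ``r_j``, ``M_i`` and ``d_i``
    fixed, the linear least-squares problem

        q_ji - M_i r_j - d_i  ~  S_i(r_j)

    with the monomial design matrix evaluated at the fitted markers.  When
    an image has too few observations for the requested parameterisation a
    fallback ladder (full -> pure_z_only -> pure_terms -> degree 1 -> no
    motion) is applied for that image and logged.

    ``refit_shifts=True`` additionally refits ``d_i`` jointly with the
    coefficients per image (experimental; by default the constant terms are
    gauge-masked instead and ``d_i`` is kept).
    """
    Nm, N = tracks.n_markers, tracks.n_images
    if sol1.n_markers != Nm or sol1.geometry.n_images != N:
        raise ValueError("step-1 solution and tracks are dimensionally inconsistent")
    r = sol1.markers
    scale = max(1.0, float(np.max(np.abs(r)))) if r.size else 1.0
    r_n = r / scale

    M = _projection_matrices(sol1.geometry)
    d = sol1.geometry.shifts()
    base = np.einsum("nab,jb->jna", M, r) + d[None, :, :]
    target = tracks.positions - base  # step-1 residual vectors

    n_terms = count_coeffs(D, Dz)
    coeffs = np.zeros((N, 2, n_terms))
    new_shifts = d.copy()
    exps = None
    for i in range(N):
        jj = np.flatnonzero(tracks.observed[:, i])
        fitted = False
        for cand in _fallback_ladder(D, Dz, mask_kind):
            if cand is None:
                logger.warning(
                    "image %d: %d observations; motion set to zero", i, jj.size
                )
                fitted = True
                break
            Dc, Dzc, kindc = cand
            mask = _enabled_mask(Dc, Dzc, kindc, gauge_fix_constant)
            n_par = int(mask.sum()) + (1 if refit_shifts else 0)
            if jj.size < n_par or jj.size == 0:
                continue
            if (Dc, Dzc, kindc) != (D, Dz, mask_kind):
                logger.info(
                    "image %d: fallback to D=%d Dz=%d mask=%s (%d observations)",
                    i, Dc, Dzc, kindc, jj.size,
                )
            B = monomial_basis(Dc, Dzc, r_n[jj])[:, mask]
            if refit_shifts:
                B = np.hstack([B, np.ones((jj.size, 1))])
            for comp in range(2):
                c, *_ = np.linalg.lstsq(B, target[jj, i, comp], rcond=1e-10)
                if refit_shifts:
                    new_shifts[i, comp] = d[i, comp] + c[-1]
                    c = c[:-1]
                # rescale normalised-coordinate coefficients to pixel units
                full = np.zeros(count_coeffs(Dc, Dzc))
                full[mask] = c
                coeffs[i, comp] = _embed_coeffs(full, Dc, Dzc, D, Dz, scale)
            fitted = True
            break
        if not fitted:  # pragma: no cover - ladder always terminates
            raise AssertionError("fallback ladder exhausted")

    motion = MotionModel2D(D, Dz, coeffs)
    geometry = sol1.geometry
    if refit_shifts:
        geometry = TiltSeriesGeometry(
            [g.replace(shift=new_shifts[i]) for i, g in enumerate(sol1.geometry)],
            sol1.geometry.tilt_axis_convention,
        )
    sol = AlignmentSolution(
        r, geometry, motion=motion, fit_report=sol1.fit_report
    ).with_residuals(tracks)
    ratio, _ = measurements_to_unknowns_ratio(tracks, D, Dz, mask_kind)
    sol.fit_report = _dc_replace(sol1.fit_report, measurements_to_unknowns=ratio)
    return sol


def _embed_coeffs(full, Dc, Dzc, D, Dz, scale):
    """Rescale from normalised coordinates and embed a (possibly lower-degree)
    coefficient vector into the (D, Dz) coefficient layout."""
    from .motion import monomial_exponents

    out = np.zeros(count_coeffs(D, Dz))
    idx = {e: k for k, e in enumerate(monomial_exponents(D, Dz))}
    for k, (m, n, l) in enumerate(monomial_exponents(Dc, Dzc)):
        out[idx[(m, n, l)]] = full[k] / scale ** (m + n + l)
    return out


def fit_motion_3d(
    sol1: AlignmentSolution,
    tracks: MarkerTrackSet,
    D: int = 2,
    Dz: int = 0,
    mask_kind: str = "full",
    gauge_fix_constant: bool = True,
) -> AlignmentSolution:
    """Fit the 3D sample-frame motion triad per image (minimum norm).

    The projection makes the beam-parallel combination of the triad
    coefficients unobservable; the minimum-norm least-squares solution
    leaves it at zero, so the fitted per-point 3D shifts are perpendicular
    to the beam and the residuals equal those of :func:`fit_motion`.
    """
    Nm, N = tracks.n_markers, tracks.n_images
    if sol1.n_markers != Nm or sol1.geometry.n_images != N:
        raise ValueError("step-1 solution and tracks are dimensionally inconsistent")
    r = sol1.markers
    scale = max(1.0, float(np.max(np.abs(r)))) if r.size else 1.0
    r_n = r / scale

    M = _projection_matrices(sol1.geometry)
    d = sol1.geometry.shifts()
    base = np.einsum("nab,jb->jna", M, r) + d[None, :, :]
    target = tracks.positions - base

    n_terms = count_coeffs(D, Dz)
    coeffs = np.zeros((N, 3, n_terms))
    for i in range(N):
        jj = np.flatnonzero(tracks.observed[:, i])
        for cand in _fallback_ladder(D, Dz, mask_kind):
            if cand is None:
                logger.warning(
                    "image %d: %d observations; 3D motion set to zero", i, jj.size
                )
                break
            Dc, Dzc, kindc = cand
            mask = _enabled_mask(Dc, Dzc, kindc, gauge_fix_constant)
            p = int(mask.sum())
            if jj.size < p or jj.size == 0:
                continue
            B = monomial_basis(Dc, Dzc, r_n[jj])[:, mask]  # (nobs, p)
            # rows: 2 per observation; unknowns: 3 per enabled term
            A = np.einsum("kp,ab->kapb", B, M[i]).reshape(2 * jj.size, 3 * p)
            y = target[jj, i].reshape(-1)
            c, *_ = np.linalg.lstsq(A, y, rcond=1e-10)  # minimum-norm via SVD
            c = c.reshape(p, 3).T  # (3, p)
            for comp in range(3):
                full = np.zeros(count_coeffs(Dc, Dzc))
                full[mask] = c[comp]
                coeffs[i, comp] = _embed_coeffs(full, Dc, Dzc, D, Dz, scale)
            break

    motion3 = MotionModel3D(D, Dz, coeffs)
    motion2 = convert_3d_to_2d(motion3, sol1.geometry)
    sol = AlignmentSolution(
        r, sol1.geometry, motion=motion2, motion3d=motion3,
        fit_report=sol1.fit_report,
    ).with_residuals(tracks)
    ratio, _ = measurements_to_unknowns_ratio(tracks, D, Dz, mask_kind)
    sol.fit_report = _dc_replace(sol1.fit_report, measurements_to_unknowns=ratio)
    return sol


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def residual_vs_acquisition(sol: AlignmentSolution) -> np.ndarray:
    """Mean residual per acquisition index (the dose-ordered residual curve).

    Returns an (n_images, 2) array of (acquisition_index, mean residual in
    pixels), sorted by acquisition index.  Requires the solution to carry
    residuals (``with_residuals``).
    """
    if sol.residuals is None or sol.observed is None:
        raise ValueError("solution has no residuals; call with_residuals first")
    acq = np.array([g.acquisition_index for g in sol.geometry])
    out = []
    for i in np.argsort(acq):
        jj = np.flatnonzero(sol.observed[:, i])
        if jj.size == 0:
            continue
        norms = np.linalg.norm(sol.residuals[jj, i], axis=-1)
        out.append((acq[i], float(norms.mean())))
    return np.array(out)


def measurements_to_unknowns_ratio(
    tracks: MarkerTrackSet,
    D: int = 2,
    Dz: int = 0,
    mask_kind: str = "full",
    form: str = "2D",
) -> tuple[float, np.ndarray]:
    """Per-image ratio 2*(observations) / (enabled motion parameters).

    Returns ``(series_average, per_image_array)``; images with zero enabled
    parameters report ``inf``.
    """
    mask = apply_term_constraint(mask_kind, D, Dz)
    n_par = per_image_param_count(form, D, Dz, mask)
    counts = tracks.observed.sum(axis=0)  # per image
    with np.errstate(divide="ignore"):
        per_image = np.where(n_par > 0, 2.0 * counts / max(n_par, 1), np.inf)
    if n_par == 0:
        per_image = np.full(tracks.n_images, np.inf)
    avg = float(np.mean(per_image)) if np.isfinite(per_image).all() else np.inf
    return avg, per_image
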