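"""Polynomial surfaces modelling beam-induced sample motion.

The sample deformation at the acquisition of image ``i`` is modelled by
homogeneous polynomial surfaces

    P(x, y, z) = sum_{l=0}^{Dz} sum_{m+n <= D-l} P_mnl x^m y^n z^l

either as a triad ``(dx_i, dy_i, dz_i)`` of 3D shifts in the sample frame,
or as a pair ``(Su_i, Sv_i)`` of 2D shifts at the image plane.  The two
forms are related through the projection matrix:

    S_i(x, y, z) = M_i D_i(x, y, z)

coefficient-wise ``(Su_mnl, Sv_mnl)^T = M_i (dx_mnl, dy_mnl, dz_mnl)^T``.

Only the bivariate (``Dz = 0``, no z-dependence — thin samples) and
trivariate (``Dz = D`` — motion varying across the thickness) families are
supported; each surface then has exactly ``(Dz+3)(D+2)(D+1)/6``
coefficients.  Quadratic surfaces (``D = 2``) suffice to describe doming.

Coefficient ordering is pinned as: z-power ``l`` outer, then total
xy-degree, then lexicographic ``(m, n)``.  For the bivariate quadratic this
reads ``P00, P10, P01, P20, P11, P02``.

Fitting routines normalise coordinates (divide by the largest absolute
fiducial coordinate) before building design matrices — quadratic monomials
of raw coordinates in the thousands of pixels are numerically hostile —
and rescale the coefficients back to pixel units afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TiltSeriesGeometry, projection_matrix

__all__ = [
    "count_coeffs",
    "monomial_exponents",
    "monomial_basis",
    "apply_term_constraint",
    "per_image_param_count",
    "total_param_count",
    "PolynomialSurface",
    "eval_surface",
    "MotionModel2D",
    "MotionModel3D",
    "convert_3d_to_2d",
    "zero_motion",
    "MASK_KINDS",
]

MASK_KINDS = ("full", "pure_terms", "pure_z_only")


def _check_degrees(D: int, Dz: int) -> None:
    if D < 0 or Dz < 0:
        raise ValueError(f"polynomial degrees must be non-negative, got D={D}, Dz={Dz}")
    if Dz not in (0, D):
        raise ValueError(
            f"only bivariate (Dz=0) and trivariate (Dz=D) surfaces are supported, "
            f"got D={D}, Dz={Dz}"
        )


def count_coeffs(D: int, Dz: int) -> int:
    """Number of coefficients of one surface: ``(Dz+3)(D+2)(D+1)/6``."""
    _check_degrees(D, Dz)
    num = (Dz + 3) * (D + 2) * (D + 1)
    assert num % 6 == 0
    return num // 6


def monomial_exponents(D: int, Dz: int) -> list[tuple[int, int, int]]:
    """Exponent triples ``(m, n, l)`` with ``l <= Dz`` and ``m + n <= D - l``,
    in the pinned coefficient order."""
    _check_degrees(D, Dz)
    out: list[tuple[int, int, int]] = []
    for l in range(Dz + 1):
        for t in range(D - l + 1):  # total xy-degree
            for m in range(t, -1, -1):  # x-power high to low: P10 before P01
                out.append((m, t - m, l))
    assert len(out) == count_coeffs(D, Dz)
    return out


def monomial_basis(D: int, Dz: int, points) -> np.ndarray:
    """Design matrix of monomials at ``points`` (n_points x n_terms).

    Column order matches the coefficient order, so
    ``basis @ coefficients == eval_surface`` at the same points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    exps = monomial_exponents(D, Dz)
    cols = [
        pts[:, 0] ** m * pts[:, 1] ** n * pts[:, 2] ** l for (m, n, l) in exps
    ]
    return np.stack(cols, axis=1)


def apply_term_constraint(mask_kind: str, D: int, Dz: int) -> np.ndarray:
    """Boolean term mask implementing the parameter-reduction strategies.

    ``full``        — all terms enabled;
    ``pure_terms``  — only pure terms ``P_m00``, ``P_0n0``, ``P_00l``
                      (mixed terms removed);
    ``pure_z_only`` — pure terms only in z: ``P_mn0`` and ``P_00l``.
    """
    exps = monomial_exponents(D, Dz)
    if mask_kind == "full":
        return np.ones(len(exps), dtype=bool)
    if mask_kind == "pure_terms":
        return np.array(
            [(n == 0 and l == 0) or (m == 0 and l == 0) or (m == 0 and n == 0)
             for (m, n, l) in exps]
        )
    if mask_kind == "pure_z_only":
        return np.array(
            [l == 0 or (m == 0 and n == 0) for (m, n, l) in exps]
        )
    raise ValueError(f"unknown mask kind {mask_kind!r}; expected one of {MASK_KINDS}")


def per_image_param_count(model_form: str, D: int, Dz: int, term_mask=None) -> int:
    """Free motion parameters per tilt image.

    Three surfaces for the 3D sample-frame form, two for the 2D image-plane
    form; 18/30 for bi/trivariate quadratics in 3D, 12/20 in 2D.
    """
    if model_form not in ("3D", "2D", "3d", "2d"):
        raise ValueError(f"model_form must be '2D' or '3D', got {model_form!r}")
    n_surf = 3 if model_form.upper() == "3D" else 2
    if term_mask is None:
        n_terms = count_coeffs(D, Dz)
    else:
        term_mask = np.asarray(term_mask, dtype=bool)
        if term_mask.size != count_coeffs(D, Dz):
            raise ValueError("term_mask length does not match coefficient count")
        n_terms = int(term_mask.sum())
    return n_surf * n_terms


def total_param_count(N: int, D: int, Dz: int) -> int:
    """Total 2D-form motion parameters over a series: ``N (Dz+3)(D+2)(D+1)/3``."""
    if N < 0:
        raise ValueError("N must be non-negative")
    if N == 0:
        return 0
    return N * 2 * count_coeffs(D, Dz)


@dataclass
class PolynomialSurface:
    """One polynomial shift surface with its coefficient vector (pixels)."""

    degree: int
    z_degree: int
    coefficients: np.ndarray
    term_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = count_coeffs(self.degree, self.z_degree)
        self.coefficients = np.array(self.coefficients, dtype=float).reshape(n)
        if self.term_mask is None:
            self.term_mask = np.ones(n, dtype=bool)
        else:
            self.term_mask = np.array(self.term_mask, dtype=bool).reshape(n)
        if np.any(self.coefficients[~self.term_mask] != 0.0):
            raise ValueError("masked-out coefficients must be zero")

    def __call__(self, points) -> np.ndarray:
        return eval_surface(self, points)


def eval_surface(s: PolynomialSurface, points) -> np.ndarray:
    """Evaluate a surface at one (3,) point or an (n, 3) array of points.

    Bivariate surfaces ignore the z coordinate by construction (no z terms).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    B = monomial_basis(s.degree, s.z_degree, np.atleast_2d(pts))
    vals = B @ s.coefficients
    return float(vals[0]) if single else vals


class _MotionModelBase:
    """Shared behaviour of the 2D and 3D per-image motion models."""

    n_components: int  # 2 or 3

    def __init__(self, degree: int, z_degree: int, coefficients, term_mask=None):
        n_terms = count_coeffs(degree, z_degree)
        coefficients = np.array(coefficients, dtype=float)
        if coefficients.ndim != 3 or coefficients.shape[1:] != (
            self.n_components,
            n_terms,
        ):
            raise ValueError(
                f"coefficients must have shape (N, {self.n_components}, {n_terms})"
            )
        self.degree = int(degree)
        self.z_degree = int(z_degree)
        self.coefficients = coefficients
        if term_mask is None:
            term_mask = np.ones(n_terms, dtype=bool)
        self.term_mask = np.asarray(term_mask, dtype=bool).reshape(n_terms)
        self.coefficients[:, :, ~self.term_mask] = 0.0

    @property
    def n_images(self) -> int:
        return self.coefficients.shape[0]

    def surface(self, image: int, component: int) -> PolynomialSurface:
        return PolynomialSurface(
            self.degree,
            self.z_degree,
            self.coefficients[image, component],
            self.term_mask,
        )

    def eval(self, image: int, points) -> np.ndarray:
        """Shift vectors at ``points`` for one image: (n, n_components)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        B = monomial_basis(self.degree, self.z_degree, pts)
        return B @ self.coefficients[image].T

    def is_zero(self) -> bool:
        return not np.any(self.coefficients)


class MotionModel2D(_MotionModelBase):
    """Per-image pair ``(Su_i, Sv_i)``: 2D motion at the projection-image level.

    ``coefficients`` has shape (N, 2, n_terms); component 0 is ``Su``,
    component 1 is ``Sv``.
    """

    n_components = 2
    form = "2D"


class MotionModel3D(_MotionModelBase):
    """Per-image triad ``(dx_i, dy_i, dz_i)``: 3D motion in the sample frame."""

    n_components = 3
    form = "3D"


def convert_3d_to_2d(m3: MotionModel3D, geom: TiltSeriesGeometry) -> MotionModel2D:
    """Project a 3D motion model to the equivalent 2D image-plane model.

    Applies ``M_i`` to each coefficient triple, so the result satisfies
    ``S_i(p) = M_i D_i(p)`` at every point.
    """
    if m3.n_images != geom.n_images:
        raise ValueError(
            f"motion model has {m3.n_images} images but geometry has {geom.n_images}"
        )
    coeffs2 = np.empty((m3.n_images, 2, m3.coefficients.shape[2]))
    for i, g in enumerate(geom):
        coeffs2[i] = projection_matrix(g) @ m3.coefficients[i]
    return MotionModel2D(m3.degree, m3.z_degree, coeffs2, m3.term_mask)


def zero_motion(
    n_images: int, D: int = 2, Dz: int = 0, form: str = "2D"
) -> MotionModel2D | MotionModel3D:
    """All-zero motion model (useful as a degenerate baseline)."""
    cls = MotionModel3D if form.upper() == "3D" else MotionModel2D
    return cls(D, Dz, np.zeros((n_images, cls.n_components, count_coeffs(D, Dz))))
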