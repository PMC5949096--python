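"""Single-tilt-axis projection geometry for cryo-ET tilt-series.

Coordinate conventions
----------------------
Three right-handed frames are involved:

* **microscope frame** — Z runs along the electron beam, Y along the tilt
  axis;
* **sample frame** — coincides with the microscope frame at zero tilt;
  its origin sits at the centroid of the fitted fiducial markers;
* **image frame** — ``u`` rightward, ``v`` upward, origin at the image
  centre, units of pixels.  When converting to array indices the centre
  maps to ``(size - 1) / 2`` with 0-based indexing.

A tilt image is described by the Euler angles (tilt ``theta`` about Y,
in-plane rotation ``psi`` about Z, optional pretilt ``alpha`` about X), an
isotropic magnification ``m`` and a 2D shift ``d``.  The projection of a
sample point ``r`` onto image ``i`` is

    p = M_i r + d_i,      M_i = m_i P R_i,    R_i = Rz(psi) Ry(theta) Rx(alpha)

where ``P`` drops the microscope Z coordinate.  ``psi`` acts after the
projection, hence it is the outermost rotation.  The sign convention is
pinned so that positive ``theta`` rotates +X toward -Z (``Ry(90°)`` maps
``(1,0,0)`` to ``(0,0,-1)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TiltImageGeometry",
    "TiltSeriesGeometry",
    "Marker3D",
    "rotation_matrix",
    "projection_matrix",
    "project_marker",
    "beam_direction",
]

#: metadata string recorded on every TiltSeriesGeometry
TILT_AXIS_CONVENTION = "single-axis:Y;euler:Rz(psi)Ry(theta)Rx(alpha);+theta:+X->-Z"


@dataclass
class TiltImageGeometry:
    """Acquisition parameters of one image in a tilt-series.

    Parameters
    ----------
    tilt_angle_deg : float
        Tilt ``theta`` about the microscope Y-axis, degrees, in [-90, 90].
    inplane_rotation_deg : float
        In-plane rotation ``psi`` about the microscope Z-axis, degrees.
    pretilt_deg : float
        Optional initial tilt ``alpha`` about the microscope X-axis, degrees.
    magnification : float
        Isotropic scale ``m`` (> 0, dimensionless).
    shift : (2,) array_like
        Image shift ``d = (du, dv)`` in pixels.
    acquisition_index : int
        Order in which the image was recorded (dose bookkeeping).
    branch_id : int
        Which of the two acquisition branches the image belongs to.
    """

    tilt_angle_deg: float
    inplane_rotation_deg: float = 0.0
    pretilt_deg: float = 0.0
    magnification: float = 1.0
    shift: np.ndarray = field(default_factory=lambda: np.zeros(2))
    acquisition_index: int = 0
    branch_id: int = 0

    def __post_init__(self) -> None:
        self.shift = np.array(self.shift, dtype=float).reshape(2)
        if not np.isfinite(self.shift).all():
            raise ValueError("shift must be finite")
        if not self.magnification > 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")
        if not -90.0 <= self.tilt_angle_deg <= 90.0:
            raise ValueError(
                f"tilt angle must lie in [-90, 90] deg, got {self.tilt_angle_deg}"
            )

    def replace(self, **changes) -> "TiltImageGeometry":
        return replace(self, **changes)


@dataclass
class TiltSeriesGeometry:
    """Ordered list of per-image geometries (storage order = stack order)."""

    images: list[TiltImageGeometry]
    tilt_axis_convention: str = TILT_AXIS_CONVENTION

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a tilt-series needs at least one image")
        acq = [g.acquisition_index for g in self.images]
        if len(set(acq)) != len(acq):
            raise ValueError("acquisition_index must be unique within a tilt-series")

    @property
    def n_images(self) -> int:
        return len(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    def __getitem__(self, i: int) -> TiltImageGeometry:
        return self.images[i]

    def tilt_angles(self) -> np.ndarray:
        return np.array([g.tilt_angle_deg for g in self.images])

    def shifts(self) -> np.ndarray:
        return np.array([g.shift for g in self.images])

    def acquisition_order(self) -> np.ndarray:
        """Stack indices sorted by acquisition_index."""
        return np.argsort([g.acquisition_index for g in self.images])


@dataclass
class Marker3D:
    """3D fiducial coordinates ``r = (x, y, z)`` in sample-frame pixels."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.array(self.coords, dtype=float).reshape(3)
        if not np.isfinite(self.coords).all():
            raise ValueError("marker coordinates must be finite")


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(g: TiltImageGeometry) -> np.ndarray:
    """Orthonormal rotation ``R = Rz(psi) Ry(theta) Rx(alpha)``, det +1."""
    return (
        _rz(np.deg2rad(g.inplane_rotation_deg))
        @ _ry(np.deg2rad(g.tilt_angle_deg))
        @ _rx(np.deg2rad(g.pretilt_deg))
    )


# projection along the microscope Z-axis: drop the Z row
_P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def projection_matrix(g: TiltImageGeometry) -> np.ndarray:
    """2x3 overall projection matrix ``M = m P R``."""
    return g.magnification * (_P @ rotation_matrix(g))


def project_marker(g: TiltImageGeometry, r) -> np.ndarray:
    """Project sample point(s) ``r`` onto image ``g``: ``p = M r + d``.

    ``r`` may be a :class:`Marker3D`, a (3,) point or an (n, 3) array;
    the result has the matching shape (2,) or (n, 2).
    """
    if isinstance(r, Marker3D):
        r = r.coords
    r = np.asarray(r, dtype=float)
    M = projection_matrix(g)
    return r @ M.T + g.shift


def beam_direction(g: TiltImageGeometry) -> np.ndarray:
    """Unit electron-beam direction expressed in the sample frame.

    This is ``R^T z-hat``; displacements along it are invisible to the
    projection (``M @ beam_direction == 0``).
    """
    return rotation_matrix(g).T @ np.array([0.0, 0.0, 1.0])
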