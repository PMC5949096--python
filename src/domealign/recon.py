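"""Motion-compensated weighted backprojection (WBP) and position tracking.

Any point ``x`` of the tomogram is tracked through the tilt-series with
the motion-aware projection model

    p_i(x) = M_i x + S_i(x) + d_i

which lets the reconstruction work directly on the *unaligned* stack (the
alignment transform is folded into the mapping, avoiding an intermediate
interpolation pass).  Images are ramp-filtered along the detector rows
(perpendicular to the tilt axis for ``psi = 0``) before backprojection —
the conventional WBP order — with optional Hamming apodisation.  Because
the motion shifts vary across the sample, a voxel's projection is sampled
bilinearly from the full 2D image rather than from a single detector line.

Each voxel is normalised by the number of images that actually contributed
(tracked positions falling outside an image contribute nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .alignment import AlignmentSolution
from .geometry import projection_matrix
from .motion import monomial_basis

__all__ = [
    "Volume",
    "Subtiltseries",
    "track_position",
    "ramp_filter",
    "reconstruct_wbp",
    "extract_subtiltseries",
]


@dataclass
class Volume:
    """Reconstructed intensities, shape (nx, ny, nz), centre at the origin."""

    data: np.ndarray
    voxel_size: float = 1.0  # Angstrom, metadata only

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Subtiltseries:
    """Per-tilt patches around one tracked 3D position.

    ``patches[i]`` is None when the projected centre falls outside image
    ``i``; ``centers[i]`` is the exact (u, v) projection of ``centre`` and
    ``offsets[i]`` the sub-pixel remainder after the integer crop.
    """

    centre: np.ndarray
    patch_px: int
    patches: list[np.ndarray | None]
    centers: np.ndarray  # (N, 2) exact projections
    offsets: np.ndarray  # (N, 2) sub-pixel offsets
    present: np.ndarray  # (N,) bool


def track_position(x, sol: AlignmentSolution) -> np.ndarray:
    """Project point(s) ``x`` into every tilt image: ``M_i x + S_i(x) + d_i``.

    ``x`` may be (3,) or (n, 3); returns (N, 2) or (N, n, 2).  Without a
    motion model this is the standard projection.
    """
    pts = np.asarray(x, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    N = sol.geometry.n_images
    out = np.empty((N, pts.shape[0], 2))
    M = np.stack([projection_matrix(g) for g in sol.geometry])
    d = sol.geometry.shifts()
    out = np.einsum("nab,kb->nka", M, pts) + d[:, None, :]
    if sol.motion is not None and not sol.motion.is_zero():
        B = monomial_basis(sol.motion.degree, sol.motion.z_degree, pts)
        out += np.einsum("kt,nat->nka", B, sol.motion.coefficients)
    return out[:, 0, :] if single else out


def ramp_filter(lines: np.ndarray, apodisation: str = "none") -> np.ndarray:
    """Ramp-filter 1D lines along the last axis (frequency-domain |w|).

    The weight is ``2 |f|`` with ``f`` in cycles/sample, so DC maps to zero
    and the Nyquist weight is 1.  ``apodisation='hamming'`` additionally
    multiplies a Hamming window over frequency.  Linear operator.
    """
    lines = np.asarray(lines, dtype=float)
    n = lines.shape[-1]
    if n < 2:
        raise ValueError("line length must be >= 2")
    freqs = np.fft.rfftfreq(n)
    weights = 2.0 * np.abs(freqs)
    if apodisation == "hamming":
        weights = weights * (0.54 + 0.46 * np.cos(np.pi * freqs / freqs[-1]))
    elif apodisation != "none":
        raise ValueError(f"unknown apodisation {apodisation!r}")
    return np.fft.irfft(np.fft.rfft(lines, axis=-1) * weights, n=n, axis=-1)


def _voxel_grid(shape):
    nx, ny, nz = shape
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    z = np.arange(nz) - (nz - 1) / 2.0
    return x, y, z


def reconstruct_wbp(
    stack: np.ndarray,
    sol: AlignmentSolution,
    shape: tuple[int, int, int],
    use_motion: bool = True,
    apodisation: str = "none",
    apply_filter: bool = True,
    voxel_size: float = 1.0,
    chunk_voxels: int = 2_000_000,
) -> Volume:
    """Weighted backprojection of a (possibly unaligned) tilt-series stack.

    Parameters
    ----------
    stack : (N, rows, cols) array
        Tilt images in stack (storage) order matching ``sol.geometry``.
    sol : AlignmentSolution
        Geometry (+ optional motion model) used to map voxels to images.
    shape : (nx, ny, nz)
        Output volume size in voxels (1 voxel = 1 pixel), centred on the
        sample-frame origin.
    use_motion : bool
        Apply the motion model during voxel tracking; with ``False`` (or a
        zero model) this is standard WBP.

    Voxels are accumulated by bilinear sampling of each filtered image at
    the tracked position and normalised by the number of contributing
    images.  Deterministic.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_images, rows, cols)")
    N = sol.geometry.n_images
    if stack.shape[0] != N:
        raise ValueError(
            f"stack has {stack.shape[0]} images but geometry has {N}"
        )
    nrows, ncols = stack.shape[1:]
    if apply_filter:
        stack = ramp_filter(stack, apodisation=apodisation)

    nx, ny, nz = shape
    if min(shape) < 1:
        raise ValueError("volume shape must be positive")
    xg, yg, zg = _voxel_grid(shape)
    X, Y, Z = np.meshgrid(xg, yg, zg, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)  # (nvox, 3)

    M = np.stack([projection_matrix(g) for g in sol.geometry])
    d = sol.geometry.shifts()
    motion = sol.motion if (use_motion and sol.motion is not None) else None

    acc = np.zeros(coords.shape[0])
    cnt = np.zeros(coords.shape[0])
    u0, v0 = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    for start in range(0, coords.shape[0], chunk_voxels):
        blk = coords[start : start + chunk_voxels]
        S = None
        if motion is not None:
            B = monomial_basis(motion.degree, motion.z_degree, blk)
        for i in range(N):
            p = blk @ M[i].T + d[i]
            if motion is not None:
                p = p + B @ motion.coefficients[i].T
            col = p[:, 0] + u0
            row = p[:, 1] + v0
            inside = (col >= 0) & (col <= ncols - 1) & (row >= 0) & (row <= nrows - 1)
            vals = map_coordinates(
                stack[i], [row, col], order=1, mode="constant", cval=0.0
            )
            acc[start : start + blk.shape[0]] += np.where(inside, vals, 0.0)
            cnt[start : start + blk.shape[0]] += inside
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return Volume(out.reshape(shape).astype(np.float32), voxel_size=voxel_size)


def extract_subtiltseries(
    stack: np.ndarray,
    sol: AlignmentSolution,
    centre,
    patch_px: int,
) -> Subtiltseries:
    """Crop per-tilt patches around the tracked projections of ``centre``.

    The crop is centred on the rounded projection; the sub-pixel remainder
    is recorded in ``offsets``.  Images where the projection (or the full
    patch) falls outside the bounds are flagged absent.
    """
    stack = np.asarray(stack, dtype=float)
    centre = np.asarray(centre, dtype=float).reshape(3)
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    N = sol.geometry.n_images
    if stack.shape[0] != N:
        raise ValueError("stack/geometry image count mismatch")
    nrows, ncols = stack.shape[1:]
    u0, v0 = (ncols - 1) / 2.0, (nrows - 1) / 2.0
    half = (patch_px - 1) // 2

    proj = track_position(centre, sol)  # (N, 2)
    patches: list[np.ndarray | None] = []
    offsets = np.zeros((N, 2))
    present = np.zeros(N, dtype=bool)
    for i in range(N):
        ci = int(round(proj[i, 0] + u0))
        ri = int(round(proj[i, 1] + v0))
        offsets[i] = (proj[i, 0] + u0 - ci, proj[i, 1] + v0 - ri)
        if (
            ri - half < 0
            or ci - half < 0
            or ri - half + patch_px > nrows
            or ci - half + patch_px > ncols
        ):
            patches.append(None)
            continue
        patches.append(
            stack[i, ri - half : ri - half + patch_px, ci - half : ci - half + patch_px].copy()
        )
        present[i] = True
    return Subtiltseries(
        centre=centre,
        patch_px=patch_px,
        patches=patches,
        centers=proj,
        offsets=offsets,
        present=present,
    )
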