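"""Readers and writers for the on-disk formats.

Plain-text, versioned formats are used for everything that carries
alignment information (marker tracks, motion models, alignment solutions,
reports) so that runs are diff-able and every output parses back through
the package's own readers.  Image data uses the MRC2014 format (modes
0/1/2/6 read, mode-2 float written).

IMOD interoperability is at the text-file level: ``.tlt`` (one tilt angle
in degrees per line, stack order), ``.xf`` (six numbers per line: 2x2
matrix row-major then two shifts) and ``model2point``-style marker tables.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .alignment import AlignmentSolution, FitReport, MarkerTrackSet
from .geometry import TiltImageGeometry, TiltSeriesGeometry
from .motion import MotionModel2D, MotionModel3D, count_coeffs
from .recon import Volume

__all__ = [
    "ParseError",
    "read_tlt", "write_tlt",
    "read_xf", "write_xf",
    "read_tracks", "write_tracks",
    "read_markers", "write_markers",
    "read_motion", "write_motion",
    "read_alignment", "write_alignment",
    "write_report",
    "read_mrc", "write_mrc",
]


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# -- .tlt / .xf -------------------------------------------------------------


def read_tlt(path, negate: bool = False) -> np.ndarray:
    """Tilt angles in degrees, one per line, stack order.

    ``negate=True`` flips the sign on import (the sign of theta relative to
    the stored stack is a convention choice some packages invert).
    """
    angles = []
    for lineno, line in _data_lines(path):
        try:
            angles.append(float(line.split()[0]))
        except ValueError:
            raise ParseError(path, lineno, f"not a tilt angle: {line!r}") from None
    out = np.array(angles)
    return -out if negate else out


def write_tlt(path, angles) -> None:
    Path(path).write_text("".join(f"{a:10.3f}\n" for a in np.asarray(angles)))


def read_xf(path) -> list[tuple[float, float, np.ndarray]]:
    """Per-image in-plane transforms: list of (psi_deg, magnification, shift).

    Each line holds A11 A12 A21 A22 DX DY (IMOD convention); the rotation
    and isotropic scale are taken from the polar part of A.
    """
    out = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 6:
            raise ParseError(path, lineno, f"expected 6 numbers, got {len(parts)}")
        try:
            a11, a12, a21, a22, dx, dy = (float(p) for p in parts)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric field in {line!r}") from None
        det = a11 * a22 - a12 * a21
        if det <= 0:
            raise ParseError(path, lineno, "transform must preserve orientation")
        mag = float(np.sqrt(det))
        psi = float(np.degrees(np.arctan2(a21, a11)))
        out.append((psi, mag, np.array([dx, dy])))
    return out


def write_xf(path, geom: TiltSeriesGeometry) -> None:
    lines = []
    for g in geom:
        a = np.radians(g.inplane_rotation_deg)
        m = g.magnification
        lines.append(
            f"{m * np.cos(a):18.12f}{-m * np.sin(a):18.12f}"
            f"{m * np.sin(a):18.12f}{m * np.cos(a):18.12f}"
            f"{g.shift[0]:16.6f}{g.shift[1]:16.6f}\n"
        )
    Path(path).write_text("".join(lines))


# -- marker tracks ----------------------------------------------------------

TRACKS_HEADER = "# domealign marker tracks v1"


def write_tracks(path, tracks: MarkerTrackSet) -> None:
    lines = [TRACKS_HEADER + "\n", "# columns: marker_id image_index u v\n"]
    for j in range(tracks.n_markers):
        for i in range(tracks.n_images):
            if tracks.observed[j, i]:
                u, v = tracks.positions[j, i]
                lines.append(f"{tracks.marker_ids[j]} {i} {u:.6f} {v:.6f}\n")
    Path(path).write_text("".join(lines))


def read_tracks(path, n_images: int | None = None, min_images: int = 3,
                image_shape: tuple[int, int] | None = None) -> MarkerTrackSet:
    """Load a marker-track table.

    Accepts the native format (``marker_id image_index u v``) and IMOD
    ``model2point``-style output (``[object] contour x y z`` with z the
    image index and x, y corner-origin pixel coordinates — pass
    ``image_shape=(rows, cols)`` to convert to centre-origin).  Markers
    observed in fewer than ``min_images`` images are dropped with a note.
    """
    rows = []  # (marker_key, image_index, u, v)
    imodlike = False
    for lineno, line in _data_lines(path):
        parts = line.split()
        try:
            if len(parts) == 4 and not _is_number(parts[0]):
                rows.append((parts[0], int(parts[1]), float(parts[2]), float(parts[3])))
            elif len(parts) in (4, 5):  # model2point: [obj] contour x y z
                imodlike = True
                *head, x, y, z = parts
                key = "-".join(head)
                rows.append((key, int(round(float(z))), float(x), float(y)))
            else:
                raise ValueError("unrecognised column layout")
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if not rows:
        raise ParseError(path, 0, "no marker observations found")
    if imodlike and image_shape is not None:
        rows = [
            (k, i, x - (image_shape[1] - 1) / 2.0, y - (image_shape[0] - 1) / 2.0)
            for (k, i, x, y) in rows
        ]

    ids = list(dict.fromkeys(k for (k, *_r) in rows))  # stable first-seen order
    N = (max(i for (_, i, _, _) in rows) + 1) if n_images is None else n_images
    Nm = len(ids)
    pos = np.zeros((Nm, N, 2))
    obs = np.zeros((Nm, N), dtype=bool)
    index = {k: j for j, k in enumerate(ids)}
    for k, i, u, v in rows:
        if i >= N:
            raise ParseError(path, 0, f"image index {i} exceeds n_images={N}")
        pos[index[k], i] = (u, v)
        obs[index[k], i] = True
    keep = obs.sum(axis=1) >= min_images
    if not keep.all():
        import logging

        logging.getLogger("domealign").warning(
            "dropping %d marker(s) observed in fewer than %d images",
            int((~keep).sum()), min_images,
        )
    return MarkerTrackSet(pos[keep], obs[keep], [k for j, k in enumerate(ids) if keep[j]])


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# -- marker 3D tables -------------------------------------------------------


def write_markers(path, markers, marker_ids=None) -> None:
    markers = np.asarray(markers, dtype=float).reshape(-1, 3)
    if marker_ids is None:
        marker_ids = [f"m{j:02d}" for j in range(markers.shape[0])]
    lines = ["# domealign markers v1\n", "# columns: marker_id x y z\n"]
    for mid, (x, y, z) in zip(marker_ids, markers):
        lines.append(f"{mid} {x:.6f} {y:.6f} {z:.6f}\n")
    Path(path).write_text("".join(lines))


def read_markers(path) -> np.ndarray:
    out = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) == 4:
            parts = parts[1:]
        if len(parts) != 3:
            raise ParseError(path, lineno, "expected 'id x y z' or 'x y z'")
        try:
            out.append([float(p) for p in parts])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric coordinate in {line!r}") from None
    return np.array(out)


# -- motion models ----------------------------------------------------------

MOTION_HEADER = "# domealign motion model v1"


def write_motion(path, motion) -> None:
    """Serialise a motion model: header, then one line per surface per image,
    coefficients in the pinned monomial order."""
    form = motion.form.lower()
    comp_names = ("su", "sv") if form == "2d" else ("dx", "dy", "dz")
    lines = [
        MOTION_HEADER + "\n",
        f"# form {form} n_images {motion.n_images} "
        f"degree {motion.degree} z_degree {motion.z_degree}\n",
        "# mask " + " ".join("1" if b else "0" for b in motion.term_mask) + "\n",
    ]
    for i in range(motion.n_images):
        for c, name in enumerate(comp_names):
            coef = " ".join(f"{v:.10e}" for v in motion.coefficients[i, c])
            lines.append(f"{i} {name} {coef}\n")
    Path(path).write_text("".join(lines))


def read_motion(path):
    header = {}
    mask = None
    with open(path) as fh:
        content = fh.readlines()
    for lineno, raw in enumerate(content, start=1):
        line = raw.strip()
        if line.startswith("# form"):
            toks = line[1:].split()
            header = {toks[k]: toks[k + 1] for k in range(0, len(toks), 2)}
        elif line.startswith("# mask"):
            mask = np.array([t == "1" for t in line.split()[2:]])
    for key in ("form", "n_images", "degree", "z_degree"):
        if key not in header:
            raise ParseError(path, 0, f"missing {key!r} in motion header")
    form = header["form"]
    N, D, Dz = int(header["n_images"]), int(header["degree"]), int(header["z_degree"])
    n_comp = 2 if form == "2d" else 3
    n_terms = count_coeffs(D, Dz)
    coeffs = np.zeros((N, n_comp, n_terms))
    comp_index = {"su": 0, "sv": 1} if form == "2d" else {"dx": 0, "dy": 1, "dz": 2}
    for lineno, raw in enumerate(content, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            i, name = int(parts[0]), parts[1]
            vals = np.array([float(p) for p in parts[2:]])
            if name not in comp_index or vals.size != n_terms:
                raise ValueError(f"bad surface line for image {i}")
            coeffs[i, comp_index[name]] = vals
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    cls = MotionModel2D if form == "2d" else MotionModel3D
    return cls(D, Dz, coeffs, mask)


# -- alignment solutions ----------------------------------------------------

ALIGN_HEADER = "# domealign alignment v1"


def write_alignment(path, sol: AlignmentSolution) -> None:
    lines = [
        ALIGN_HEADER + "\n",
        f"# n_images {sol.geometry.n_images} n_markers {sol.n_markers}\n",
        "# image: index tilt psi alpha mag du dv acq branch\n",
    ]
    for i, g in enumerate(sol.geometry):
        lines.append(
            f"image {i} {g.tilt_angle_deg:.9f} {g.inplane_rotation_deg:.9f} "
            f"{g.pretilt_deg:.9f} {g.magnification:.9f} "
            f"{g.shift[0]:.9f} {g.shift[1]:.9f} "
            f"{g.acquisition_index} {g.branch_id}\n"
        )
    for j in range(sol.n_markers):
        x, y, z = sol.markers[j]
        lines.append(f"marker {j} {x:.9f} {y:.9f} {z:.9f}\n")
    Path(path).write_text("".join(lines))


def read_alignment(path) -> AlignmentSolution:
    images, markers = {}, {}
    for lineno, line in _data_lines(path):
        parts = line.split()
        try:
            if parts[0] == "image":
                i = int(parts[1])
                tilt, psi, alpha, mag, du, dv = (float(p) for p in parts[2:8])
                acq, branch = int(parts[8]), int(parts[9])
                images[i] = TiltImageGeometry(
                    tilt, psi, alpha, mag, (du, dv), acq, branch
                )
            elif parts[0] == "marker":
                markers[int(parts[1])] = [float(p) for p in parts[2:5]]
            else:
                raise ValueError(f"unknown record {parts[0]!r}")
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    if not images:
        raise ParseError(path, 0, "no image records found")
    geom = TiltSeriesGeometry([images[i] for i in sorted(images)])
    mk = np.array([markers[j] for j in sorted(markers)]) if markers else np.zeros((0, 3))
    return AlignmentSolution(mk, geom, fit_report=FitReport())


# -- report -----------------------------------------------------------------


def write_report(path, sol: AlignmentSolution, loo=None, extra: dict | None = None) -> None:
    """Human-readable alignment summary (mean residual, per-image residuals,
    measurements/unknowns ratio, LOO residual when computed)."""
    lines = ["# domealign alignment report v1\n"]
    lines.append(f"mean_residual_px {sol.mean_residual:.6f}\n")
    lines.append(
        f"measurements_to_unknowns {sol.fit_report.measurements_to_unknowns:.4f}\n"
    )
    lines.append(f"converged {int(sol.fit_report.converged)}\n")
    if extra:
        for k, v in extra.items():
            lines.append(f"{k} {v}\n")
    if loo is not None:
        lines.append(f"loo_residual_px {loo.loo_residual:.6f}\n")
        lines.append(
            f"loo_reference_standard_px {loo.reference_standard_residual:.6f}\n"
        )
        lines.append(f"loo_model_valid {int(loo.verdict)}\n")
        for mid, val in zip(loo.marker_ids, loo.per_marker_residual):
            lines.append(f"loo_marker {mid} {val:.6f}\n")
    if sol.residuals is not None and sol.observed is not None:
        lines.append("# per-image: index mean_residual_px n_markers\n")
        for i in range(sol.geometry.n_images):
            jj = np.flatnonzero(sol.observed[:, i])
            if jj.size:
                m = float(np.mean(np.linalg.norm(sol.residuals[jj, i], axis=-1)))
                lines.append(f"per_image {i} {m:.6f} {jj.size}\n")
    Path(path).write_text("".join(lines))


# -- MRC --------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file; returns (data, pixel_size_angstrom).

    Data comes back as float32 with shape (nz, ny, nx) (a stack of nz
    images); integer modes are promoted exactly.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ParseError(path, 0, "truncated MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MRC_MODES:
        raise ParseError(path, 0, f"unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1 or nx * ny * nz > 2**31:
        raise ParseError(path, 0, f"bad MRC dimensions {(nx, ny, nz)}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    offset = 1024 + nsymbt
    need = nx * ny * nz * dtype.itemsize
    if len(raw) - offset < need:
        raise ParseError(
            path, 0,
            f"header promises {nx}x{ny}x{nz} values but file holds fewer",
        )
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz, offset=offset)
    pixel = float(cella[0] / mx) if mx > 0 and cella[0] > 0 else 1.0
    return data.reshape(nz, ny, nx).astype(np.float32), pixel


def write_mrc(path, data, pixel_size: float = 1.0) -> None:
    """Write a float32 (mode 2) MRC2014 file; ``data`` is (nz, ny, nx)."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("MRC data must be 2D or 3D")
    nz, ny, nx = arr.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.astype("<f4").tobytes())


def write_volume(path, vol: Volume) -> None:
    # volume stored (nx, ny, nz) in memory, (nz, ny, nx) on disk
    write_mrc(path, np.ascontiguousarray(vol.data.T), pixel_size=vol.voxel_size)


def read_volume(path) -> Volume:
    data, pixel = read_mrc(path)
    return Volume(np.ascontiguousarray(data.T), voxel_size=pixel)
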