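"""Leave-one-out (LOO) cross-validation of the motion model.

Each fiducial in turn is withheld from the motion fitting and treated as
an object whose image positions must be predicted; the mean distance
between its measured and predicted positions, averaged over markers, is
the *LOO residual*.  A LOO residual below the standard-alignment residual
indicates the deformation model generalises across the field of view;
a larger one flags overfitting (scarce or poorly distributed fiducials).

By default only step 2 (the per-image polynomial fit) is redone per fold;
``refit_step1=True`` additionally redoes the bundle adjustment without the
held-out marker.  The held-out marker's 3D coordinates are always taken
from the full fit, since the fold cannot estimate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (
    AlignmentSolution,
    MarkerTrackSet,
    fit_motion,
    predict_positions,
    standard_align,
)

__all__ = ["LOOReport", "loo_residual"]


@dataclass
class LOOReport:
    """Per-marker held-out prediction errors and their mean."""

    per_marker_residual: np.ndarray  # (n_markers,) pixels
    loo_residual: float
    reference_standard_residual: float
    verdict: bool  # True when the motion model generalises
    marker_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.per_marker_residual = np.asarray(self.per_marker_residual, dtype=float)
        if np.any(self.per_marker_residual < 0):
            raise ValueError("per-marker residuals must be non-negative")


def loo_residual(
    tracks: MarkerTrackSet,
    sol1: AlignmentSolution,
    D: int = 2,
    Dz: int = 0,
    mask_kind: str = "full",
    refit_step1: bool = False,
    pooled: bool = False,
    **fit_kwargs,
) -> LOOReport:
    """Leave-one-out assessment of the motion-model quality.

    Parameters
    ----------
    tracks, sol1
        Full track set and its step-1 (standard) alignment solution.
    D, Dz, mask_kind
        Motion parameterisation passed to :func:`fit_motion` per fold.
    refit_step1
        Redo the bundle adjustment per fold as well (slower).
    pooled
        Average over all held-out observations pooled, instead of the
        default per-marker means then mean over markers.

    Deterministic: a pure function of its inputs (folds are independent).
    """
    Nm = tracks.n_markers
    if Nm < 2:
        raise ValueError("LOO needs at least 2 markers")
    if sol1.residuals is None:
        sol1 = sol1.with_residuals(tracks)

    per_marker = np.zeros(Nm)
    all_errors: list[np.ndarray] = []
    for j in range(Nm):
        fold_tracks = tracks.without_marker(j)
        if refit_step1:
            base = standard_align(fold_tracks, sol1.geometry)
        else:
            keep = np.arange(Nm) != j
            base = AlignmentSolution(
                sol1.markers[keep], sol1.geometry, fit_report=sol1.fit_report
            )
        fold_sol = fit_motion(base, fold_tracks, D, Dz, mask_kind, **fit_kwargs)

        # predict the held-out marker at its full-fit 3D coordinates
        probe = AlignmentSolution(
            sol1.markers[j : j + 1], fold_sol.geometry, motion=fold_sol.motion
        )
        pred = predict_positions(probe)[0]  # (n_images, 2)
        ii = np.flatnonzero(tracks.observed[j])
        err = np.linalg.norm(tracks.positions[j, ii] - pred[ii], axis=-1)
        per_marker[j] = float(err.mean())
        all_errors.append(err)

    loo = (
        float(np.concatenate(all_errors).mean())
        if pooled
        else float(per_marker.mean())
    )
    ref = float(sol1.mean_residual)
    return LOOReport(
        per_marker_residual=per_marker,
        loo_residual=loo,
        reference_standard_residual=ref,
        verdict=bool(loo < ref),
        marker_ids=list(tracks.marker_ids),
    )
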