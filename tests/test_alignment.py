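"""Two-step alignment: bundle adjustment, per-image motion fitting,
residual diagnostics."""

import numpy as np
import pytest

import domealign as da
from domealign.alignment import UnderdeterminedError


def _identity_series(n=3):
    return da.TiltSeriesGeometry(
        [da.TiltImageGeometry(0.0, acquisition_index=i) for i in range(n)]
    )


# -- prediction and objective ------------------------------------------------


def test_predict_positions_trivial_cases():
    geom = _identity_series(2)
    sol = da.AlignmentSolution([[1.0, 2.0, 3.0]], geom)
    np.testing.assert_allclose(da.predict_positions(sol)[0], [[1, 2], [1, 2]])

    coeffs = np.zeros((2, 2, 6))
    coeffs[:, 0, 0] = 0.5  # Su constant 0.5 via the enabled constant term
    sol.motion = da.MotionModel2D(2, 0, coeffs)
    np.testing.assert_allclose(da.predict_positions(sol)[0], [[1.5, 2], [1.5, 2]])


def test_predict_positions_matches_3d_form_oracle(rng):
    # oracle: evaluate the 3D triad then project, instead of the 2D model
    geom = da.TiltSeriesGeometry(
        [
            da.TiltImageGeometry(rng.uniform(-60, 60), shift=rng.normal(size=2),
                                 acquisition_index=i)
            for i in range(4)
        ]
    )
    m3 = da.MotionModel3D(2, 0, rng.normal(size=(4, 3, 6)))
    markers = rng.uniform(-2, 2, size=(6, 3))
    sol = da.AlignmentSolution(markers, geom, motion=da.convert_3d_to_2d(m3, geom))
    pred = da.predict_positions(sol)
    for i, g in enumerate(geom):
        M = da.projection_matrix(g)
        expected = (markers + m3.eval(i, markers)) @ M.T + g.shift
        np.testing.assert_allclose(pred[:, i], expected, atol=1e-10)


def test_objective_examples_and_naive_oracle(rng):
    geom = _identity_series(2)
    sol = da.AlignmentSolution([[1.0, 2.0, 3.0], [0.0, -1.0, 0.5]], geom)
    pred = da.predict_positions(sol)
    tracks = da.MarkerTrackSet(pred.copy(), np.ones((2, 2), bool))
    assert da.objective(sol, tracks) == 0.0

    off = pred.copy()
    off[0, 0] += (3.0, 4.0)
    assert da.objective(sol, da.MarkerTrackSet(off, np.ones((2, 2), bool))) == 25.0

    noisy = pred + rng.normal(size=pred.shape)
    obs = rng.uniform(size=(2, 2)) > 0.2
    tracks = da.MarkerTrackSet(noisy, obs)
    brute = sum(
        np.sum((noisy[j, i] - pred[j, i]) ** 2)
        for j in range(2) for i in range(2) if obs[j, i]
    )
    assert da.objective(sol, tracks) == pytest.approx(brute, rel=1e-10)


# -- standard alignment ------------------------------------------------------


def test_standard_align_recovers_truth_without_noise():
    s = da.DomingScenario(seed=5, amplitude0=0.0, amplitude_plateau=0.0,
                          noise_sigma=0.0)
    tracks, truth = da.simulate_tracks(s)
    sol = da.standard_align(tracks, truth.geometry)
    assert sol.mean_residual < 1e-6
    # markers recovered up to the centroid gauge
    np.testing.assert_allclose(
        sol.markers, truth.markers - truth.markers.mean(axis=0), atol=1e-6
    )


def test_standard_align_residual_matches_degrees_of_freedom():
    # least squares: E mean residual ~ sigma * sqrt(pi/2) * sqrt(1 - p/n)
    sigma = 1.0
    s = da.DomingScenario(seed=6, amplitude0=0.0, amplitude_plateau=0.0,
                          noise_sigma=sigma, n_markers=60)
    tracks, truth = da.simulate_tracks(s)
    sol = da.standard_align(tracks, truth.geometry)
    n = 2 * tracks.n_observations
    p = 3 * tracks.n_markers + 2 * tracks.n_images - 3
    expected = sigma * np.sqrt(np.pi / 2) * np.sqrt(1 - p / n)
    assert sol.mean_residual == pytest.approx(expected, rel=0.2)


def test_standard_align_underdetermined_raises():
    geom = _identity_series(2)
    tracks = da.MarkerTrackSet(np.zeros((1, 2, 2)), np.ones((1, 2), bool))
    with pytest.raises(UnderdeterminedError):
        da.standard_align(tracks, geom)


def test_standard_align_with_parameter_refinement():
    # true geometry has per-image rotations/magnifications; refinement
    # must recover them well enough to reach the noise-free optimum
    rng = np.random.default_rng(9)
    base = da.DomingScenario(seed=9, amplitude0=0.0, amplitude_plateau=0.0,
                             noise_sigma=0.0, n_markers=25)
    images = [
        g.replace(inplane_rotation_deg=rng.normal(0, 2.0),
                  magnification=1.0 + rng.normal(0, 0.01))
        for g in base.geometry
    ]
    geom_true = da.TiltSeriesGeometry(images)
    ref = da.solution_from_reference(geom_true, base.markers)
    tracks = da.MarkerTrackSet(da.predict_positions(ref), np.ones((25, base.n_images), bool))
    # without refinement the rotations show up as residual
    sol_plain = da.standard_align(tracks, base.geometry)
    sol_ref = da.standard_align(tracks, base.geometry,
                                refine_rotation=True, refine_magnification=True)
    assert sol_ref.mean_residual < 0.05 * sol_plain.mean_residual


# -- external alignment import ----------------------------------------------


def test_import_external_alignment_round_trip(tmp_path):
    from domealign import io as dio

    angles = np.arange(-9.0, 10.0, 3.0)
    geom = da.TiltSeriesGeometry(
        [
            da.TiltImageGeometry(a, inplane_rotation_deg=10.0, magnification=1.02,
                                 shift=(1.5, -2.0), acquisition_index=i)
            for i, a in enumerate(angles)
        ]
    )
    markers = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 1.0]])
    dio.write_tlt(tmp_path / "a.tlt", angles)
    dio.write_xf(tmp_path / "a.xf", geom)
    dio.write_markers(tmp_path / "m.txt", markers)
    sol = da.import_external_alignment(
        tmp_path / "a.tlt", tmp_path / "a.xf", tmp_path / "m.txt"
    )
    np.testing.assert_allclose(sol.geometry.tilt_angles(), angles, atol=1e-9)
    for g in sol.geometry:
        assert g.inplane_rotation_deg == pytest.approx(10.0, abs=1e-9)
        assert g.magnification == pytest.approx(1.02, abs=1e-9)
        np.testing.assert_allclose(g.shift, (1.5, -2.0), atol=1e-9)
    np.testing.assert_allclose(sol.markers, markers)


def test_import_identity_xf_gives_identity_geometry(tmp_path):
    from domealign import io as dio

    (tmp_path / "a.tlt").write_text("0.0\n0.0\n")
    (tmp_path / "a.xf").write_text("1 0 0 1 0 0\n1 0 0 1 0 0\n")
    dio.write_markers(tmp_path / "m.txt", np.zeros((1, 3)))
    sol = da.import_external_alignment(
        tmp_path / "a.tlt", tmp_path / "a.xf", tmp_path / "m.txt"
    )
    g = sol.geometry[0]
    assert (g.tilt_angle_deg, g.inplane_rotation_deg, g.magnification) == (0, 0, 1)


# -- motion fitting ----------------------------------------------------------


def test_fit_motion_recovers_true_coefficients_noise_free():
    s = da.DomingScenario(seed=8, noise_sigma=0.0)
    tracks, truth = da.simulate_tracks(s)
    ref = da.solution_from_reference(truth.geometry, truth.markers, tracks)
    sol = da.fit_motion(ref, tracks)
    assert sol.mean_residual < 1e-6
    assert np.max(np.abs(sol.motion.coefficients - truth.motion2d.coefficients)) < 1e-6


def test_fit_motion_never_increases_residual(default_tracks, default_sol1,
                                             default_sol2):
    assert default_sol2.mean_residual <= default_sol1.mean_residual
    # holds for constrained masks too: zero motion is always feasible
    tracks, _ = default_tracks
    for kind in ("pure_terms", "pure_z_only"):
        sol = da.fit_motion(default_sol1, tracks, 2, 0, kind)
        assert sol.mean_residual <= default_sol1.mean_residual + 1e-12


def test_fit_motion_degree_fallback_with_scarce_markers(caplog):
    import logging

    s = da.DomingScenario(seed=12, n_markers=3, amplitude0=0.0,
                          amplitude_plateau=0.0, noise_sigma=0.2)
    tracks, truth = da.simulate_tracks(s)
    ref = da.solution_from_reference(truth.geometry, truth.markers, tracks)
    with caplog.at_level(logging.INFO, logger="domealign"):
        sol = da.fit_motion(ref, tracks, 2, 0, "full")
    assert "fallback" in caplog.text
    # fell back to degree 1: quadratic coefficient columns stay zero
    assert np.all(sol.motion.coefficients[:, :, 3:] == 0.0)


def test_fit_motion_3d_matches_2d_residuals(default_tracks, default_sol1,
                                            default_sol2):
    tracks, _ = default_tracks
    sol3 = da.fit_motion_3d(default_sol1, tracks)
    assert abs(sol3.mean_residual - default_sol2.mean_residual) < 1e-8
    np.testing.assert_allclose(
        da.predict_positions(sol3), da.predict_positions(default_sol2), atol=1e-8
    )


def test_fit_motion_3d_beam_parallel_component_is_null(default_tracks,
                                                       default_sol1, rng):
    tracks, _ = default_tracks
    sol3 = da.fit_motion_3d(default_sol1, tracks)
    pts = rng.uniform(-500, 500, size=(100, 3))
    for i, g in enumerate(sol3.geometry):
        shifts = sol3.motion3d.eval(i, pts)  # sample frame
        beam = da.beam_direction(g)
        assert np.max(np.abs(shifts @ beam)) < 1e-8


def test_fit_motion_3d_zero_tilt_has_zero_axial_coefficients():
    s = da.DomingScenario(seed=13, tilt_min=0.0, tilt_max=0.0, branch_start=0.0)
    tracks, truth = da.simulate_tracks(s)
    ref = da.solution_from_reference(truth.geometry, truth.markers, tracks)
    sol3 = da.fit_motion_3d(ref, tracks)
    # z is exactly the beam direction at zero tilt: minimum norm leaves dz = 0
    np.testing.assert_allclose(sol3.motion3d.coefficients[:, 2, :], 0.0, atol=1e-10)


# -- diagnostics -------------------------------------------------------------


def test_residual_vs_acquisition_flat_for_uniform_residuals():
    geom = da.TiltSeriesGeometry(
        [da.TiltImageGeometry(3.0 * i, acquisition_index=2 - i) for i in range(3)]
    )
    sol = da.AlignmentSolution(np.zeros((4, 3)), geom)
    pred = da.predict_positions(sol)
    tracks = da.MarkerTrackSet(pred + np.array([1.0, 0.0]), np.ones((4, 3), bool))
    curve = da.residual_vs_acquisition(sol.with_residuals(tracks))
    np.testing.assert_allclose(curve[:, 1], 1.0, atol=1e-12)
    np.testing.assert_array_equal(curve[:, 0], [0, 1, 2])  # acquisition order


def test_residual_curve_decays_and_motion_fit_lies_below(default_tracks,
                                                         default_sol1,
                                                         default_sol2):
    c1 = da.residual_vs_acquisition(default_sol1)
    c2 = da.residual_vs_acquisition(default_sol2)
    assert c1[0, 1] == c1[:, 1].max()  # highest at the acquisition start
    assert np.all(c2[:, 1] < c1[:, 1])


def test_measurements_to_unknowns_ratio_examples():
    obs = np.ones((6, 5), dtype=bool)
    tracks = da.MarkerTrackSet(np.zeros((6, 5, 2)), obs)
    avg, per_image = da.measurements_to_unknowns_ratio(tracks, 2, 0, "full")
    assert avg == pytest.approx(1.0)  # 12 measurements / 12 parameters
    obs44 = np.ones((44, 5), dtype=bool)
    tracks44 = da.MarkerTrackSet(np.zeros((44, 5, 2)), obs44)
    avg44, _ = da.measurements_to_unknowns_ratio(tracks44, 2, 0, "full")
    assert avg44 == pytest.approx(88 / 12, rel=1e-9)
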