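"""Motion-compensated WBP, voxel tracking, ramp filter, subtiltseries."""

import numpy as np
import pytest

import domealign as da


@pytest.fixture(scope="module")
def bead_case():
    s = da.DomingScenario(seed=31, n_markers=3, extent=90.0, thickness=30.0,
                          noise_sigma=0.0, shift_sigma=1.0)
    stack = da.render_stack(s, "beads", image_size=128)
    return s, stack


# -- tracking ----------------------------------------------------------------


def test_track_position_identity_geometry():
    geom = da.TiltSeriesGeometry(
        [da.TiltImageGeometry(0.0, acquisition_index=i) for i in range(3)]
    )
    sol = da.AlignmentSolution(np.zeros((1, 3)), geom)
    proj = da.track_position((4.0, -2.0, 9.0), sol)
    np.testing.assert_allclose(proj, [[4, -2]] * 3)


def test_track_position_equals_marker_prediction(default_tracks, default_sol2):
    _tracks, _ = default_tracks
    pred = da.predict_positions(default_sol2)
    for j in (0, 7):
        proj = da.track_position(default_sol2.markers[j], default_sol2)
        np.testing.assert_allclose(proj, pred[j], atol=1e-12)


def test_track_position_matches_3d_motion_oracle(rng):
    # both sides of the motion-aware projection: M(x + D(x)) + d == Mx + S(x) + d
    geom = da.TiltSeriesGeometry(
        [da.TiltImageGeometry(rng.uniform(-60, 60), shift=rng.normal(size=2),
                              acquisition_index=i) for i in range(5)]
    )
    m3 = da.MotionModel3D(2, 0, rng.normal(size=(5, 3, 6)) * 0.01)
    sol = da.AlignmentSolution(np.zeros((1, 3)), geom,
                               motion=da.convert_3d_to_2d(m3, geom))
    x = rng.uniform(-5, 5, size=3)
    proj = da.track_position(x, sol)
    for i, g in enumerate(geom):
        expected = da.projection_matrix(g) @ (x + m3.eval(i, x[None])[0]) + g.shift
        np.testing.assert_allclose(proj[i], expected, atol=1e-10)


# -- ramp filter -------------------------------------------------------------


def test_ramp_filter_removes_dc():
    out = da.ramp_filter(np.full((4, 33), 7.5))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_ramp_filter_is_linear(rng):
    f, g = rng.normal(size=64), rng.normal(size=64)
    lhs = da.ramp_filter(2.0 * f - 0.5 * g)
    rhs = 2.0 * da.ramp_filter(f) - 0.5 * da.ramp_filter(g)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_ramp_filter_matches_direct_dft_oracle():
    # brute force: multiply the DFT by 2|f| bin by bin
    n = 32
    delta = np.zeros(n)
    delta[5] = 1.0
    out = da.ramp_filter(delta)
    freqs = np.fft.fftfreq(n)
    brute = np.real(np.fft.ifft(np.fft.fft(delta) * 2.0 * np.abs(freqs)))
    np.testing.assert_allclose(out, brute, atol=1e-12)


def test_ramp_filter_hamming_attenuates_high_frequencies(rng):
    line = rng.normal(size=128)
    plain = da.ramp_filter(line)
    apod = da.ramp_filter(line, apodisation="hamming")
    assert np.linalg.norm(apod) < np.linalg.norm(plain)
    with pytest.raises(ValueError):
        da.ramp_filter(line, apodisation="hann")


# -- WBP ---------------------------------------------------------------------


def test_wbp_zero_motion_model_equals_standard_path(bead_case):
    s, stack = bead_case
    truth = s.truth
    plain = da.AlignmentSolution(truth.markers, truth.geometry)
    with_zero = da.AlignmentSolution(truth.markers, truth.geometry,
                                     motion=da.zero_motion(s.n_images))
    v1 = da.reconstruct_wbp(stack, plain, (48, 48, 24), use_motion=False)
    v2 = da.reconstruct_wbp(stack, with_zero, (48, 48, 24), use_motion=True)
    assert np.max(np.abs(v1.data - v2.data)) <= 1e-8


def test_wbp_motion_compensation_restores_bead_peaks(bead_case):
    s, stack = bead_case
    truth = s.truth
    shape = (112, 112, 48)
    vol_c = da.reconstruct_wbp(stack, truth.solution(), shape, use_motion=True)
    vol_s = da.reconstruct_wbp(
        stack, da.AlignmentSolution(truth.markers, truth.geometry), shape,
        use_motion=False,
    )
    off = (np.array(shape) - 1) / 2.0
    for j in range(truth.markers.shape[0]):
        tv = truth.markers[j] + off
        lo = np.maximum(np.round(tv).astype(int) - 5, 0)
        hi = np.round(tv).astype(int) + 6
        sub_c = vol_c.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub_s = vol_s.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        peak_c = lo + np.unravel_index(np.argmax(sub_c), sub_c.shape)
        # compensated peak lands on the true voxel; uncompensated is weaker
        assert np.all(np.abs(peak_c - tv) <= 1.0)
        assert sub_c.max() > sub_s.max()


def test_wbp_is_linear_in_the_stack(bead_case, rng):
    s, _ = bead_case
    truth = s.truth
    sol = truth.solution()
    a = rng.normal(size=(s.n_images, 32, 32))
    b = rng.normal(size=(s.n_images, 32, 32))
    shape = (16, 16, 8)
    va = da.reconstruct_wbp(a, sol, shape).data
    vb = da.reconstruct_wbp(b, sol, shape).data
    vab = da.reconstruct_wbp(3.0 * a - b, sol, shape).data
    np.testing.assert_allclose(vab, 3.0 * va - vb, atol=1e-4)


def test_backprojection_of_projected_delta_peaks_at_source():
    # adjointness sanity: unfiltered backprojection of a point's projections
    # is maximal at the point itself
    geom = da.TiltSeriesGeometry(
        [da.TiltImageGeometry(a, acquisition_index=i)
         for i, a in enumerate(np.arange(-60.0, 61.0, 10.0))]
    )
    sol = da.AlignmentSolution(np.zeros((1, 3)), geom)
    src = np.array([3.0, -2.0, 1.0])
    stack = np.zeros((geom.n_images, 33, 33))
    from domealign.synthetic import _gaussian_splat

    for i, g in enumerate(geom):
        u, v = da.project_marker(g, src)
        _gaussian_splat(stack[i], u, v, 1.0, 1.0)
    vol = da.reconstruct_wbp(stack, sol, (17, 17, 9), apply_filter=False)
    peak = np.unravel_index(np.argmax(vol.data), vol.data.shape)
    np.testing.assert_array_equal(peak, np.round(src + np.array([8, 8, 4])))


def test_wbp_rejects_mismatched_stack():
    geom = da.TiltSeriesGeometry([da.TiltImageGeometry(0.0)])
    sol = da.AlignmentSolution(np.zeros((1, 3)), geom)
    with pytest.raises(ValueError):
        da.reconstruct_wbp(np.zeros((3, 8, 8)), sol, (4, 4, 4))


# -- subtiltseries -----------------------------------------------------------


def test_extract_subtiltseries_centres_beads(bead_case):
    s, stack = bead_case
    truth = s.truth
    sub = da.extract_subtiltseries(stack, truth.solution(), truth.markers[0], 15)
    assert sub.present.any()
    for i, patch in enumerate(sub.patches):
        if patch is None:
            continue
        # centroid of the patch sits within half a pixel of the centre
        rows, cols = np.mgrid[0:15, 0:15]
        w = patch / patch.sum()
        centroid = np.array([(cols * w).sum(), (rows * w).sum()])
        np.testing.assert_allclose(centroid, 7.0 + sub.offsets[i], atol=0.5)


def test_extract_flags_out_of_bounds_images():
    geom = da.TiltSeriesGeometry(
        [da.TiltImageGeometry(a, acquisition_index=i)
         for i, a in enumerate([0.0, 60.0])]
    )
    sol = da.AlignmentSolution(np.zeros((1, 3)), geom)
    stack = np.ones((2, 32, 32))
    # projects at u = 14 cos(60) = 7 inside, u = 14 at 0 deg near the edge
    sub = da.extract_subtiltseries(stack, sol, (14.0, 0.0, 0.0), 9)
    assert not sub.present[0]  # patch would overhang the right edge
    assert sub.present[1]


def test_volume_validation():
    with pytest.raises(ValueError):
        da.Volume(np.zeros((4, 4)))
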