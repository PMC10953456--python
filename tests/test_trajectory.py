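"""Trajectory generation: golden angles, interleaf counts, density profiles,
spiral pitch self-consistency, orderings, and density compensation."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiralcine.trajectory import (
    PHI,
    ImagingGrid,
    SpiralParams,
    acceleration_profile,
    build_radial,
    build_trajectory,
    density_compensation,
    design_interleave,
    frame_acceleration_range,
    interleaf_count,
    load_trajectory,
    save_trajectory,
    tiny_golden_angle,
)

from conftest import nyquist_params


@pytest.mark.parametrize(
    "order,arc,expected,decimals",
    [
        (7, 360, 47.3, 1),  # the spiral-ordering increment
        (2, 180, 68.75, 2),
        (1, 360, 222.49, 2),
    ],
)
def test_tiny_golden_angle_values(order, arc, expected, decimals):
    assert round(tiny_golden_angle(order, arc), decimals) == pytest.approx(expected)


def test_tiny_golden_angle_rejects_bad_order():
    with pytest.raises(ValueError):
        tiny_golden_angle(0)
    with pytest.raises(ValueError):
        tiny_golden_angle(-3)


@pytest.mark.parametrize(
    "tr,expected", [(2.88, 19), (3.7, 14), (3.67, 14)]
)
def test_interleaf_count(tr, expected):
    assert interleaf_count(tr, 55.0) == expected


def test_interleaf_count_monotone_in_tr():
    trs = np.linspace(2.88, 3.7, 50)
    counts = [interleaf_count(t, 55.0) for t in trs]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_interleaf_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        interleaf_count(0.0, 55.0)


def test_interleaf_override_matches_protocol_table(optimized_params):
    # The published protocol runs 15 interleaves at TR 3.67 even though the
    # floor formula gives 14; the override carries that choice.
    assert interleaf_count(3.67, 55.0) == 14
    assert optimized_params.interleaves_per_frame() == 15


class TestAccelerationProfile:
    def test_inner_plateau(self, optimized_params):
        assert acceleration_profile(optimized_params, 0.10) == pytest.approx(16.0)

    def test_outer_plateau(self, optimized_params):
        assert acceleration_profile(optimized_params, 0.80) == pytest.approx(16.0 / 0.07)

    def test_linear_transition_midpoint(self, optimized_params):
        p = dataclasses.replace(optimized_params, transition="linear")
        mid = (p.r_inner + p.r_outer) / 2.0
        d_mid = (1.0 / 16.0 + 0.07 / 16.0) / 2.0
        assert acceleration_profile(p, mid) == pytest.approx(1.0 / d_mid, rel=1e-9)
        assert acceleration_profile(p, mid) == pytest.approx(29.91, abs=0.005)

    def test_continuity_all_transitions(self, optimized_params):
        k = np.linspace(0.0, 1.0, 2001)
        for tname in ("linear", "hanning", "quadratic"):
            p = dataclasses.replace(optimized_params, transition=tname)
            a = acceleration_profile(p, k)
            jumps = np.abs(np.diff(a)) / np.maximum(a[:-1], 1.0)
            assert jumps.max() < 0.02, tname

    def test_rejects_k_outside_unit_interval(self, optimized_params):
        with pytest.raises(ValueError):
            acceleration_profile(optimized_params, 1.2)


class TestDesignInterleave:
    def test_starts_at_origin_ends_at_kmax(self, optimized_params, grid64):
        path = design_interleave(optimized_params, grid64, 256)
        assert np.allclose(path[0], 0.0)
        assert np.hypot(*path[-1]) == pytest.approx(0.5, abs=1e-6)

    def test_radius_monotone(self, optimized_params, grid64):
        path = design_interleave(optimized_params, grid64, 256)
        r = np.hypot(path[:, 0], path[:, 1])
        assert np.all(np.diff(r) >= -1e-12)

    def test_uniform_spiral_radial_gap(self):
        # Single-interleave pitch a/matrix: one full turn advances the radius
        # by 92/240 in normalized units.
        grid = ImagingGrid(240, 400.0)
        params = nyquist_params(15)
        params = dataclasses.replace(params, a_inner=92.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = design_interleave(params, grid, 2048)
        theta = np.unwrap(np.arctan2(path[:, 1], path[:, 0]))
        r = np.hypot(path[:, 0], path[:, 1])
        t0 = 2.0
        gap = np.interp(t0 + 2 * np.pi, theta, r) - np.interp(t0, theta, r)
        assert gap == pytest.approx(92.0 / 240.0, rel=0.02)

    def test_rejects_tiny_sample_count(self, optimized_params, grid64):
        with pytest.raises(ValueError):
            design_interleave(optimized_params, grid64, 8)


def test_nyquist_self_consistency(grid64):
    """A uniform spiral with a_inner = N rotated into N interleaves tiles
    k-space at the composite Nyquist pitch 1/matrix at all radii."""
    from spiralcine.trajectory import turn_crossings

    n = 15
    traj = build_trajectory(nyquist_params(n), grid64, 1, samples_per_interleave=2048)
    checked = 0
    for az in (0.0, 45.0, 110.0, 237.0):
        rs = turn_crossings(traj, 0, az)
        rs = rs[(rs > 0.08) & (rs < 0.47)]
        gaps = np.diff(rs)
        assert gaps.size > 10
        # within 2% of 1/matrix at every radius band
        assert np.all(np.abs(gaps * 64.0 - 1.0) < 0.02)
        checked += gaps.size
    assert checked > 50


class TestBuildTrajectory:
    def test_linear_ordering_frame_stationary(self, optimized_params, grid64):
        traj = build_trajectory(optimized_params, grid64, 2, samples_per_interleave=64)
        assert np.array_equal(traj.frame(0), traj.frame(1))

    def test_tiny_golden_constant_increment(self, optimized_params, grid64):
        p = dataclasses.replace(optimized_params, ordering="tiny_golden")
        traj = build_trajectory(p, grid64, 2, samples_per_interleave=64)
        inc = 360.0 / (PHI + 6.0)
        coords = traj.coords.reshape(-1, 64, 2)
        # Angle of an off-center sample of each interleave, consecutive diffs.
        ang = np.degrees(np.arctan2(coords[:, 40, 1], coords[:, 40, 0]))
        d = np.diff(ang) % 360.0
        assert np.allclose(d, inc, atol=1e-9)
        assert inc == pytest.approx(47.25, abs=0.01)

    def test_single_interleave_single_frame(self, grid64):
        traj = build_trajectory(nyquist_params(1), grid64, 1, samples_per_interleave=64)
        assert traj.coords.shape[:2] == (1, 1)
        # Linear ordering at N=1: base interleave unrotated.
        base = design_interleave(nyquist_params(1), grid64, 64)
        assert np.allclose(traj.frame(0)[0], base)

    def test_rejects_zero_frames(self, optimized_params, grid64):
        with pytest.raises(ValueError):
            build_trajectory(optimized_params, grid64, 0)

    @settings(max_examples=30, deadline=None)
    @given(
        r_inner=st.floats(0.1, 0.3),
        a_inner=st.floats(12.0, 24.0),
        u_outer=st.floats(0.0, 1.0),
        ratio=st.floats(0.01, 0.35),
        transition=st.sampled_from(["linear", "hanning", "quadratic"]),
        tr=st.floats(2.88, 3.7),
    )
    def test_random_params_stay_in_disk_and_monotone(
        self, r_inner, a_inner, u_outer, ratio, transition, tr
    ):
        params = SpiralParams(
            r_inner=r_inner,
            a_inner=a_inner,
            r_outer=r_inner + u_outer * (1.0 - 2.0 * r_inner),
            density_ratio=ratio,
            transition=transition,
            ordering="linear",
            tr_ms=tr,
        )
        grid = ImagingGrid(32, 400.0)
        path = design_interleave(params, grid, 128)
        r = np.hypot(path[:, 0], path[:, 1])
        assert r.max() <= 0.5 + 1e-9
        assert np.all(np.diff(r) >= -1e-12)


class TestRadial:
    def test_default_spokes_per_frame(self, grid64):
        traj = build_radial(grid64, n_frames=1, samples_per_spoke=64)
        assert traj.n_interleaves_per_frame == 17

    def test_first_spoke_geometry(self, grid64):
        traj = build_radial(grid64, 4, 1, samples_per_spoke=65)
        spoke = traj.frame(0)[0]
        assert np.allclose(spoke[:, 1], 0.0, atol=1e-12)  # angle 0
        assert spoke[0, 0] == pytest.approx(-0.5)
        assert spoke[-1, 0] == pytest.approx(0.5)

    def test_successive_increment(self, grid64):
        traj = build_radial(grid64, 5, 2, samples_per_spoke=64)
        coords = traj.coords.reshape(-1, 64, 2)
        ang = np.degrees(np.arctan2(coords[:, -1, 1], coords[:, -1, 0]))
        d = np.diff(ang) % 360.0
        assert np.allclose(d, 180.0 / (PHI + 6.0), atol=1e-9)
        assert round(180.0 / (PHI + 6.0), 2) == 23.63


class TestDensityCompensation:
    def test_weights_finite_nonnegative(self, traj_optimized_64):
        w = traj_optimized_64.dcw
        assert np.all(np.isfinite(w))
        assert np.all(w >= 0)

    def test_sum_approximates_disk_area(self, traj_optimized_64):
        assert traj_optimized_64.dcw[0].sum() == pytest.approx(np.pi / 4, rel=0.10)

    def test_pitch_matches_voronoi_oracle(self, grid64):
        traj = build_trajectory(
            nyquist_params(15), grid64, 1, samples_per_interleave=512
        )
        wv = density_compensation(traj, 0, method="voronoi")
        wp = density_compensation(traj, 0, method="pitch")
        rms = np.sqrt(np.mean(((wp - wv) / np.maximum(wv, 1e-12)) ** 2))
        assert rms < 0.15

    def test_radial_weights_ramp_with_radius(self, grid64):
        traj = build_radial(grid64, 8, 1, samples_per_spoke=128)
        w = density_compensation(traj, 0, method="voronoi")[0]
        r = np.hypot(*traj.frame(0)[0].T)
        mid, outer = (r > 0.1) & (r < 0.2), (r > 0.3) & (r < 0.4)
        assert w[outer].mean() > 1.5 * w[mid].mean()

    def test_duplicate_center_samples_split_weight(self, grid64):
        # All interleaves start at k=0; the shared cell must be split, not
        # multiply counted.
        traj = build_trajectory(nyquist_params(8), grid64, 1, samples_per_interleave=128)
        for method in ("voronoi", "pitch"):
            w = density_compensation(traj, 0, method=method)
            center_w = w[:, 0]
            assert center_w.max() < 5 * w.mean(), method


class TestFrameAccelerationRange:
    def test_uniform_table_row(self, uniform_params):
        lo, hi = frame_acceleration_range(uniform_params)
        assert round(lo, 1) == 6.1
        assert round(hi, 1) == 6.1

    def test_optimized_table_row(self, optimized_params):
        lo, hi = frame_acceleration_range(optimized_params)
        assert round(lo, 1) == 1.1
        assert hi == pytest.approx(16.0 / (0.07 * 15.0), rel=1e-9)

    def test_nyquist_is_unity(self):
        lo, hi = frame_acceleration_range(nyquist_params(13))
        assert lo == pytest.approx(1.0)
        assert hi == pytest.approx(1.0)


def test_out_of_range_params_warn_but_construct():
    with pytest.warns(UserWarning):
        SpiralParams(r_inner=0.5, r_outer=0.5)


def test_trajectory_csv_export(tmp_path, optimized_params, grid64):
    from spiralcine.trajectory import save_trajectory_csv

    traj = build_trajectory(optimized_params, grid64, 1, samples_per_interleave=32)
    path = tmp_path / "traj.csv"
    save_trajectory_csv(traj, str(path))
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "interleave,sample,kx,ky,dcw"
    assert len(lines) == 1 + 15 * 32


def test_trajectory_hdf5_roundtrip(tmp_path, optimized_params, grid64):
    traj = build_trajectory(optimized_params, grid64, 2, samples_per_interleave=32)
    path = str(tmp_path / "traj.h5")
    save_trajectory(traj, path)
    back = load_trajectory(path)
    assert np.allclose(back.coords, traj.coords)
    assert np.allclose(back.dcw, traj.dcw)
    assert back.grid == traj.grid
    assert back.params.r_inner == traj.params.r_inner
    assert back.params.n_interleaves == 15
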