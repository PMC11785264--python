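"""Radial trajectory, exact NDFT operators, binning, determinedness."""

import numpy as np
import pytest

from spars.encoding import (
    CoilMaps,
    EncodingOperator,
    RadialKSpace,
    RadialTrajectory,
    bin_spokes,
    coefficient_counts,
    encode,
    golden_angle_angles,
    hit_count_map,
    nufft_adjoint,
    nufft_forward,
    radial_sample_coords,
    rebin_kspace,
    underdetermined_fraction,
    uniform_angles,
)


def brute_force_ndft(image, coords):
    """O(N^2 M) double-sum oracle with the package's coordinate convention."""
    N = image.shape[0]
    x = np.arange(N) - N // 2
    out = np.zeros(len(coords), dtype=complex)
    for m, (kx, ky) in enumerate(coords):
        for i in range(N):
            for j in range(N):
                out[m] += image[i, j] * np.exp(-2j * np.pi * (kx * x[i] + ky * x[j]))
    return out


class TestAngles:
    def test_single_spoke_at_zero(self):
        assert golden_angle_angles(1).tolist() == [0.0]

    def test_increment_is_golden_angle(self):
        inc = np.rad2deg(golden_angle_angles(2)[1])
        assert inc == pytest.approx(137.5077640500378, abs=1e-9)

    def test_wraps_mod_pi(self):
        a2 = np.rad2deg(golden_angle_angles(3)[2])
        assert a2 == pytest.approx((2 * 137.5077640500378) % 180.0, abs=1e-9)

    def test_near_uniform_coverage(self):
        # golden-angle sets cover [0, pi) with bounded gap ratio
        a = np.sort(golden_angle_angles(100))
        gaps = np.diff(np.concatenate([a, [a[0] + np.pi]]))
        assert np.rad2deg(gaps.max()) < 3.0  # ~3 deg at 100 spokes

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            golden_angle_angles(0)


class TestRadialCoords:
    def test_angle_zero_lies_on_kx_axis(self):
        c = radial_sample_coords(0.0, 16)
        assert np.allclose(c[:, 1], 0.0)

    def test_angle_half_pi_lies_on_ky_axis(self):
        c = radial_sample_coords(np.pi / 2, 16)
        assert np.allclose(c[:, 0], 0.0, atol=1e-12)

    def test_radii_match_direct_formula(self):
        n = 20
        c = radial_sample_coords(0.3, n)
        r = np.hypot(c[:, 0], c[:, 1])
        want = np.abs((np.arange(n) - n / 2) / n)
        assert np.allclose(r, want)
        assert r.min() == 0.0  # passes through the origin for even n


class TestNDFT:
    def test_matches_brute_force(self, rng):
        img = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        coords = rng.uniform(-0.5, 0.4999, (16, 2))
        got = nufft_forward(img, coords)
        want = brute_force_ndft(img, coords)
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_zero_image_zero_samples(self):
        assert np.all(nufft_forward(np.zeros((8, 8)), np.zeros((3, 2))) == 0)

    def test_center_impulse_constant_magnitude(self):
        img = np.zeros((8, 8), dtype=complex)
        img[4, 4] = 1.0  # grid origin at N//2
        out = nufft_forward(img, np.random.default_rng(0).uniform(-0.5, 0.5 - 1e-9, (20, 2)))
        assert np.allclose(np.abs(out), 1.0)

    @pytest.mark.parametrize("N", [8, 16, 32])
    def test_adjoint_identity(self, N, rng):
        coords = rng.uniform(-0.5, 0.4999, (3 * N, 2))
        x = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
        y = rng.standard_normal(3 * N) + 1j * rng.standard_normal(3 * N)
        Fx = nufft_forward(x, coords)
        lhs = np.vdot(Fx, y)
        rhs = np.vdot(x, nufft_adjoint(y, coords, N))
        assert abs(lhs - rhs) / (np.linalg.norm(Fx) * np.linalg.norm(y)) < 1e-5

    def test_adjoint_of_origin_sample_is_constant(self):
        img = nufft_adjoint(np.array([3.0 + 0j]), np.array([[0.0, 0.0]]), 8)
        assert np.allclose(img, 3.0)

    def test_out_of_range_coords_rejected(self):
        with pytest.raises(ValueError):
            nufft_forward(np.zeros((8, 8)), np.array([[0.6, 0.0]]))


class TestEncodingOperator:
    def test_adjoint_identity_on_kspace(self, rank3_fixture, rng):
        y, coils = rank3_fixture["kspace"], rank3_fixture["coils"]
        op = EncodingOperator.for_kspace(y, coils)
        shape = rank3_fixture["gt"].data.shape
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        s = rng.standard_normal(y.samples.shape) + 1j * rng.standard_normal(y.samples.shape)
        Fx = op.forward(x)
        lhs = np.vdot(Fx, s)
        rhs = np.vdot(x, op.adjoint(s))
        assert abs(lhs - rhs) / (np.linalg.norm(Fx) * np.linalg.norm(s)) < 1e-5

    def test_linearity(self, rank3_fixture, rng):
        y, coils = rank3_fixture["kspace"], rank3_fixture["coils"]
        op = EncodingOperator.for_kspace(y, coils)
        shape = rank3_fixture["gt"].data.shape
        a, b = 1.7, -0.3 + 2j
        x1 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        x2 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = op.forward(a * x1 + b * x2)
        rhs = a * op.forward(x1) + b * op.forward(x2)
        assert np.allclose(lhs, rhs, atol=1e-9 * np.abs(lhs).max())

    def test_matches_per_spoke_ndft(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        op = EncodingOperator.for_kspace(y, coils)
        F = op.forward(gt.data)
        for s in [0, 5, len(y.frame_of_spoke) - 1]:
            frame = y.frame_of_spoke[s]
            direct = nufft_forward(gt.frames()[:, :, frame], y.trajectory.kcoords[s])
            assert np.allclose(F[s, :, 0], direct, atol=1e-10 * np.abs(direct).max())

    def test_identical_unit_coils_give_identical_channels(self, rank3_fixture):
        gt, y = rank3_fixture["gt"], rank3_fixture["kspace"]
        coils2 = CoilMaps.uniform(gt.N, n_coils=2)
        out = encode(gt, y.trajectory, y.frame_of_spoke, coils2)
        assert np.array_equal(out[:, :, 0], out[:, :, 1])

    def test_smooth_coil_maps_adjoint(self, rank3_fixture, rng):
        gt, y = rank3_fixture["gt"], rank3_fixture["kspace"]
        N = gt.N
        xg, yg = np.meshgrid(np.linspace(-1, 1, N), np.linspace(-1, 1, N), indexing="ij")
        maps = np.stack([np.exp(-(xg - 0.3) ** 2 - yg**2), (1 + 1j) * np.exp(-(xg + 0.3) ** 2 - yg**2)])
        op = EncodingOperator(y.trajectory, y.frame_of_spoke, y.n_frames, CoilMaps(maps))
        x = rng.standard_normal(gt.data.shape) + 1j * rng.standard_normal(gt.data.shape)
        s = rng.standard_normal((y.trajectory.n_spokes, y.trajectory.n_samples, 2)) + 0j
        Fx = op.forward(x)
        assert abs(np.vdot(Fx, s) - np.vdot(x, op.adjoint(s))) / (np.linalg.norm(Fx) * np.linalg.norm(s)) < 1e-5


class TestBinning:
    @pytest.mark.parametrize(
        "n_spokes,per_frame,n_frames,dropped",
        [(1000, 25, 40, 0), (600, 21, 28, 12), (7, 1, 7, 0)],
    )
    def test_floor_division_grouping(self, n_spokes, per_frame, n_frames, dropped):
        b = bin_spokes(n_spokes, per_frame)
        assert b.n_frames == n_frames
        assert int((b.frame_of_spoke == -1).sum()) == dropped

    def test_identity_binning(self):
        b = bin_spokes(5, 1)
        assert np.array_equal(b.frame_of_spoke, np.arange(5))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bin_spokes(10, 0)
        with pytest.raises(ValueError):
            bin_spokes(3, 5)

    def test_rebin_preserves_dense_frames(self, rank3_fixture):
        y = rank3_fixture["kspace"]  # frames 0 and T-1 dense, middle 1 spoke/frame
        yb = rebin_kspace(y, 3)
        assert yb.dense_frames == (0, yb.n_frames - 1)
        counts = np.bincount(yb.frame_of_spoke)
        # middle frames carry exactly 3 spokes
        assert np.all(counts[1:-1] == 3)
        # dense frames keep their full spoke sets
        n_dense = int((y.frame_of_spoke == 0).sum())
        assert counts[0] == n_dense and counts[-1] == n_dense

    def test_rebin_drops_remainder(self):
        traj = RadialTrajectory(golden_angle_angles(10), 8)
        samples = np.zeros((10, 8, 1), dtype=complex)
        y = RadialKSpace(samples=samples, trajectory=traj, frame_of_spoke=np.arange(10), n_frames=10)
        yb = rebin_kspace(y, 4)
        assert yb.n_frames == 2
        assert yb.trajectory.n_spokes == 8


class TestDeterminedness:
    def test_hit_counts_conserved(self):
        traj = RadialTrajectory(golden_angle_angles(50), 32)
        counts = hit_count_map(traj, 16)
        assert counts.sum() == 50 * 32

    def test_origin_cell_hit_by_every_spoke(self):
        traj = RadialTrajectory(golden_angle_angles(37), 32)
        counts = hit_count_map(traj, 16)
        assert counts[8, 8] >= 37

    def test_corner_cells_empty(self):
        traj = RadialTrajectory(golden_angle_angles(50), 64)
        counts = hit_count_map(traj, 32)
        assert counts[0, 0] == 0 and counts[-1, -1] == 0

    def test_underdetermined_fraction_limits_and_monotonicity(self):
        traj = RadialTrajectory(golden_angle_angles(40), 64)
        counts = hit_count_map(traj, 32)
        assert underdetermined_fraction(counts, 0) == 0.0
        assert underdetermined_fraction(counts, int(counts.max()) + 1) == 1.0
        fracs = [underdetermined_fraction(counts, M) for M in range(8)]
        assert np.all(np.diff(fracs) >= 0)

    def test_coefficient_counts(self):
        assert coefficient_counts(200, 1000, 20) == (800000, 20000)
        assert coefficient_counts(8, 4, 0) == (0, 0)
        N, T, M = 64, 100, 5
        spatial_unknowns = coefficient_counts(N, T, M)[1]
        temporal_unknowns = coefficient_counts(N, T, M)[0]
        assert spatial_unknowns < temporal_unknowns  # whenever T < N^2


class TestUniformAngles:
    def test_spacing(self):
        a = uniform_angles(4)
        assert np.allclose(np.diff(a), np.pi / 4)
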