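"""SPARS pipeline: stage-1 CS solve, spatial basis, stage-2 coefficient fit."""

import numpy as np
import pytest

from spars.encoding import CoilMaps, RadialKSpace, RadialTrajectory, nufft_forward, uniform_angles, nyquist_spokes
from spars.phantom import DynamicSeries
from spars.recon import (
    SparsConfig,
    SpatialBasis,
    estimate_spatial_basis,
    reconstruct_spars,
    solve_high_temporal,
    solve_low_temporal,
)
from spars.solvers import CGConfig


class TestSpatialBasis:
    def test_orthonormality(self, rank3_fixture):
        basis = estimate_spatial_basis(rank3_fixture["gt"], 3)
        gram = basis.U.conj().T @ basis.U
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_exact_rank_projection_residual(self, rank3_fixture):
        gt = rank3_fixture["gt"]
        basis = estimate_spatial_basis(gt, 3)
        proj = basis.U @ (basis.U.conj().T @ gt.data)
        assert np.linalg.norm(gt.data - proj) < 1e-10 * np.linalg.norm(gt.data)

    def test_eckart_young_residual(self, rng):
        X = rng.standard_normal((50, 10)) + 1j * rng.standard_normal((50, 10))
        series = DynamicSeries(data=np.zeros((49, 10)), frame_times=np.arange(10.0), N=7)
        series.data = X[:49]  # any (N^2, T) matrix
        basis = estimate_spatial_basis(series, 5)
        resid = np.linalg.norm(series.data - basis.U @ (basis.U.conj().T @ series.data))
        s = np.linalg.svd(series.data, compute_uv=False)
        assert resid == pytest.approx(np.sqrt((s[5:] ** 2).sum()), rel=1e-10)

    def test_oversized_b_rejected(self, rank3_fixture):
        with pytest.raises(ValueError):
            estimate_spatial_basis(rank3_fixture["gt"], 100)

    def test_truncation(self, rank3_fixture):
        b3 = estimate_spatial_basis(rank3_fixture["gt"], 3)
        assert np.array_equal(b3.truncated(2).U, b3.U[:, :2])


class TestStageTwo:
    def test_lambda_zero_matches_pseudoinverse_oracle(self, rank3_fixture):
        """Per-frame solutions equal dense normal-equation solves built from
        an independent brute-force encoded-basis matrix."""
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        basis = estimate_spatial_basis(gt, 3)
        cfg = SparsConfig(L=3, H=1, b=3, lambda_H=0.0)
        coeffs, xh = solve_high_temporal(y, coils, basis, cfg)

        N = gt.N
        for frame in [0, 4, gt.n_frames - 1]:
            spokes = np.flatnonzero(y.frame_of_spoke == frame)
            G = np.zeros((spokes.size * y.trajectory.n_samples, basis.b), dtype=complex)
            for j in range(basis.b):
                img = basis.U[:, j].reshape(N, N)
                G[:, j] = np.concatenate(
                    [nufft_forward(img, y.trajectory.kcoords[s]) for s in spokes]
                )
            yt = y.samples[spokes, :, 0].reshape(-1)
            a_oracle = np.linalg.solve(G.conj().T @ G, G.conj().T @ yt)
            rel = np.linalg.norm(coeffs.A[:, frame] - a_oracle) / np.linalg.norm(a_oracle)
            assert rel < 1e-6

    def test_ground_truth_basis_exact_recovery(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        basis = estimate_spatial_basis(gt, 3)  # spans the rank-3 truth exactly
        cfg = SparsConfig(L=3, H=1, b=3, lambda_H=0.0)
        _, xh = solve_high_temporal(y, coils, basis, cfg)
        rel = np.linalg.norm(xh.data - gt.data, axis=0) / np.linalg.norm(gt.data, axis=0)
        assert rel.max() < 1e-6

    def test_subspace_containment_is_exact(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        basis = estimate_spatial_basis(gt, 2)  # deliberately too small
        cfg = SparsConfig(L=3, H=1, b=2, lambda_H=0.0)
        _, xh = solve_high_temporal(y, coils, basis, cfg)
        proj = basis.U @ (basis.U.conj().T @ xh.data)
        assert np.linalg.norm(xh.data - proj) < 1e-12 * np.linalg.norm(xh.data)

    def test_temporal_regularization_path_runs_and_descends(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        basis = estimate_spatial_basis(gt, 3)
        cfg = SparsConfig(
            L=3, H=1, b=3, lambda_H=0.5, p=2, cg_high=CGConfig(max_iters=10)
        )
        _, xh, info = solve_high_temporal(y, coils, basis, cfg, x_low=gt, return_info=True)
        assert np.all(np.diff(info.objectives) <= 1e-9)
        assert xh.data.shape == gt.data.shape

    def test_p1_regularization_path(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        basis = estimate_spatial_basis(gt, 3)
        cfg = SparsConfig(L=3, H=1, b=3, lambda_H=0.1, p=1, cg_high=CGConfig(max_iters=10))
        _, xh, info = solve_high_temporal(y, coils, basis, cfg, x_low=gt, return_info=True)
        assert np.all(np.diff(info.objectives) <= 1e-9)


class TestStageOne:
    def _dense_kspace(self, gt, coils):
        """Every frame fully sampled (dense radial)."""
        from spars.experiment import sample_radial_kspace
        from spars.encoding import encode

        N = gt.N
        nd = nyquist_spokes(N)
        T = gt.n_frames
        angles = np.tile(uniform_angles(nd), T)
        fos = np.repeat(np.arange(T), nd)
        traj = RadialTrajectory(angles, 2 * N)
        samples = encode(gt, traj, fos, coils)
        return RadialKSpace(
            samples=samples,
            trajectory=traj,
            frame_of_spoke=fos,
            n_frames=T,
            spoke_times=gt.frame_times[fos],
            dense_frames=tuple(range(T)),
        )

    def test_unregularized_dense_data_recovers_ground_truth(self):
        """With per-frame dense radial sampling and no regularization, stage 1
        recovers the (disc-bandlimited) truth to iterative tolerance."""
        from spars.encoding import disc_bandlimit
        from spars.experiment import make_fixture

        fx = make_fixture("rank3", seed=3)
        gt, coils = disc_bandlimit(fx["gt"]), fx["coils"]
        gt_small = DynamicSeries(gt.data[:, :4], gt.frame_times[:4], gt.N)
        y = self._dense_kspace(gt_small, coils)
        cfg = SparsConfig(
            L=2, H=1, b=2, lambda_L=0.0, gamma=0.0,
            cg_low=CGConfig(max_iters=300, grad_tol=1e-12),
        )
        xl = solve_low_temporal(y, coils, cfg)
        rel = np.linalg.norm(xl.data - gt_small.data) / np.linalg.norm(gt_small.data)
        assert rel < 1e-3

    def test_zero_measurements_give_zero_series(self, rank3_fixture):
        import dataclasses

        y = dataclasses.replace(
            rank3_fixture["kspace"], samples=np.zeros_like(rank3_fixture["kspace"].samples)
        )
        cfg = SparsConfig(L=3, H=1, b=2, cg_low=CGConfig(max_iters=5))
        xl = solve_low_temporal(y, rank3_fixture["coils"], cfg)
        assert np.allclose(xl.data, 0)

    def test_oversized_L_rejected(self, rank3_fixture):
        cfg = SparsConfig(L=500, H=1, b=2)
        with pytest.raises(ValueError):
            solve_low_temporal(rank3_fixture["kspace"], rank3_fixture["coils"], cfg)

    def test_paper_scale_factors_accepted(self):
        cfg = SparsConfig(L=25, H=1, b=20, lambda_L=0.25, gamma=0.5, lambda_H=0.0, p=2)
        assert cfg.lambda_L == 0.25 and cfg.gamma == 0.5
        cfg_invivo = SparsConfig(L=21, H=1, b=20, lambda_H=50.0, p=2)
        assert cfg_invivo.lambda_H == 50.0


class TestPipeline:
    def test_end_to_end_beats_zero_fill(self, rank3_fixture):
        from spars.encoding import encode_adjoint
        from spars.metrics import total_rmse
        from spars.solvers import scaled_adjoint

        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        cfg = SparsConfig(L=3, H=1, b=5, cg_low=CGConfig(max_iters=40))
        res = reconstruct_spars(y, coils, cfg)
        zf_data, _ = scaled_adjoint(y, coils)
        zf = DynamicSeries(zf_data, res.x_high.frame_times, gt.N)
        assert total_rmse(res.x_high, gt) < total_rmse(zf, gt)

    def test_deterministic(self, rank3_fixture):
        gt, y, coils = rank3_fixture["gt"], rank3_fixture["kspace"], rank3_fixture["coils"]
        cfg = SparsConfig(L=3, H=1, b=4, cg_low=CGConfig(max_iters=10))
        r1 = reconstruct_spars(y, coils, cfg)
        r2 = reconstruct_spars(y, coils, cfg)
        assert np.array_equal(r1.x_high.data, r2.x_high.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SparsConfig(L=1, H=1)
        with pytest.raises(ValueError):
            SparsConfig(L=5, H=1, b=0)
        with pytest.raises(ValueError):
            SparsConfig(L=5, H=1, p=3)
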