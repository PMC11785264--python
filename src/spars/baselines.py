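"""GRASP and GRASP-Pro comparator reconstructions.

GRASP is the temporal-TV compressed-sensing reconstruction (stage-1 objective
with the nuclear-norm weight set to zero).  GRASP-Pro constrains every
pixel's time curve to a temporal subspace V_M (right singular vectors),
either learned from a low-spatial-resolution first stage or taken from a
fully sampled ground-truth series (the simulation variant, which hands the
baseline a perfect subspace).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .encoding import CoilMaps, EncodingOperator, RadialKSpace, RadialTrajectory, rebin_kspace
from .phantom import DynamicSeries
from .recon import _normalized, _series_times
from .solvers import CGConfig, nonlinear_cg, smoothed_l1, temporal_tv, temporal_tv_adjoint

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalBasis",
    "grasp_reconstruct",
    "learn_temporal_basis",
    "ground_truth_temporal_basis",
    "grasp_pro_reconstruct",
    "lowres_reconstruct",
]


@dataclass(frozen=True)
class TemporalBasis:
    """Orthonormal temporal basis V_M (T x M)."""

    V: np.ndarray
    source: str = "learned-from-low-res"

    def __post_init__(self) -> None:
        V = np.asarray(self.V)
        object.__setattr__(self, "V", V)
        if V.ndim != 2:
            raise ValueError("V must be a matrix")
        if not np.allclose(V.conj().T @ V, np.eye(V.shape[1]), atol=1e-10):
            raise ValueError("temporal basis columns must be orthonormal")
        if self.source not in ("learned-from-low-res", "ground-truth"):
            raise ValueError(f"unknown basis source {self.source!r}")

    @property
    def M(self) -> int:
        return self.V.shape[1]


def learn_temporal_basis(x: DynamicSeries, M: int, source: str = "learned-from-low-res") -> TemporalBasis:
    """First M right singular vectors of a series' Casorati matrix."""
    if not (1 <= M <= x.n_frames):
        raise ValueError(f"M must be in [1, {x.n_frames}]")
    _, _, Vh = np.linalg.svd(x.data, full_matrices=False)
    return TemporalBasis(V=Vh.conj().T[:, :M], source=source)


def ground_truth_temporal_basis(gt: DynamicSeries, M: int) -> TemporalBasis:
    """Temporal basis from a fully sampled ground-truth series."""
    return learn_temporal_basis(gt, M, source="ground-truth")


def grasp_reconstruct(
    y: RadialKSpace,
    coils: CoilMaps,
    spokes_per_frame: int,
    lambda_scale_factor: float = 0.25,
    cg: CGConfig | None = None,
) -> DynamicSeries:
    """GRASP: temporal-TV CS reconstruction at the requested binning."""
    yb = rebin_kspace(y, spokes_per_frame)
    return _tv_solve(yb, coils, lambda_scale_factor, cg or CGConfig(max_iters=27))


def _tv_solve(yb: RadialKSpace, coils: CoilMaps, lam_factor: float, cg: CGConfig) -> DynamicSeries:
    yb, scale = _normalized(yb, coils, True)
    op = EncodingOperator.for_kspace(yb, coils, weighted=True)
    mu = cg.smoothing_mu
    ys = op.weight_samples(yb.samples)
    x0 = op.adjoint(ys)
    Ex0 = op.forward(x0)
    denom = float(np.vdot(Ex0, Ex0).real)
    x0 = (np.vdot(Ex0, ys) / denom) * x0 if denom > 0 else x0  # image-scale start

    def objective(x):
        r = op.forward(x) - ys
        f = float(np.vdot(r, r).real)
        g = 2.0 * op.adjoint(r)
        if lam_factor > 0 and x.shape[1] >= 2:
            v, gl = smoothed_l1(temporal_tv(x), mu)
            f += lam_factor * v
            g += lam_factor * temporal_tv_adjoint(gl)
        return f, g

    res = nonlinear_cg(objective, x0, cg)
    return DynamicSeries(data=res.x * scale, frame_times=_series_times(yb), N=op.N)


def grasp_pro_reconstruct(
    y: RadialKSpace,
    coils: CoilMaps,
    basis: TemporalBasis,
    lambda_scale_factor: float = 0.25,
    cg: CGConfig | None = None,
    spokes_per_frame: int = 1,
) -> DynamicSeries:
    """GRASP-Pro final stage: CS reconstruction confined to a temporal subspace.

    Optimizes coefficient maps Theta (N^2 x M) of x = Theta V^H, so every
    pixel's time curve lies exactly in span(V_M).  Initialized from the
    projection of the zero-filled adjoint onto the subspace.
    """
    cg = cg or CGConfig(max_iters=27)
    yb = rebin_kspace(y, spokes_per_frame) if spokes_per_frame > 1 else rebin_kspace(y, 1)
    if basis.V.shape[0] != yb.n_frames:
        raise ValueError(
            f"temporal basis has {basis.V.shape[0]} frames but data bin to {yb.n_frames}"
        )
    yb, scale = _normalized(yb, coils, True)
    op = EncodingOperator.for_kspace(yb, coils, weighted=True)
    mu = cg.smoothing_mu
    V = basis.V
    ys = op.weight_samples(yb.samples)
    x0 = op.adjoint(ys)
    Ex0 = op.forward(x0)
    denom = float(np.vdot(Ex0, Ex0).real)
    if denom > 0:
        x0 = (np.vdot(Ex0, ys) / denom) * x0  # image-scale start
    theta0 = x0 @ V

    def objective(theta):
        x = theta @ V.conj().T
        r = op.forward(x) - ys
        f = float(np.vdot(r, r).real)
        gx = 2.0 * op.adjoint(r)
        if lambda_scale_factor > 0 and x.shape[1] >= 2:
            v, gl = smoothed_l1(temporal_tv(x), mu)
            f += lambda_scale_factor * v
            gx += lambda_scale_factor * temporal_tv_adjoint(gl)
        return f, gx @ V

    res = nonlinear_cg(objective, theta0, cg)
    return DynamicSeries(data=(res.x @ V.conj().T) * scale, frame_times=_series_times(yb), N=op.N)


def lowres_reconstruct(
    y: RadialKSpace,
    coils: CoilMaps,
    N_low: int,
    spokes_per_frame: int,
    lambda_scale_factor: float = 0.25,
    cg: CGConfig | None = None,
    allow_equal: bool = False,
) -> DynamicSeries:
    """GRASP-Pro first stage: low-spatial-resolution TV reconstruction.

    Keeps only the central readout samples with |k| <= 0.5 N_low / N,
    rescales them to the coarser grid's frequency units, resamples the coil
    maps bilinearly (renormalized to unit root-sum-of-squares), and runs the
    TV reconstruction on the N_low grid.
    """
    N = coils.N
    if N_low > N or (N_low == N and not allow_equal):
        raise ValueError("N_low must be smaller than the native grid")
    n = y.trajectory.n_samples
    r = (np.arange(n) - n / 2.0) / n
    keep = np.abs(r) <= 0.5 * N_low / N
    if keep.sum() < 2:
        raise ValueError("central truncation leaves fewer than 2 samples")

    # scale retained radii to the coarse grid's frequency units
    r_low = r[keep] * (N / N_low)
    r_low = np.clip(r_low, -0.5, np.nextafter(0.5, 0.0))
    coords = np.stack(
        [r_low[None, :] * np.cos(y.trajectory.angles)[:, None],
         r_low[None, :] * np.sin(y.trajectory.angles)[:, None]],
        axis=-1,
    )
    traj_low = RadialTrajectory(y.trajectory.angles, int(keep.sum()), coords_override=coords)

    # bilinear coil-map resampling onto the coarse pixel-center grid
    xi = (np.arange(N_low) + 0.5) * N / N_low - 0.5
    gx, gy = np.meshgrid(xi, xi, indexing="ij")
    maps_low = np.stack(
        [
            ndimage.map_coordinates(c.real, [gx, gy], order=1, mode="nearest")
            + 1j * ndimage.map_coordinates(c.imag, [gx, gy], order=1, mode="nearest")
            for c in coils.maps
        ]
    )
    rss = np.sqrt((np.abs(maps_low) ** 2).sum(axis=0))
    rss[rss == 0] = 1.0
    coils_low = CoilMaps(maps_low / rss)

    y_low = RadialKSpace(
        samples=y.samples[:, keep, :],
        trajectory=traj_low,
        frame_of_spoke=y.frame_of_spoke,
        n_frames=y.n_frames,
        spoke_times=y.spoke_times,
        dense_frames=y.dense_frames,
    )
    yb = rebin_kspace(y_low, spokes_per_frame)
    return _tv_solve(yb, coils_low, lambda_scale_factor, cg or CGConfig(max_iters=27))
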