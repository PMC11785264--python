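"""The SPARS reconstruction pipeline.

Stage 1 solves a low-temporal-resolution compressed-sensing problem at L
spokes per frame,

    x_L = argmin ||E x - y_L||_2^2 + lambda ||TV_t x||_1 + gamma ||x||_*,

stage 2 extracts the b leading left singular vectors U_b of x_L (the spatial
subspace), and stage 3 re-bins the same measured spokes at H < L spokes per
frame and fits only per-frame subspace coefficients,

    A_H = argmin ||E U_b A - y_H||_2^2 + lambda_H ||TV_t U_b A||_p,
    x_H = U_b A_H,

so every reconstructed frame lies exactly in span(U_b).  With lambda_H = 0
the coefficient fit decouples over frames and is solved exactly by per-frame
SVD least squares; with lambda_H > 0 the joint problem is solved by nonlinear
conjugate gradient.

Regularization weights are the given scale factors times max|E^H y| at the
stage's own binning; internally the data are normalized so that this maximum
is 1 and the inverse scale is applied to all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import CoilMaps, EncodingOperator, RadialKSpace, rebin_kspace
from .phantom import DynamicSeries
from .solvers import (
    CGConfig,
    CGResult,
    ObjectiveSpec,
    nonlinear_cg,
    smoothed_l1,
    smoothed_nuclear_norm,
    temporal_tv,
    temporal_tv_adjoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SparsConfig",
    "SpatialBasis",
    "CoefficientMatrix",
    "SparsResult",
    "solve_low_temporal",
    "estimate_spatial_basis",
    "solve_high_temporal",
    "reconstruct_spars",
]


@dataclass(frozen=True)
class SparsConfig:
    """All SPARS hyperparameters.

    ``lambda_L``, ``gamma`` and ``lambda_H`` are scale factors: the weights
    actually applied are these numbers times max|E^H y| for the stage's data.
    Defaults follow the standard simulation protocol (L = 25, H = 1, b = 20,
    lambda_L = 0.25, gamma = 0.5, stage-2 lambda = 0, p = 2).
    """

    L: int = 25
    H: int = 1
    b: int = 20
    lambda_L: float = 0.25
    gamma: float = 0.5
    lambda_H: float = 0.0
    p: int = 2
    p2_squared: bool = True  # treat the p=2 stage-2 penalty as a squared L2 norm
    cg_low: CGConfig = field(default_factory=lambda: CGConfig(max_iters=27))
    cg_high: CGConfig = field(default_factory=lambda: CGConfig(max_iters=6))
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.H < self.L):
            raise ValueError("need 1 <= H < L")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.p not in (1, 2):
            raise ValueError("p must be 1 or 2")
        if min(self.lambda_L, self.gamma, self.lambda_H) < 0:
            raise ValueError("regularization scale factors must be >= 0")


@dataclass(frozen=True)
class SpatialBasis:
    """Orthonormal spatial basis U_b (N^2 x b) with its singular values."""

    U: np.ndarray  # (N*N, b), orthonormal columns ordered by singular value
    singular_values: np.ndarray  # length >= b, non-increasing

    def __post_init__(self) -> None:
        U = np.asarray(self.U)
        s = np.asarray(self.singular_values, dtype=float)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "singular_values", s)
        if U.ndim != 2:
            raise ValueError("U must be a matrix")
        gram = U.conj().T @ U
        if not np.allclose(gram, np.eye(U.shape[1]), atol=1e-10):
            raise ValueError("basis columns must be orthonormal")
        if s.size >= 2 and np.any(np.diff(s) > 1e-12 * s[0]):
            raise ValueError("singular values must be non-increasing")

    @property
    def b(self) -> int:
        return self.U.shape[1]

    def truncated(self, b: int) -> "SpatialBasis":
        if b > self.b:
            raise ValueError("cannot enlarge a basis by truncation")
        return SpatialBasis(self.U[:, :b], self.singular_values)


@dataclass(frozen=True)
class CoefficientMatrix:
    """Per-frame subspace coefficients A_H (b x T_H)."""

    A: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.A).ndim != 2:
            raise ValueError("A must be a matrix")


@dataclass
class SparsResult:
    """Everything the pipeline produced, stage by stage."""

    x_low: DynamicSeries
    basis: SpatialBasis
    coefficients: CoefficientMatrix
    x_high: DynamicSeries
    cg_low: CGResult | None = None
    cg_high: CGResult | None = None


def _normalized(y: RadialKSpace, coils: CoilMaps, enabled: bool) -> tuple[RadialKSpace, float]:
    """Scale samples so max|E^H y| = 1; returns (scaled copy, scale)."""
    from .solvers import lambda_scale

    scale = lambda_scale(y, coils)
    if not enabled or scale == 0.0:
        return y, 1.0
    return replace_samples(y, y.samples / scale), scale


def replace_samples(y: RadialKSpace, samples: np.ndarray) -> RadialKSpace:
    return RadialKSpace(
        samples=samples,
        trajectory=y.trajectory,
        frame_of_spoke=y.frame_of_spoke,
        n_frames=y.n_frames,
        spoke_times=y.spoke_times,
        dense_frames=y.dense_frames,
    )


def _series_times(y: RadialKSpace) -> np.ndarray:
    t = y.frame_times()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        t = np.arange(y.n_frames, dtype=float)
    return t


def solve_low_temporal(
    y: RadialKSpace,
    coils: CoilMaps,
    cfg: SparsConfig,
    *,
    gamma_override: float | None = None,
    return_info: bool = False,
):
    """Stage 1: TV + nuclear-norm CS reconstruction at L spokes per frame.

    Re-bins ``y`` at ``cfg.L`` spokes per frame (fully sampled frames kept
    intact), normalizes, and minimizes the composite objective by nonlinear
    CG started from the zero-filled adjoint.
    """
    total_undersampled = int(np.sum([f not in y.dense_frames for f in y.frame_of_spoke]))
    if total_undersampled and cfg.L > total_undersampled:
        raise ValueError("L exceeds the number of available under-sampled spokes")
    yL = rebin_kspace(y, cfg.L)
    yL, scale = _normalized(yL, coils, cfg.normalize)
    op = EncodingOperator.for_kspace(yL, coils, weighted=True)
    lam = cfg.lambda_L * (1.0 if cfg.normalize else scale)
    gam = (cfg.gamma if gamma_override is None else gamma_override) * (1.0 if cfg.normalize else scale)
    mu = cfg.cg_low.smoothing_mu

    spec = ObjectiveSpec(
        data_term="||E x - y_L||^2",
        regularizers=(("temporal_tv_l1", lam, 1), ("nuclear_norm", gam, 1)),
    )
    logger.info("stage 1: %s + %s", spec.data_term, spec.regularizers)

    ys = op.weight_samples(yL.samples)
    x0 = op.adjoint(ys)
    Ex0 = op.forward(x0)
    denom = float(np.vdot(Ex0, Ex0).real)
    x0 = (np.vdot(Ex0, ys) / denom) * x0 if denom > 0 else x0  # image-scale start

    def objective(x):
        r = op.forward(x) - ys
        f = float(np.vdot(r, r).real)
        g = 2.0 * op.adjoint(r)
        if lam > 0:
            v, gl = smoothed_l1(temporal_tv(x), mu)
            f += lam * v
            g += lam * temporal_tv_adjoint(gl)
        if gam > 0:
            v, gn = smoothed_nuclear_norm(x, mu)
            f += gam * v
            g += gam * gn
        return f, g

    res = nonlinear_cg(objective, x0, cfg.cg_low)
    series = DynamicSeries(data=res.x * scale, frame_times=_series_times(yL), N=op.N)
    return (series, res) if return_info else series


def estimate_spatial_basis(xL: DynamicSeries, b: int) -> SpatialBasis:
    """SVD of the stage-1 Casorati matrix; keep the b leading left vectors."""
    T = xL.n_frames
    if not (1 <= b <= min(xL.data.shape[0], T)):
        raise ValueError(f"b must be in [1, min(N^2, T_L)] = [1, {min(xL.data.shape[0], T)}]")
    U, s, _ = np.linalg.svd(xL.data, full_matrices=False)
    return SpatialBasis(U=U[:, :b], singular_values=s)


def solve_high_temporal(
    y: RadialKSpace,
    coils: CoilMaps,
    basis: SpatialBasis,
    cfg: SparsConfig,
    *,
    x_low: DynamicSeries | None = None,
    return_info: bool = False,
):
    """Stage 2: fit per-frame subspace coefficients at H spokes per frame.

    With ``cfg.lambda_H == 0`` the objective decouples over frames and each
    frame's coefficients are the exact least-squares solution of
    (E U_b) a = y_frame; otherwise the joint objective (with temporal
    regularization of order ``cfg.p``) is minimized by nonlinear CG, warm
    started from the projection of the nearest-in-time stage-1 frame.
    """
    yH = rebin_kspace(y, cfg.H)
    yH, scale = _normalized(yH, coils, cfg.normalize)
    op = EncodingOperator.for_kspace(yH, coils)
    b = basis.b
    n_meas_per_frame = np.bincount(yH.frame_of_spoke, minlength=yH.n_frames) * yH.trajectory.n_samples * yH.n_coils
    if np.any(n_meas_per_frame < b):
        logger.warning(
            "underdetermined per-frame fit: b=%d exceeds %d measurements in some frame",
            b,
            int(n_meas_per_frame.min()),
        )

    # encoded basis, per frame: G[s, m, c, j] = (E u_j) at spoke s
    T = yH.n_frames
    G = np.empty(yH.samples.shape + (b,), dtype=op.dtype)
    col = np.empty((op.N * op.N, T), dtype=op.dtype)
    for j in range(b):
        col[:] = basis.U[:, j][:, None]
        G[..., j] = op.forward(col)

    starts = np.searchsorted(yH.frame_of_spoke, np.arange(T))
    stops = np.searchsorted(yH.frame_of_spoke, np.arange(T), side="right")
    lam = cfg.lambda_H * (1.0 if cfg.normalize else scale)

    def frame_system(t):
        sl = slice(starts[t], stops[t])
        Gt = G[sl].reshape(-1, b)
        yt = yH.samples[sl].reshape(-1)
        return Gt, yt

    if lam == 0.0:
        A = np.empty((b, T), dtype=np.complex128)
        for t in range(T):
            Gt, yt = frame_system(t)
            A[:, t] = np.linalg.lstsq(Gt, yt, rcond=None)[0]
        res = None
    else:
        mu = cfg.cg_high.smoothing_mu
        if x_low is not None:
            tL = x_low.frame_times
            tH = _series_times(yH)
            nearest = np.abs(tH[:, None] - tL[None, :]).argmin(axis=1)
            A0 = basis.U.conj().T @ x_low.data[:, nearest] / max(scale, np.finfo(float).tiny)
        else:
            A0 = np.zeros((b, T), dtype=np.complex128)

        def objective(A):
            f = 0.0
            g = np.empty_like(A)
            for t in range(T):
                Gt, yt = frame_system(t)
                r = Gt @ A[:, t] - yt
                f += float(np.vdot(r, r).real)
                g[:, t] = 2.0 * (Gt.conj().T @ r)
            D = temporal_tv(basis.U @ A)
            if cfg.p == 2 and cfg.p2_squared:
                f += lam * float(np.vdot(D, D).real)
                g += lam * (basis.U.conj().T @ temporal_tv_adjoint(2.0 * D))
            elif cfg.p == 2:
                nrm = max(float(np.linalg.norm(D)), np.sqrt(mu))
                f += lam * nrm
                g += lam * (basis.U.conj().T @ temporal_tv_adjoint(D / nrm))
            else:
                v, gl = smoothed_l1(D, mu)
                f += lam * v
                g += lam * (basis.U.conj().T @ temporal_tv_adjoint(gl))
            return f, g

        res = nonlinear_cg(objective, A0, cfg.cg_high)
        A = res.x

    A = A * scale
    xH = DynamicSeries(data=basis.U @ A, frame_times=_series_times(yH), N=op.N)
    out = (CoefficientMatrix(A=A), xH)
    return out + (res,) if return_info else out


def reconstruct_spars(y: RadialKSpace, coils: CoilMaps, cfg: SparsConfig) -> SparsResult:
    """Run the full SPARS pipeline: Stage 1 -> SVD basis -> Stage 2."""
    x_low, info_low = solve_low_temporal(y, coils, cfg, return_info=True)
    basis = estimate_spatial_basis(x_low, cfg.b)
    coeffs, x_high, info_high = solve_high_temporal(
        y, coils, basis, cfg, x_low=x_low, return_info=True
    )
    return SparsResult(
        x_low=x_low,
        basis=basis,
        coefficients=coeffs,
        x_high=x_high,
        cg_low=info_low,
        cg_high=info_high,
    )
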