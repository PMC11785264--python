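"""Optimization machinery shared by all reconstructions.

Provides the regularizer building blocks (temporal total variation, smoothed
L1, smoothed nuclear norm), the data-scale estimate used to set regularization
weights, and a Polak-Ribiere nonlinear conjugate-gradient driver with a
backtracking Armijo line search.

All objectives here are real-valued functions of complex arrays.  Gradients
use the convention f(x + d) ~ f(x) + Re<g, d>, i.e. g = 2 df/d(conj x), which
is what a finite-difference check against independent real/imaginary
perturbations measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CGConfig",
    "ObjectiveSpec",
    "CGResult",
    "temporal_tv",
    "temporal_tv_adjoint",
    "smoothed_l1",
    "smoothed_nuclear_norm",
    "nonlinear_cg",
    "lambda_scale",
]


@dataclass(frozen=True)
class CGConfig:
    """Nonlinear conjugate-gradient settings.

    ``smoothing_mu`` is the corner-smoothing constant for the L1 and nuclear
    terms; it is relative to a data-normalized problem (inputs scaled so the
    zero-filled adjoint has unit maximum magnitude).
    """

    max_iters: int = 27
    grad_tol: float = 1e-6  # relative gradient-norm stopping tolerance
    initial_step: float = 1.0
    shrink: float = 0.5
    c_armijo: float = 1e-4
    max_backtracks: int = 40
    smoothing_mu: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.max_iters, self.grad_tol, self.initial_step, self.c_armijo, self.smoothing_mu) <= 0:
            raise ValueError("CGConfig fields must be positive")
        if not (0.0 < self.shrink < 1.0):
            raise ValueError("shrink factor must be in (0, 1)")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Declarative description of a composite objective, for logging/reports.

    The data-consistency term is always ||E x - y||_2^2; ``regularizers`` is a
    list of (id, weight, norm order p).
    """

    data_term: str
    regularizers: tuple[tuple[str, float, int], ...] = ()

    def __post_init__(self) -> None:
        for rid, w, p in self.regularizers:
            if w < 0:
                raise ValueError(f"regularizer {rid}: weight must be >= 0")
            if p not in (1, 2):
                raise ValueError(f"regularizer {rid}: p must be 1 or 2")


@dataclass
class CGResult:
    x: np.ndarray
    objectives: list = field(default_factory=list)
    grad_norms: list = field(default_factory=list)
    converged: bool = False
    line_search_failed: bool = False


def temporal_tv(series: np.ndarray) -> np.ndarray:
    """First differences along time of a Casorati matrix: (P, T) -> (P, T-1)."""
    X = np.asarray(series)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("temporal TV needs a (pixels, T>=2) matrix")
    return X[:, 1:] - X[:, :-1]


def temporal_tv_adjoint(diffs: np.ndarray, out_frames: int | None = None) -> np.ndarray:
    """Exact adjoint of :func:`temporal_tv`: (P, T-1) -> (P, T)."""
    D = np.asarray(diffs)
    T = D.shape[1] + 1
    if out_frames is not None and out_frames != T:
        raise ValueError("out_frames inconsistent with difference count")
    Z = np.zeros((D.shape[0], T), dtype=D.dtype)
    Z[:, 0] = -D[:, 0]
    Z[:, -1] = D[:, -1]
    if T > 2:
        Z[:, 1:-1] = D[:, :-1] - D[:, 1:]
    return Z


def smoothed_l1(values: np.ndarray, mu: float) -> tuple[float, np.ndarray]:
    """Smoothed L1 norm sum sqrt(|z|^2 + mu) and its gradient z / sqrt(|z|^2 + mu)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    z = np.asarray(values)
    w = np.sqrt(np.abs(z) ** 2 + mu)
    return float(w.sum()), z / w


def smoothed_nuclear_norm(X: np.ndarray, mu: float) -> tuple[float, np.ndarray]:
    """Smoothed nuclear norm sum sqrt(sigma_i^2 + mu) and its gradient.

    The gradient is U diag(sigma / sqrt(sigma^2 + mu)) V^H from the economy
    SVD; at mu = 0 the value is the exact nuclear norm.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    U, s, Vh = np.linalg.svd(np.asarray(X), full_matrices=False)
    w = np.sqrt(s**2 + mu)
    value = float(w.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(w > 0, s / w, 0.0)
    return value, (U * d) @ Vh


def _inner(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.real(np.vdot(a, b)))


def nonlinear_cg(
    fun: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    cfg: CGConfig | None = None,
) -> CGResult:
    """Polak-Ribiere nonlinear CG with restart and backtracking line search.

    ``fun(x)`` returns (objective value, gradient).  The line search starts
    from a warm-started step (double the last accepted one), enforces the
    Armijo sufficient-decrease condition, and shrinks by parabolic
    interpolation clipped to [0.1 t, shrink t]; the objective trace is
    therefore monotone non-increasing.  Stops at ``max_iters``, when the
    gradient norm falls below ``grad_tol`` relative to its initial value, or
    when the line search cannot find a decrease (returns the best iterate with
    ``line_search_failed`` set).
    """
    if cfg is None:
        cfg = CGConfig()
    x = np.array(x0, copy=True)
    f, g = fun(x)
    if not np.isfinite(f):
        raise ValueError("objective is not finite at the starting point")
    res = CGResult(x=x, objectives=[f], grad_norms=[float(np.linalg.norm(g))])
    g_norm0 = max(res.grad_norms[0], np.finfo(float).tiny)
    d = -g
    t_prev = cfg.initial_step
    for it in range(cfg.max_iters):
        gnorm = float(np.linalg.norm(g))
        if gnorm / g_norm0 < cfg.grad_tol:
            res.converged = True
            break
        gd = _inner(g, d)
        if gd >= 0:  # not a descent direction: restart with steepest descent
            d = -g
            gd = _inner(g, d)
            if gd >= 0:
                res.converged = True
                break
        t = min(2.0 * t_prev, 1e12)
        f_new = np.inf
        for bt in range(cfg.max_backtracks):
            f_new, g_new = fun(x + t * d)
            if np.isfinite(f_new) and f_new <= f + cfg.c_armijo * t * gd:
                break
            # parabolic interpolation through f(0), f'(0), f(t)
            denom = 2.0 * (f_new - f - gd * t)
            t_quad = -gd * t * t / denom if np.isfinite(denom) and denom > 0 else cfg.shrink * t
            t = float(np.clip(t_quad, 0.1 * t, cfg.shrink * t))
        else:
            logger.warning("line search failed after %d backtracks at iter %d", cfg.max_backtracks, it)
            res.line_search_failed = True
            break
        if bt == 0:
            # first trial accepted: refine once with the parabolic minimizer
            denom = 2.0 * (f_new - f - gd * t)
            if np.isfinite(denom) and denom > 0:
                t_quad = float(-gd * t * t / denom)
                if 0 < t_quad and abs(t_quad - t) > 1e-3 * t:
                    f_q, g_q = fun(x + t_quad * d)
                    if np.isfinite(f_q) and f_q < f_new:
                        t, f_new, g_new = t_quad, f_q, g_q
        x = x + t * d
        t_prev = t
        beta = max(0.0, _inner(g_new, g_new - g) / max(gnorm**2, np.finfo(float).tiny))
        d = -g_new + beta * d
        f, g = f_new, g_new
        res.objectives.append(f)
        res.grad_norms.append(float(np.linalg.norm(g)))
        logger.debug("cg iter %d: f=%.6e |g|=%.3e step=%.3e", it + 1, f, res.grad_norms[-1], t)
    else:
        res.converged = res.grad_norms[-1] / g_norm0 < cfg.grad_tol
    res.x = x
    return res


def scaled_adjoint(y, coils) -> tuple[np.ndarray, float]:
    """Image-scale zero-filled reconstruction of radial k-space data.

    Computes the density-compensated adjoint E^H W y (the gridding
    zero-filled reconstruction) and rescales it by the least-squares-optimal
    scalar alpha so that it sits at the intensity scale of the underlying
    image.  Returns (alpha E^H W y, alpha).
    """
    from .encoding import EncodingOperator

    op = EncodingOperator.for_kspace(y, coils, weighted=True)
    ys = op.weight_samples(y.samples)
    x0 = op.adjoint(ys)
    Ex0 = op.forward(x0)
    denom = float(np.vdot(Ex0, Ex0).real)
    alpha = complex(np.vdot(Ex0, ys) / denom) if denom > 0 else 0.0
    return alpha * x0, alpha


def lambda_scale(y, coils, N: int | None = None) -> float:
    """Data intensity scale used to set regularization weights.

    Returns the maximum magnitude over pixels and frames of the image-scale
    zero-filled reconstruction (:func:`scaled_adjoint`), i.e. the peak
    intensity of the unregularized first-look image.  Regularization weights
    are specified as multiples of this number.  Zero (with a warning) for
    all-zero data; homogeneous of degree 1 in ``y``.
    """
    x0, _ = scaled_adjoint(y, coils)
    m = float(np.max(np.abs(x0)))
    if m == 0.0:
        logger.warning("lambda_scale: data are identically zero; regularizers vanish")
    return m
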