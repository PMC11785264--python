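"""Reconstruction-quality metrics for dynamic series.

All RMSEs are computed on the magnitude of the complex residual x - gt, so a
reconstruction with spurious phase is penalized even when the ground truth is
real.  The three views are means of the same squared residuals, hence

    mean_t rmse_over_time(t)^2 = mean_p rmse_over_space(p)^2 = total_rmse^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DynamicSeries

__all__ = [
    "RmseReport",
    "rmse_over_time",
    "rmse_over_space",
    "total_rmse",
    "rmse_report",
    "extract_timecurve",
]


def _residual(x: DynamicSeries, gt: DynamicSeries) -> np.ndarray:
    if x.data.shape != gt.data.shape:
        raise ValueError(f"shape mismatch: {x.data.shape} vs {gt.data.shape}")
    return np.abs(x.data - gt.data) ** 2


def rmse_over_time(x: DynamicSeries, gt: DynamicSeries) -> np.ndarray:
    """Per-frame RMSE over all pixels (length T)."""
    return np.sqrt(_residual(x, gt).mean(axis=0))


def rmse_over_space(x: DynamicSeries, gt: DynamicSeries) -> np.ndarray:
    """Per-pixel RMSE over all frames, as an N x N map."""
    return np.sqrt(_residual(x, gt).mean(axis=1)).reshape(x.N, x.N)


def total_rmse(x: DynamicSeries, gt: DynamicSeries) -> float:
    """RMS of all residuals over pixels and frames."""
    return float(np.sqrt(_residual(x, gt).mean()))


@dataclass(frozen=True)
class RmseReport:
    rmse_over_time: np.ndarray
    rmse_over_space: np.ndarray
    total: float

    def __post_init__(self) -> None:
        if np.any(self.rmse_over_time < 0) or np.any(self.rmse_over_space < 0) or self.total < 0:
            raise ValueError("RMSE values must be non-negative")


def rmse_report(x: DynamicSeries, gt: DynamicSeries) -> RmseReport:
    return RmseReport(
        rmse_over_time=rmse_over_time(x, gt),
        rmse_over_space=rmse_over_space(x, gt),
        total=total_rmse(x, gt),
    )


def extract_timecurve(x: DynamicSeries, pixel) -> np.ndarray:
    """Signal magnitude over time at one pixel ((i, j) pair or flat index)."""
    if np.ndim(pixel) == 1 or isinstance(pixel, (tuple, list)):
        i, j = pixel
        if not (0 <= i < x.N and 0 <= j < x.N):
            raise IndexError(f"pixel {pixel} out of range for N={x.N}")
        flat = i * x.N + j
    else:
        flat = int(pixel)
        if not (0 <= flat < x.N * x.N):
            raise IndexError(f"pixel index {flat} out of range")
    return np.abs(x.data[flat, :])
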