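"""Golden-angle radial k-space encoding.

Conventions (fixed so that oracle DFT sums are bit-stable):

* frequencies are in cycles per pixel spacing, in [-0.5, 0.5);
* image coordinates are pixel-centered with the origin at index N/2
  (even N), i.e. x = i - N//2;
* the forward transform is the plain sum
  F[k] = sum_x image(x) exp(-2 pi i k.x) and the adjoint is its exact
  conjugate transpose — no density compensation, no normalization.

The transform is evaluated exactly: for a point k = (kx, ky) the 2-D
exponential separates into an outer product, so samples for a whole spoke
reduce to two small matrix products.  This makes the operator exact while
remaining fast at the package's problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "GOLDEN_ANGLE",
    "RadialTrajectory",
    "CoilMaps",
    "RadialKSpace",
    "FrameBinning",
    "golden_angle_angles",
    "uniform_angles",
    "radial_sample_coords",
    "nufft_forward",
    "nufft_adjoint",
    "ramp_sample_weights",
    "EncodingOperator",
    "encode",
    "encode_adjoint",
    "bin_spokes",
    "rebin_kspace",
    "nyquist_spokes",
    "disc_bandlimit",
    "hit_count_map",
    "underdetermined_fraction",
    "coefficient_counts",
]

#: golden-angle increment, pi (3 - sqrt 5) radians = 137.5077640...  degrees
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def golden_angle_angles(n_spokes: int, start_index: int = 0) -> np.ndarray:
    """Spoke angles (k * golden angle) mod pi, k = start_index .. +n_spokes.

    Angles live on the half circle [0, pi): a spoke and its 180-degree
    rotation sample the same line through the k-space origin.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    k = np.arange(start_index, start_index + n_spokes)
    return (k * GOLDEN_ANGLE) % np.pi


def uniform_angles(n_spokes: int) -> np.ndarray:
    """Uniformly spaced spoke angles on [0, pi) (fully sampled radial frame)."""
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    return np.arange(n_spokes) * np.pi / n_spokes


def nyquist_spokes(N: int) -> int:
    """Spokes needed for a fully sampled radial frame: ceil(pi/2 * N)."""
    return int(np.ceil(np.pi / 2.0 * N))


def radial_sample_coords(angle: float, n_samples: int) -> np.ndarray:
    """(n_samples, 2) frequency coordinates of one radial readout.

    Radii are (j - n/2)/n for j = 0..n-1, so the line passes through the
    exact origin sample when n_samples is even.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    r = (np.arange(n_samples) - n_samples / 2.0) / n_samples
    return np.stack([r * np.cos(angle), r * np.sin(angle)], axis=-1)


@dataclass(frozen=True)
class RadialTrajectory:
    """A set of radial spokes: per-spoke angles plus a shared readout.

    ``coords_override`` replaces the standard readout coordinates (used e.g.
    when a readout is truncated and rescaled for a low-resolution grid).
    """

    angles: np.ndarray  # (S,), radians in [0, pi)
    n_samples: int
    coords_override: np.ndarray | None = None  # (S, n_samples, 2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.atleast_1d(np.asarray(self.angles, dtype=float)))
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.coords_override is not None:
            c = np.asarray(self.coords_override, dtype=float)
            if c.shape != (self.angles.size, self.n_samples, 2):
                raise ValueError("coords_override must be (S, n_samples, 2)")
            object.__setattr__(self, "coords_override", c)

    @property
    def n_spokes(self) -> int:
        return self.angles.size

    @cached_property
    def kcoords(self) -> np.ndarray:
        """(S, n_samples, 2) frequency coordinates, |k| <= 0.5."""
        if self.coords_override is not None:
            return self.coords_override
        return np.stack([radial_sample_coords(a, self.n_samples) for a in self.angles])


@dataclass(frozen=True)
class CoilMaps:
    """Complex receiver sensitivity maps, one N x N grid per coil."""

    maps: np.ndarray  # (C, N, N)

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.complex128)
        if m.ndim == 2:
            m = m[None]
        if m.ndim != 3 or m.shape[0] < 1 or m.shape[1] != m.shape[2]:
            raise ValueError("maps must be (C, N, N) with C >= 1")
        object.__setattr__(self, "maps", m)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def N(self) -> int:
        return self.maps.shape[1]

    @classmethod
    def uniform(cls, N: int, n_coils: int = 1) -> "CoilMaps":
        return cls(np.ones((n_coils, N, N)))


@dataclass(frozen=True)
class FrameBinning:
    """Assignment of temporally ordered spokes to frames.

    ``frame_of_spoke`` is -1 for spokes dropped as a trailing remainder.
    """

    spokes_per_frame: int
    frame_of_spoke: np.ndarray  # (S,), int, -1 = dropped
    n_frames: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frame_of_spoke, dtype=int)
        object.__setattr__(self, "frame_of_spoke", f)
        kept = f[f >= 0]
        if kept.size and np.any(np.diff(kept) < 0):
            raise ValueError("frame assignment must be non-decreasing")
        if self.n_frames > 0 and set(range(self.n_frames)) - set(kept.tolist()):
            raise ValueError("every frame must own at least one spoke")


def bin_spokes(n_spokes: int, spokes_per_frame: int) -> FrameBinning:
    """Group consecutive spokes into frames of ``spokes_per_frame`` each.

    n_frames = floor(n_spokes / spokes_per_frame); trailing remainder spokes
    are dropped (marked -1) so every frame carries the same measurement count.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    if spokes_per_frame > n_spokes:
        raise ValueError("spokes_per_frame exceeds the number of spokes")
    n_frames = n_spokes // spokes_per_frame
    f = np.arange(n_spokes) // spokes_per_frame
    f[n_frames * spokes_per_frame:] = -1
    return FrameBinning(spokes_per_frame=spokes_per_frame, frame_of_spoke=f, n_frames=n_frames)


@dataclass
class RadialKSpace:
    """Measured radial samples organized by spoke and coil.

    ``frame_of_spoke`` gives the temporal binning currently in force;
    ``dense_frames`` lists frames that are fully sampled (e.g. the first and
    last frame of the simulation protocol) — ``rebin_kspace`` keeps those
    intact and regroups only the under-sampled stream.
    """

    samples: np.ndarray  # (S, n_samples, C) complex
    trajectory: RadialTrajectory
    frame_of_spoke: np.ndarray  # (S,) int
    n_frames: int
    spoke_times: np.ndarray | None = None  # seconds, (S,)
    dense_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim == 2:
            self.samples = self.samples[:, :, None]
        self.frame_of_spoke = np.asarray(self.frame_of_spoke, dtype=int)
        S, n_samp, _ = self.samples.shape
        if S != self.trajectory.n_spokes or n_samp != self.trajectory.n_samples:
            raise ValueError("samples shape does not match trajectory")
        if self.frame_of_spoke.shape != (S,):
            raise ValueError("frame_of_spoke must have one entry per spoke")
        if np.any(np.diff(self.frame_of_spoke) < 0):
            raise ValueError("frame_of_spoke must be non-decreasing")
        owned = np.unique(self.frame_of_spoke)
        if not np.array_equal(owned, np.arange(self.n_frames)):
            raise ValueError("every frame must own at least one spoke")
        if self.spoke_times is not None:
            self.spoke_times = np.asarray(self.spoke_times, dtype=float)
            if self.spoke_times.shape != (S,):
                raise ValueError("spoke_times must have one entry per spoke")

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]

    def frame_times(self) -> np.ndarray:
        """Per-frame timestamp: mean acquisition time of the frame's spokes."""
        if self.spoke_times is None:
            return np.arange(self.n_frames, dtype=float)
        sums = np.bincount(self.frame_of_spoke, weights=self.spoke_times, minlength=self.n_frames)
        cnts = np.bincount(self.frame_of_spoke, minlength=self.n_frames)
        return sums / cnts


def rebin_kspace(y: RadialKSpace, spokes_per_frame: int) -> RadialKSpace:
    """Re-organize measured spokes at a new temporal resolution.

    Fully sampled frames (``y.dense_frames``) are preserved as their own
    frames.  Between them, contiguous runs of under-sampled spokes are grouped
    ``spokes_per_frame`` at a time in acquisition order; each run's trailing
    remainder is dropped.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    dense = set(y.dense_frames)
    keep = np.ones(y.trajectory.n_spokes, dtype=bool)
    new_frame = np.full(y.trajectory.n_spokes, -1, dtype=int)

    next_frame = 0
    new_dense: list[int] = []
    i = 0
    S = y.trajectory.n_spokes
    fos = y.frame_of_spoke
    while i < S:
        f = fos[i]
        j = i
        while j < S and fos[j] == f:
            j += 1
        if f in dense:
            new_frame[i:j] = next_frame
            new_dense.append(next_frame)
            next_frame += 1
            i = j
        else:
            # extend the run across consecutive under-sampled frames
            while j < S and fos[j] not in dense:
                j += 1
            run = j - i
            n_groups = run // spokes_per_frame
            if n_groups == 0:
                keep[i:j] = False
            else:
                g = np.arange(run) // spokes_per_frame
                g[n_groups * spokes_per_frame:] = -1
                sel = g >= 0
                new_frame[i:j][sel] = next_frame + g[sel]
                keep[i:j][~sel] = False
                next_frame += n_groups
            i = j

    idx = np.flatnonzero(keep & (new_frame >= 0))
    co = y.trajectory.coords_override
    return RadialKSpace(
        samples=y.samples[idx],
        trajectory=RadialTrajectory(
            y.trajectory.angles[idx],
            y.trajectory.n_samples,
            coords_override=None if co is None else co[idx],
        ),
        frame_of_spoke=new_frame[idx],
        n_frames=next_frame,
        spoke_times=None if y.spoke_times is None else y.spoke_times[idx],
        dense_frames=tuple(new_dense),
    )


# ---------------------------------------------------------------------------
# exact non-uniform DFT
# ---------------------------------------------------------------------------


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[None, :]
    if coords.shape[-1] != 2:
        raise ValueError("coords must be (..., 2)")
    if np.any(coords < -0.5) or np.any(coords >= 0.5):
        raise ValueError("frequency coordinates must lie in [-0.5, 0.5)")
    return coords.reshape(-1, 2)


def _factors(coords: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Separable phase factors A, B with A[m, i] = exp(-2 pi i kx_m (i - N//2))."""
    x = np.arange(N) - N // 2
    A = np.exp(-2j * np.pi * np.outer(coords[:, 0], x))
    B = np.exp(-2j * np.pi * np.outer(coords[:, 1], x))
    return A, B


def nufft_forward(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Exact non-uniform DFT of an N x N image at arbitrary frequencies.

    Returns one complex sample per coordinate row.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    flat = _check_coords(coords)
    A, B = _factors(flat, image.shape[0])
    return np.einsum("mj,mj->m", A @ image, B, optimize=True)


def nufft_adjoint(samples: np.ndarray, coords: np.ndarray, N: int) -> np.ndarray:
    """Exact adjoint of :func:`nufft_forward` (conjugate-transpose sum)."""
    flat = _check_coords(coords)
    s = np.asarray(samples).reshape(-1)
    if s.size != flat.shape[0]:
        raise ValueError("one sample per coordinate required")
    A, B = _factors(flat, N)
    return A.conj().T @ (s[:, None] * B.conj())


# ---------------------------------------------------------------------------
# dynamic-series encoding operator  E = Phi F B
# ---------------------------------------------------------------------------


def ramp_sample_weights(trajectory: RadialTrajectory) -> np.ndarray:
    """Radial density-compensation weights, one per readout sample.

    Proportional to |k| (ramp filter), floored at half the readout step for
    the origin sample, and normalized to unit maximum.  Folding the square
    root of these weights into the encoding operator and data re-weights the
    least-squares data term by the inverse sampling density, which
    conditions iterative solves the way gridding reconstruction does.
    """
    n = trajectory.n_samples
    r = np.abs((np.arange(n) - n / 2.0) / n)
    w = np.maximum(r, 0.5 / n)
    return w / w.max()


class EncodingOperator:
    """Forward/adjoint radial encoding of a dynamic series.

    Applies, per spoke, the exact NDFT of the coil-weighted image of the frame
    that owns the spoke.  The adjoint conjugate-weights and coil-sums.  The
    per-spoke separable phase factors are precomputed once.

    ``sample_weights`` (per readout sample) fold sqrt-density-compensation
    into the operator: forward output and adjoint input are multiplied by
    sqrt(w).  The forward/adjoint pair remains exactly adjoint.
    """

    def __init__(
        self,
        trajectory: RadialTrajectory,
        frame_of_spoke: np.ndarray,
        n_frames: int,
        coils: CoilMaps,
        dtype=np.complex128,
        sample_weights: np.ndarray | None = None,
    ):
        self.traj = trajectory
        self.frame_of_spoke = np.asarray(frame_of_spoke, dtype=int)
        if np.any(np.diff(self.frame_of_spoke) < 0):
            raise ValueError("frame_of_spoke must be non-decreasing")
        self.n_frames = int(n_frames)
        self.coils = coils
        self.N = coils.N
        self.dtype = np.dtype(dtype)
        coords = trajectory.kcoords  # (S, n, 2)
        x = np.arange(self.N) - self.N // 2
        self._A = np.exp(-2j * np.pi * coords[:, :, 0, None] * x).astype(self.dtype)
        self._B = np.exp(-2j * np.pi * coords[:, :, 1, None] * x).astype(self.dtype)
        if sample_weights is not None:
            sw = np.asarray(sample_weights, dtype=float)
            if sw.shape != (trajectory.n_samples,):
                raise ValueError("sample_weights must have one entry per readout sample")
            self.sqrt_weights = np.sqrt(sw)
        else:
            self.sqrt_weights = None
        # contiguous spoke ranges per frame (frame_of_spoke is sorted)
        self._starts = np.searchsorted(self.frame_of_spoke, np.arange(self.n_frames))
        self._stops = np.searchsorted(self.frame_of_spoke, np.arange(self.n_frames), side="right")

    @classmethod
    def for_kspace(
        cls, y: RadialKSpace, coils: CoilMaps, dtype=np.complex128, weighted: bool = False
    ) -> "EncodingOperator":
        sw = ramp_sample_weights(y.trajectory) if weighted else None
        return cls(y.trajectory, y.frame_of_spoke, y.n_frames, coils, dtype=dtype, sample_weights=sw)

    def weight_samples(self, samples: np.ndarray) -> np.ndarray:
        """Apply sqrt(w) to measured samples (identity when unweighted)."""
        if self.sqrt_weights is None:
            return samples
        return samples * self.sqrt_weights[None, :, None]

    def forward(self, casorati: np.ndarray) -> np.ndarray:
        """(N^2, T) series -> (S, n_samples, C) samples."""
        T = casorati.shape[1]
        if T != self.n_frames or casorati.shape[0] != self.N * self.N:
            raise ValueError("series shape does not match operator")
        imgs = np.ascontiguousarray(
            casorati.reshape(self.N, self.N, T).transpose(2, 0, 1)
        ).astype(self.dtype, copy=False)  # (T, N, N)
        out = np.empty((self.traj.n_spokes, self.traj.n_samples, self.coils.n_coils), dtype=self.dtype)
        per_spoke = imgs[self.frame_of_spoke]  # (S, N, N) gather
        for c in range(self.coils.n_coils):
            weighted = per_spoke * self.coils.maps[c].astype(self.dtype)
            tmp = np.matmul(self._A, weighted)  # (S, n, N)
            out[:, :, c] = np.einsum("smy,smy->sm", tmp, self._B)
        if self.sqrt_weights is not None:
            out *= self.sqrt_weights[None, :, None]
        return out

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """(S, n_samples, C) samples -> (N^2, T) series (exact adjoint)."""
        samples = np.asarray(samples)
        if samples.ndim == 2:
            samples = samples[:, :, None]
        S, n, C = samples.shape
        if S != self.traj.n_spokes or n != self.traj.n_samples or C != self.coils.n_coils:
            raise ValueError("samples shape does not match operator")
        if self.sqrt_weights is not None:
            samples = samples * self.sqrt_weights[None, :, None]
        acc = np.zeros((self.n_frames, self.N, self.N), dtype=np.complex128)
        Ah = self._A.conj().transpose(0, 2, 1)  # (S, N, n)
        Bc = self._B.conj()
        for c in range(self.coils.n_coils):
            tmp = samples[:, :, c, None].astype(self.dtype) * Bc  # (S, n, N)
            per_spoke = np.matmul(Ah, tmp)  # (S, N, N)
            per_spoke = per_spoke * self.coils.maps[c].conj().astype(self.dtype)
            for f in range(self.n_frames):
                s0, s1 = self._starts[f], self._stops[f]
                acc[f] += per_spoke[s0:s1].sum(axis=0)
        return acc.transpose(1, 2, 0).reshape(self.N * self.N, self.n_frames).astype(self.dtype, copy=False)


def encode(series, trajectory: RadialTrajectory, binning, coils: CoilMaps) -> np.ndarray:
    """Functional wrapper: sample a DynamicSeries along a binned trajectory.

    ``binning`` may be a FrameBinning or a raw frame_of_spoke array; spokes
    marked -1 are skipped.  Returns (S_kept, n_samples, C) samples.
    """
    fos = binning.frame_of_spoke if isinstance(binning, FrameBinning) else np.asarray(binning, dtype=int)
    kept = fos >= 0
    traj = RadialTrajectory(trajectory.angles[kept], trajectory.n_samples)
    op = EncodingOperator(traj, fos[kept], series.n_frames, coils)
    return op.forward(series.data)


def encode_adjoint(y: RadialKSpace, coils: CoilMaps, N: int | None = None):
    """Zero-filled adjoint reconstruction E^H y as a DynamicSeries."""
    from .phantom import DynamicSeries  # local import to avoid cycle

    op = EncodingOperator.for_kspace(y, coils)
    data = op.adjoint(y.samples)
    times = y.frame_times()
    if times.size > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(y.n_frames, dtype=float)
    return DynamicSeries(data=data, frame_times=times, N=op.N)


# ---------------------------------------------------------------------------
# k-t determinedness analysis
# ---------------------------------------------------------------------------


def disc_bandlimit(series):
    """Project a dynamic series onto the disc-bandlimited spectrum.

    Radial readouts sample only the inscribed disc |k| <= 0.5 of the k-space
    square; image content whose spectrum lies in the corners is essentially
    unobserved by any radial acquisition.  This helper zeroes that corner
    spectrum (per frame, via FFT with the package's pixel-centered
    convention), yielding the component of a series that radial data can
    actually determine — useful as the ground truth in exact-recovery tests.
    """
    from .phantom import DynamicSeries

    N = series.N
    k = (np.arange(N) - N // 2) / N
    mask = (k[:, None] ** 2 + k[None, :] ** 2) <= 0.25
    imgs = series.frames().transpose(2, 0, 1)
    out = np.empty_like(imgs, dtype=complex)
    for i, im in enumerate(imgs):
        K = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(im)))
        out[i] = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(K * mask)))
    data = out.transpose(1, 2, 0).reshape(N * N, series.n_frames)
    return DynamicSeries(data=data, frame_times=series.frame_times, N=N)


def hit_count_map(traj: RadialTrajectory, N: int) -> np.ndarray:
    """Nearest-neighbour re-gridding census of a radial trajectory.

    Each sample increments the Cartesian cell nearest to it on an N x N grid;
    total counts are conserved exactly.
    """
    coords = traj.kcoords.reshape(-1, 2)
    idx = np.rint(coords * N).astype(int) + N // 2
    np.clip(idx, 0, N - 1, out=idx)
    counts = np.zeros((N, N), dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1]), 1)
    return counts


def underdetermined_fraction(counts: np.ndarray, M: int) -> float:
    """Fraction of in-disc k-space cells with fewer than M hits.

    A cell sampled fewer than M times across the series cannot determine M
    temporal-coefficient unknowns, so this is the underdetermined share of k-t
    space for an M-vector temporal subspace.  Non-decreasing in M; cells never
    sampled count as underdetermined for any M >= 1.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    counts = np.asarray(counts)
    N = counts.shape[0]
    x = np.arange(N) - N // 2
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    disc = r2 <= (N / 2.0) ** 2
    return float(np.mean(counts[disc] < M))


def coefficient_counts(N: int, T: int, M: int) -> tuple[int, int]:
    """Unknown-coefficient counts: (temporal-subspace N^2 M, spatial-subspace M T)."""
    if N <= 0 or T <= 0 or M < 0:
        raise ValueError("N and T must be positive, M non-negative")
    return (N * N * M, M * T)
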