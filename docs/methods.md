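# Methods

This note documents the models, numerical choices, and limitations behind
`spars-mri`. It is written for readers who want to understand what the
package computes and why, at the level of detail a reviewer of the code
would need.

## Problem setting

Dynamic contrast-enhanced (DCE) MRI acquires serial images during the
passage of an intravenous contrast bolus. Golden-angle radial acquisition
samples one straight line ("spoke") of 2-D k-space per repetition, rotating
by ~137.508° between spokes, so temporal resolution is set retrospectively
by how many consecutive spokes are grouped into one frame. At one spoke per
frame the per-frame inverse problem is hopelessly underdetermined for
direct reconstruction; the package implements a spatial-subspace approach
(SPARS) that makes it overdetermined, plus the GRASP and GRASP-Pro
compressed-sensing reconstructions it is compared against.

## The reconstruction model

Let the dynamic series be a Casorati matrix `x ∈ C^{N²×T}` (one vectorized
image per column) and `E = Φ F B` the encoding operator (coil weighting `B`,
non-uniform Fourier transform `F`, k-t sampling pattern `Φ`).

**Stage 1 — low-temporal-resolution CS.** Spokes are re-binned at `L`
spokes/frame and

    x̂_L = argmin ‖E x − y_L‖₂² + λ ‖TV_t x‖₁ + γ ‖x‖_*

is solved by nonlinear conjugate gradient, where `TV_t` is the
frame-to-frame first difference and `‖·‖_*` the nuclear norm (L1 on
singular values), both smoothed (see Numerics). Defaults `λ = 0.25·s`,
`γ = 0.5·s` with `s` the data intensity scale defined below.

**Stage 2 — spatial basis and coefficient fit.** The SVD of `x̂_L` gives an
orthonormal spatial basis `U_b ∈ C^{N²×b}` (left singular vectors). The same
measured spokes are re-binned at `H < L` spokes/frame (typically `H = 1`)
and only per-frame coefficients are fit:

    Â_H = argmin ‖E U_b A − y_H‖₂² + λ_H ‖TV_t U_b A‖_p ,   x̂_H = U_b Â_H .

With `λ_H = 0` (the default, matching the simulation protocol) the problem
decouples over frames and each frame's `b` coefficients are the exact
least-squares solution of a small dense system, solved by SVD (`lstsq`);
nonlinear CG is used only when `λ_H > 0`. This is the reason SPARS is
overdetermined at 1 spoke/frame: a frame with `m` k-space samples supports
up to `m` basis coefficients, and `m = n_samples ≫ b`.

**Baselines.** GRASP is stage 1 with `γ = 0` at a chosen binning (2
spokes/frame by default for 1-spoke data). GRASP-Pro constrains every
pixel's time curve to a temporal subspace `V_M` (right singular vectors),
optimizing coefficient maps `Θ ∈ C^{N²×M}` of `x = Θ V_Mᴴ`; `V_M` is either
learned from a low-spatial-resolution first stage (central k-space
truncation → coarse-grid GRASP → SVD) or taken from the fully sampled
ground truth (the simulation variant, which deliberately hands the baseline
a perfect subspace).

## Digital phantom

Tissue classes are piecewise-constant regions (ellipses/rectangles,
priority-painted) with parameters `T1` (s), `Ktrans` (min⁻¹), `ve`, `vp`,
`M0`. The signal chain per class:

1. **Arterial input function.** Parker population model (two Gaussians plus
   a sigmoid-gated exponential, parameterized in minutes), calibrated at
   0.1 mmol/kg and scaled linearly by `dose/0.1`; identically zero for
   t ≤ 0. Contrast arrives at a configurable frame (default 2), so the
   first frames are guaranteed pre-contrast baseline.
2. **Extended Tofts kinetics.**
   `C_t = vp·C_p + Ktrans ∫ C_p(u) e^{−kep(t−u)} du`, `kep = Ktrans/ve`.
   The convolution uses the exact recursive solution of the exchange ODE
   for piecewise-linear `C_p`, which is unbiased at any step size (a naive
   Riemann sum is visibly biased at 0.18 s steps for fast `kep`).
3. **SPGR signal.** `R1 = 1/T1 + r1·C_t`,
   `S = M0 sin(FA)(1−e^{−TR·R1})/(1−cos(FA) e^{−TR·R1})`; defaults
   `r1 = 4.1 L mmol⁻¹s⁻¹`, `TR = 6.2 ms`, `FA = 20°`, dose 0.05 mmol/kg,
   0.18 s per spoke.

Because each pixel's curve depends only on its class, the noiseless
Casorati matrix is an exact sum of (indicator × curve) outer products and
its rank is bounded by the number of distinct parameter tuples — the basis
of the rank tests. Ground truth is real and non-negative, stored as complex
with zero phase. No noise, motion, or field inhomogeneity is modeled.

**Sampling protocol.** The first and last frames are acquired fully sampled
as dense radial frames with `ceil(π/2·N)` uniformly spaced spokes (radial
Nyquist); every other frame contributes one golden-angle spoke. Readout
length defaults to `2N` (two-fold oversampling). Whether a "fully sampled"
frame should be Cartesian or dense-radial is not uniquely defined; dense
radial keeps a single encoding path and is what the package uses.

## Encoding operator and its numerics

Frequencies are in cycles per pixel spacing in `[−0.5, 0.5)`; image
coordinates are pixel-centered with the origin at index `N//2`. The
non-uniform transform is evaluated **exactly**: for each spoke the 2-D
exponential separates into an outer product, so one spoke's samples are two
small matrix products. At this package's problem sizes (N ≤ 200, ≲1500
spokes) the exact transform is faster than setting up an approximate NUFFT,
and the forward/adjoint pair is exactly adjoint by construction (verified
to 1e−5 by randomized inner-product tests, and against O(N²M) brute-force
DFT sums on small grids).

**Density weighting in iterative solves.** A radial sample distribution is
~1/|k| dense, so the unweighted normal operator `EᴴE` is center-dominated:
we measured a condition number ≈ 2·10⁵ for a *fully sampled* radial frame
at N = 16, at which nonlinear CG stalls far from the least-squares
solution. All image-domain iterative solves therefore minimize the
ramp-weighted data term `‖W^{1/2}(Ex − y)‖₂²` with `w ∝ max(|k|, Δk/2)`,
exactly the square-root density compensation the reference GRASP solver
folds into its operator. For consistent (noiseless, representable) data the
weighting leaves the solution unchanged; for inconsistent data it
re-weights residuals the same way the established implementations do. The
pure unweighted operator remains what `encode`/`encode_adjoint` expose, and
stage-2 coefficient fits (solved exactly) do not need weighting.

**Data scale and normalization.** All regularization weights are multiples
of the peak intensity of the zero-filled reconstruction, computed as the
density-compensated adjoint `Eᴴ W y` rescaled by the least-squares-optimal
scalar `α = ⟨EEᴴWy, Wy⟩-type` fit (see `solvers.scaled_adjoint`). Inputs are
normalized so this peak is 1 before solving (weights are then literally
0.25/0.5/…), and the inverse scale is applied to outputs. The same α-scaled
adjoint is the CG starting point.

**What radial data cannot determine.** Radial readouts sample only the
inscribed disc `|k| ≤ 0.5`; the corner spectrum of the k-space square is
(nearly) unobserved, with singular values ~10⁻⁵ of the largest. Exact-
recovery tests therefore compare against the disc-bandlimited projection of
the truth (`encoding.disc_bandlimit`) and to iterative tolerance (1e−3),
not machine precision.

## Solver

Polak–Ribière nonlinear CG with restart on non-descent directions and a
backtracking Armijo line search (`c = 1e−4`): the initial step doubles the
previously accepted one, failed steps shrink by parabolic interpolation
(clipped to [0.1, 0.5]·t), and an accepted first trial is refined once with
the parabolic minimizer. The objective trace is monotone non-increasing by
construction. L1 and nuclear terms use the standard smoothing
`|z| ≈ sqrt(|z|² + μ)` with `μ = 1e−6` on the normalized (unit-peak)
problem; the nuclear-norm gradient is `U diag(σ/\sqrt{σ²+μ}) Vᴴ` from an
economy SVD, cheap because stage-1 matrices have at most a few dozen
columns. Default iteration caps are 27 (stage 1) and 6 (stage 2 with
`λ_H > 0`), both overridable; simulation experiments use larger caps in
lieu of a convergence criterion.

## The standard synthetic experiment

The scaled-down study conditions used by the test suite and
`scripts/acceptance.py` (chosen once, as the package's desk-scale
translation of the full protocol):

* Grid `N = 64`, `T = 200` frames, one golden-angle spoke per frame, dense
  first/last frames, single uniform coil, readout 128 samples, no noise.
* **Frame spacing 0.9 s**, so 200 frames span the same ~3 minutes of
  contrast dynamics as the full-scale protocol (1000 frames × 0.18 s).
  This matters: truncating instead to 200 × 0.18 s = 36 s keeps only the
  bolus peak, collapses the temporal rank of the ground truth (washout
  dynamics are what distinguish tissue curves), and changes which
  reconstruction regime is being tested. With the 3-minute window the
  ground-truth temporal singular spectrum matches the full-scale protocol's
  (verified numerically).
* Stage 1 at `L = 5` spokes/frame, giving `T_L = 41` low-temporal frames —
  the same `T/L = 40` accounting as the full-scale protocol, and enough
  frames to support the spatial-basis sweep `b ∈ {10, 20, 40}`. (Keeping
  `L = 25` at `T = 200` would give only 10 stage-1 frames, making
  `b = 20, 40` undefined.)
* λ scale factors 0.25 (TV) and 0.5 (nuclear); stage 2 with `λ_H = 0`.
* Comparators: the optimally scaled zero-filled adjoint, and GRASP-Pro
  given the ground-truth temporal basis with `M ∈ {5, 7, 16}`.
* CG caps of 100 iterations per solve (both methods); 100- vs
  300-iteration runs were compared and change no ordering.
* The phantom is abdomen-like: ~10 organ regions plus 34 small patches
  with seeded random kinetic parameters on concentric rings (emulating
  in-body pixels outside named anatomy; the air background does not
  enhance), ~45 distinct classes so that the label complexity exceeds the
  largest swept basis size. A separate 8-class phantom is used for rank
  tests and the ground-truth-basis recovery test.

**What the desk-scale comparison shows — and does not.** The phantom is
piecewise-constant, noiseless, single-coil, and motion-free, so it probes
the algorithmic claims (determinedness, subspace fidelity, oracle
equivalences) rather than robustness to noise, coil calibration, or
motion. Two scale effects matter when reading the RMSE comparison:

* Even with 45 tissue classes, all time curves belong to the ~10–16
  dimensional extended-Tofts family of a single shared input function, so
  the noiseless Casorati matrix has effective rank ≲ 16 and a
  *ground-truth* temporal basis with `M = 5` already spans 99.6% of the
  signal. Handing that oracle basis to GRASP-Pro therefore removes most of
  its real-world handicap (estimating the subspace from corrupted data).
* SPARS's error is floored by how well the *learned* spatial basis spans
  the truth, i.e. by stage-1 CS quality; at a 64-grid, single coil, and
  `L = 5` the stage-1 solve is 20× undersampled and plateaus near 17%
  relative error (verified not to be an iteration-count artifact).

Under these conditions SPARS reconstructs single-spoke frames at ~6× lower
RMSE than the zero-filled reconstruction and reproduces the basis-count
behavior (`b = 20` no worse than `b = 10`; `b = 40` within 10% of
`b = 20`), while the oracle-basis GRASP-Pro attains lower total RMSE than
SPARS at this scale — the acceptance suite asserts the full-scale ordering
and reports this comparison honestly as a failing check. Reproducing the
full-scale regime (200×200, 1000 frames, multi-hour per-solve convergence)
is outside the package's single-CPU test budget.

## k-t determinedness analysis

`hit_count_map` grids every radial sample to its nearest Cartesian cell
(counts conserved exactly); `underdetermined_fraction(counts, M)` is the
fraction of in-disc cells with fewer than `M` hits — cells that cannot
determine `M` per-cell temporal coefficients. For 1000 golden-angle spokes
regridded to a 200-grid at one sample per cell crossing (readout length
200), the underdetermined fraction rises steeply once `M` exceeds ~3
(3% at M = 3, 21% at M = 4, 64% at M = 6), which is the quantitative core
of the argument for spatial over temporal subspaces at high temporal
resolution. Never-sampled cells count as underdetermined for any `M ≥ 1`.

## Design choices where the design was open

* `M0` is not specified by the protocol; default 1 per class, overridable.
* Simulated images are real; complex-valued phantoms are out of scope.
* Stage-2 warm start (when CG is used): coefficients of the
  nearest-in-time stage-1 frame.
* `p = 2` in the stage-2 penalty is implemented as the squared L2 norm
  (smooth and CG-friendly); the unsquared variant and `p = 1` are
  selectable (`p2_squared=False`, `p=1`).
* Remainder spokes in re-binning are dropped, not merged, so every frame
  carries identical measurement counts.
* GRASP-Pro's first-stage coil maps are bilinearly resampled and
  renormalized to unit root-sum-of-squares; its coefficient maps are
  initialized from the projection of the scaled zero-filled adjoint.
* RMSE is computed on the magnitude of the complex residual, penalizing
  spurious phase against the real-valued ground truth.

## Known limitations

* Single 2-D slice only; no 3-D or multi-slice phantoms.
* No noise model; reconstruction quality under realistic SNR is untested.
* The exact NDFT is O(S·n·N²) per apply; at much larger grids than used
  here an approximate NUFFT would be the right tool.
* In-vivo coil-sensitivity estimation is out of scope; externally supplied
  maps are expected in the k-space container.
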