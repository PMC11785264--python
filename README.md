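# spars-mri

Spatial-subspace reconstruction (SPARS) of golden-angle radial dynamic
contrast-enhanced (DCE) MRI, with GRASP / GRASP-Pro comparators, a
Tofts/Parker digital phantom, and k-t determinedness analysis.

## Who this is for

DCE-MRI needs sub-second temporal resolution to quantify perfusion, but
high spatial resolution to see small lesions — and conventional
reconstruction forces a trade between them. This package is for MRI
reconstruction researchers who want a complete, testable reference
implementation of the spatial-subspace idea: reconstruct a full
high-resolution image from **one radial k-space spoke per time frame** by
first learning *where* signal lives (a spatial basis) from a
low-temporal-resolution reconstruction of the same data, then fitting only
a handful of per-frame basis coefficients.

## The method

With the dynamic series as a Casorati matrix `x ∈ C^{N²×T}` and encoding
operator `E = ΦFB` (coil maps, non-uniform Fourier transform, k-t
sampling):

1. **Low-temporal CS reconstruction** at `L` spokes/frame:
   `x̂_L = argmin ‖Ex − y_L‖₂² + λ‖TV_t x‖₁ + γ‖x‖_*`
2. **Spatial basis**: SVD of `x̂_L`; keep the `b` leading left singular
   vectors `U_b ∈ C^{N²×b}`.
3. **High-temporal coefficient fit** at `H < L` spokes/frame:
   `Â_H = argmin ‖E U_b A − y_H‖₂² + λ_H‖TV_t U_b A‖_p`, `x̂_H = U_b Â_H`.

At `H = 1` each frame has `n_samples ≫ b` measurements for only `b`
unknowns — an *overdetermined* per-frame fit, in contrast to
temporal-subspace methods (GRASP-Pro), which need every k-space cell to be
sampled at least `M` times across the series and become underdetermined at
high frequencies (quantified by the package's determinedness tools). Both
baselines are included, including the simulation variant that hands
GRASP-Pro a temporal basis computed from the ground truth.

The phantom module simulates the standard DCE protocol: piecewise-constant
tissue maps, Parker population arterial input function, extended Tofts
kinetics, and the spoiled-gradient-echo signal equation, sampled on a
golden-angle radial trajectory at one spoke per frame with fully sampled
first and last frames.

## Worked example

```python
import numpy as np
from spars.experiment import (standard_phantom_geometry, default_acquisition,
                              sample_radial_kspace)
from spars.phantom import build_phantom, simulate_dynamic_series, AcquisitionParams
from spars.recon import SparsConfig, reconstruct_spars
from spars.solvers import CGConfig
from spars.metrics import total_rmse

# simulate: 64x64 phantom, 200 frames spanning ~3 min, 1 spoke/frame
acq = AcquisitionParams(dt_spoke=0.9, n_frames_total=200)
ph = build_phantom(standard_phantom_geometry(N=64, seed=1), seed=1)
gt = simulate_dynamic_series(ph, acq)
y, coils = sample_radial_kspace(gt)

# reconstruct: L=8 spokes/frame stage 1, b=20 basis vectors, H=1 stage 2
cfg = SparsConfig(L=8, H=1, b=20, lambda_L=0.25, gamma=0.5, lambda_H=0.0,
                  cg_low=CGConfig(max_iters=100))
res = reconstruct_spars(y, coils, cfg)
print(f"stage-1 frames: {res.x_low.n_frames}")
print(f"total RMSE vs ground truth: {total_rmse(res.x_high, gt):.5f}")
```

prints (exact RMSE varies slightly with the seed):

```
stage-1 frames: 26
total RMSE vs ground truth: 0.00418
```

i.e. the 200-frame series reconstructed from single spokes deviates from
the noiseless ground truth by ~0.005 in the same arbitrary units as the
SPGR signal (pre-contrast tissue baseline ≈ 0.1–0.3) — compared with
≈ 0.05 for the zero-filled adjoint of the same data.

The same pipelines are available from the shell:

```
spars simulate --grid 64 --frames 200 --out k.h5 --gt-out gt.h5
spars reconstruct spars --in k.h5 --out recon.h5 --L 8 --b 20
spars evaluate --recon recon.h5 --gt gt.h5
spars determinedness --spokes 1000 --grid 200 --samples 200 --m-max 16
```

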