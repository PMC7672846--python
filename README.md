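# csiirr — missing-wedge suppression for limited-angle tomography

Electron tomography tilts a specimen through a limited angular range
(typically ±60°), leaving a wedge of Fourier space unmeasured. This
*missing wedge* elongates and streaks every direct reconstruction. This
package implements **CSIIRR** — compressed-sensing improved iterative
reconstruction–reprojection — which combines two ideas:

* **reprojection**: alternately reconstruct from the measured projections
  plus current estimates of the missing ones, then re-estimate the missing
  projections by reprojecting the reconstruction
  (`p_unknown = (1−χ_Ω)·𝓡f`, damped by a relaxation factor λ ∈ (0,1));
* **sparsity**: biological ultrastructure is sparse against solvent, so
  each reconstruction step solves `min ‖f‖₀ s.t. 𝓡f = p_known + λ·p_unknown`
  greedily by *modified matching pursuit* (MMP): per inner iteration, take
  the filtered backprojection of the sinogram residual, select the M
  largest-magnitude pixels inside the specimen support, accumulate their
  values, and recompute the residual until ‖R‖₂ < ε.

The classical baselines (FBP, IRR, IIRR, classic matching pursuit,
IRR-TV) and the evaluation suite from the field (PCC, SSIM, Fourier
ring correlation, point-to-point phase difference, log-power spectra,
leave-one-out reprojection validation) are included, along with a sparse
phantom generator and tilt-series simulator so everything runs without
external data. Real tilt series load from MRC stacks + IMOD-style
`.rawtlt` angle files. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import numpy as np
from csiirr import (PhantomSpec, NoiseSpec, ReconConfig,
                    make_sparse_phantom, simulate_tilt_series, add_noise,
                    fbp, iirr, csiirr, pcc, ssim)

truth, support = make_sparse_phantom(PhantomSpec(size=128, seed=1))
sino  = simulate_tilt_series(truth, -60, 60, 1)       # 121 measured angles
noisy = add_noise(sino, NoiseSpec(snr=1.0, seed=2))

cfg = ReconConfig()        # lambda=0.99, K=10 outer, L=50 inner, M=1% of support
for name, img in [("fbp",    fbp(noisy)),
                  ("iirr",   iirr(noisy, cfg, support=support)[0]),
                  ("csiirr", csiirr(noisy, support, cfg)[0])]:
    print(f"{name:7s} pcc={pcc(img, truth):.3f} ssim={ssim(img, truth):.3f}")
```

prints

```
fbp     pcc=0.497 ssim=0.112
iirr    pcc=0.588 ssim=0.128
csiirr  pcc=0.669 ssim=0.752
```

i.e. on an SNR=1 tilt series with a ±60° wedge, the reprojection loop
(IIRR) recovers some of what zero-filling (FBP) loses, and adding the
sparsity prior (CSIIRR) recovers substantially more — the Pearson
correlation with the ground truth rises from 0.50 to 0.67 and the
structural similarity from 0.11 to 0.75. On the noiseless series the
same ordering reads 0.856 / 0.975 / 0.996 in PCC.

The same pipeline is scriptable from the shell:

```
csiirr-bench simulate --size 128 --snr 1 --seed 1 -o sim/
csiirr-bench reconstruct --projections sim/projections.mrc \
    --tilt sim/angles.rawtlt --method csiirr --lam 0.99 \
    --outer 10 --inner 50 -o recon.mrc
csiirr-bench metrics --image-a sim/phantom.mrc --image-b recon.mrc
csiirr-bench bench loo sim/projections.mrc --angles sim/angles.rawtlt \
    --method csiirr -o loo/
```

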