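# Methods

## Problem setting

Electron tomography reconstructs a specimen's density from projections
taken over a tilt range limited to roughly ±60–70°. The unsampled
directions form the *missing wedge*: by the projection-slice theorem each
tilt at angle α measures the central line of the 2-D Fourier transform
along direction (cos α, sin α), so a limited tilt range leaves a
double-cone of Fourier space empty. Direct inversion (filtered
backprojection, FBP) then produces elongation and streak artifacts.

This package works in 2-D (one reconstruction slice per detector row; the
extension to stacks is a loop). A tilt series is a sinogram `p(s, α)` on a
detector-bin × angle grid, with an explicit boolean `known` mask: the full
angular grid covers (−90°, 90°) at the measurement increment, and the
missing wedge is simply the set of `known=False` columns.

## Operator core

* **Radon transform** — pixel-driven with linear splatting: each pixel
  deposits its value into the two detector bins bracketing its signed
  distance `s = x₁ cos α + x₂ sin α`. The image center sits at pixel
  ((N−1)/2, (N−1)/2) and bin s=0 passes through it; angles are degrees in
  every interface (α = angle between the line normal and the x₁ axis).
* **Backprojection** — the gather dual of the splat with the same weights,
  multiplied by the angular spacing Δα in radians so that FBP is
  quantitatively correct. With the angular weight off, the discrete
  backprojector is the *exact matrix transpose* of the discrete Radon
  operator. We chose the matched pixel-driven pair (rather than a
  ray-driven forward model) precisely to make the adjoint relation exact:
  the matching-pursuit reconstruction below interrogates the residual with
  the backprojected filter and behaves best when forward and backward
  operators are a true adjoint pair. Accuracy is unaffected at the scales
  used here: the projection of a uniform disk matches the analytic chord
  profile 2√(r²−s²) to <1% RMS, and per-angle mass is conserved exactly.
* **Ramp filter** — realized as FFT multiplication with the transform of
  the closed-form band-limited ramp kernel (h(0)=1/(4τ²),
  h(k)=−1/(π²k²τ²) for odd k, 0 for even k, detector spacing τ), applied
  on columns zero-padded to a power of two ≥ 2·n_bins. This is the
  standard discretization of the |ω| filter; because the kernel is exact
  in the spatial domain, the output is bit-for-bit independent of any
  extra padding, and the impulse response equals the closed-form kernel to
  machine precision. No apodization window is applied.

## Reconstruction methods

**FBP** zero-fills the wedge: `f = B(ramp(p_known))`.

**IRR / IIRR** alternate reconstruction and reprojection:
`fⁱ = B(ramp(p_known + λ·p_unknownⁱ))`, then
`p_unknownⁱ⁺¹ = (1−χ_Ω)·R(C(fⁱ))`, starting from zero wedge estimates
(so the first iterate is exactly FBP). IRR uses λ=1, IIRR damps the
estimates by λ ∈ (0,1), default 0.99. `C` applies the classical a-priori
constraints — positivity and the specimen support (inscribed disk by
default) — *to the reprojected image only*; the returned reconstruction
is the raw composite FBP. This choice matters: reprojecting the
unconstrained image feeds the wedge streaks back into the estimates and
makes the iteration degrade below FBP, whereas the constrained variant
converges monotonically (PCC 0.86 → 0.98 over ten iterations on the
noiseless benchmark). A config switch (`constrain_reprojection=False`)
restores the literal unconstrained recursion.

**IRR-TV** inserts `tv_iters` steps of smoothed total-variation gradient
descent `f ← f − d·∂TV(f)/∂f` after each reconstruction step. The TV
subgradient uses a smoothing constant δ=1e−4 under the square root; since
the smoothed subgradient is nearly sign-valued, the step size d must be
small relative to the pixel-value scale — default d=0.002 for
unit-density phantoms. Divergence (norm growth beyond 1e6× the first
iterate) raises an error.

**Modified matching pursuit (MMP)** is the sparse reconstruction step.
The dictionary atoms are the pixels of the support set T. Starting from
`f=0` and residual `R₀ = p_known + λ·p_unknown_est`, each inner iteration

1. forms the selection image `χ_T · B(ramp(R))` (the filtered
   backprojection of the residual — the natural image-domain correlate of
   the atom inner products, since `B∘ramp∘R ≈ identity`),
2. selects the M pixels of largest absolute value (ties broken by
   row-major index; re-selection allowed, coefficients accumulate),
3. adds the selection-image values to `f` at those pixels and clamps
   `f ≥ 0`,
4. recomputes the residual in full, `R = R₀ − R(f)` (chosen over
   incremental updates for numerical robustness),

and stops after L iterations or when ‖R‖₂ < ε (ℓ2 over all sinogram
entries; default ε = 1e−6·‖R₀‖, a relative form since no absolute scale
is canonical). M defaults to `round(0.01 · |T|)`. Classic MP is exactly
the M=1 case with zero wedge estimates. The nonnegativity clamp encodes
the physical prior that density is nonnegative; without it the greedy fit
semiconverges on noisy data — quality peaks within a few iterations and
then decays as the residual is driven into the noise floor — and the
method loses its advantage over the unregularized baselines. A switch
(`nonneg=False`) restores the unclamped update.

**CSIIRR** composes the two loops: K outer iterations of
(1) estimate the wedge projections by reprojecting the current sparse
estimate, `p_unknown = (1−χ_Ω)·R(f)`; (2) re-solve from scratch with MMP
on `p_known + λ·p_unknown`. Defaults follow the simulated-data protocol:
λ=0.99, K=10, L=50, m_ratio=0.01, f⁰=0.

## Synthetic data

Biological ultrastructure is sparse: bright macromolecular features in
empty solvent. The phantom generator reproduces exactly that property —
soft-edged random ellipses (radius 2.5–7 px, density 0.4–1.0) placed in a
disk of radius 0.4·N, with the nonzero fraction required to land within
±20% of a sparsity target (default 5%); the feature count is derived from
the target via the expected ellipse-union area unless given explicitly.
The support mask is the inscribed disk.

The simulator projects on the full (−90°, 90°) angular grid at the
measurement increment and zeroes the wedge columns, so downstream code
can never accidentally use wedge data. Noise is zero-mean Gaussian added
to measured columns only, with variance `var(known signal)/SNR` — SNR is
a variance ratio, and the noise law is an explicit modeling choice (no
detector/dose physics, no CTF). Default benchmark: 128×128 phantom,
−60°..60° at 1°, noiseless and SNR=1.

What the phantoms do *not* emulate: textured backgrounds, contrast
transfer, alignment errors, and the 3-D nature of real tilt series.
Passing benchmarks here demonstrates the algorithmic behavior
(wedge-information restoration, sparsity recovery, convergence order),
not end-to-end performance on micrographs.

## Metrics

PCC and SSIM (11-pixel Gaussian window, shared data range) score global
agreement with ground truth. FRC bins the normalized Fourier
cross-correlation into rings uniform in [0, 0.5] cycles/pixel (N/2 rings
by default; 1-D profiles use ±frequency pairs). The point-to-point phase
difference Δ = ||φ_a−φ_b|/π − 1| compares Fourier phases per component
(1 = identical, 0 = opposite; the formula is wrap-invariant). The
log-scaled power spectrum log(1+|F|²) visualizes the wedge; a helper
compares mean spectral power inside vs outside the wedge at matched
radii. No FRC threshold criterion (0.143/0.5) is applied — whole curves
and their means/areas are reported.

## Problem sizes and determinism

All benchmarks run at desk scale — 128² for the quality orderings and
leave-one-out, 64² for the matching-pursuit convergence comparison —
chosen so the full suite completes in minutes on one CPU while leaving
the comparative claims comfortably clear of their margins. Comparative
results are asserted as orderings, not absolute values. Every stochastic
step (phantom placement, noise) is driven by an explicit seed; methods
themselves are deterministic, so every pipeline is bit-reproducible from
its manifest.

## Known limitations

* The leave-one-out comparison by mean 1-D FRC has little statistical
  power at this scale: rings hold ~2 Fourier components, the reference
  projection is itself noisy at SNR=1, and IIRR's reprojection errors are
  largely per-ring amplitude errors that ring-normalized correlation
  ignores. The reprojection RMSE against the true held-out projection
  discriminates robustly (CSIIRR ≈ 40% lower across seeds); both numbers
  are reported.
* Greedy ℓ0 recovery offers no global optimality guarantee; with heavy
  noise the ε stopping rule should be set near the noise norm if the
  noise level is known.
* 2-D parallel-beam geometry only; no fan/cone beam, no 3-D shells, no
  alignment.
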