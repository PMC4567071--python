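# hdtv2 — second-degree total variation compressive-sensing reconstruction

Recovering an image from a small fraction of its Fourier coefficients — the
setting of compressed-sensing MRI and Fourier microscopy — needs a prior
that says what plausible images look like. First-order total variation (TV)
prefers piecewise-constant images and notoriously turns smooth intensity
ramps into blocky "staircase" artifacts. This package implements
reconstruction under the **second-degree total variation (HDTV2)** prior,
which penalizes second *directional* derivatives across all orientations and
therefore prefers piecewise-*linear* images: edges stay sharp, gradients
stay smooth, and elongated filament-like structures survive.

## The model

Given measurements `g = A f + e`, where `A = P F` selects `M` coefficients
of the unitary 2-D DFT and `e` is complex white Gaussian noise, the
reconstruction solves

```
f̂ = argmin_{f ∈ [a,b]^N}  ½‖g − A f‖² + λ · HDTV2(f)
```

with

```
HDTV2(f) = Σᵢ √( (1/2π) ∫₀^{2π} |f_{θ,2}(i)|² dθ )  =  Σᵢ ‖W₂ (V₂ f)ᵢ‖₂  =  ‖Λ₂V₂ f‖₁,₂
```

where `f_{θ,2} = S₂(θ)ᵀ G₂` is the second directional derivative,
`S₂(θ) = (cos²θ, 2cosθsinθ, sin²θ)`, `V₂` stacks the discrete second
differences `(Δxx, Δxy, Δyy)`, and `W₂ = C₂^{1/2}` is the symmetric square
root of the steering Gram matrix `C₂ = (1/8)[[3,0,1],[0,4,0],[1,0,3]]`. The
weighted-norm form makes the functional a plain analysis-sparsity norm, so
the model is solved by **forward-backward splitting**: a gradient step on
the data term followed by the box-constrained HDTV2 proximal map, itself
computed by Nesterov-accelerated projected ascent on the dual problem with
the guaranteed step `1/(24α)` (since `‖Λ₂V₂‖² ≤ 24`). Iteratively
reweighted MM (conjugate-gradient inner solves) and TV-FISTA baselines share
the same forward model and metrics.

## Worked example

`python examples/03_cs_reconstruction.py` simulates a 64×64 piecewise-affine
phantom, keeps 30% of k-space under variable-density sampling at 30 dB SNR,
and reconstructs:

```
sampling 1229/4096 coefficients, noise sigma=0.0361
zero-filled PSNR: 28.50 dB  (the Aᵀg initializer)
HDTV2-FBS: 141 outer iterations
  final PSNR 36.26 dB, SSIM 0.9966
  cost fell 1.177 -> 0.973, residual 9.8e-06
```

The 7.8 dB gain over the zero-filled inverse is what the prior recovers from
the missing 70% of the data; the residual shows the iteration has reached a
fixed point of the splitting operator. The other examples demonstrate the
functional's spectral machinery (`01`), standalone denoising with the prox
(`02`), and the three-method benchmark protocol (`04`).

The same workflows are available from the shell:

```
hdtv2 simulate --kind piecewise_linear --size 64 --ratio 0.3 --out-dir sim/
hdtv2 reconstruct --method hdtv2-fbs --lam 0.01 --mask sim/mask.npy \
      --meas sim/meas.npy --ref sim/phantom.npy --out recon.png
hdtv2 metrics sim/phantom.png recon.png
hdtv2 benchmark --out-dir bench/
```

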