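"""Full compressive-sensing reconstruction from 30% of k-space at 30 dB SNR.

Simulates variable-density Fourier sampling of a phantom, then reconstructs
with forward-backward splitting under the HDTV2 prior, tracking cost, PSNR
and the fixed-point residual per outer iteration.
"""

import numpy as np

from hdtv2 import (
    SolverConfig,
    fbs_reconstruct,
    forward_adjoint,
    make_phantom,
    psnr,
    simulate_measurement,
    ssim_global,
    variable_density_mask,
)

truth = make_phantom("piecewise_linear", 64, 64, seed=3)
mask = variable_density_mask(64, 64, ratio=0.3, seed=4)
g = simulate_measurement(truth, mask, snr_db=30.0, seed=5)
print(f"sampling {mask.M}/{mask.N} coefficients, noise sigma={g.noise_sd:.4f}")

zero_fill = np.clip(forward_adjoint(g, mask), 0, 1)
print(f"zero-filled PSNR: {psnr(truth, zero_fill):.2f} dB  (the Aᵀg initializer)")

cfg = SolverConfig(lam=0.01, tau=1.0, max_outer=200, inner_iters=15,
                   tol=1e-5, warm_start=True)
recon, trace = fbs_reconstruct(g, mask, cfg, f_ref=truth)
print(f"HDTV2-FBS: {trace.iterations} outer iterations")
print(f"  final PSNR {trace.psnr[-1]:.2f} dB, SSIM {ssim_global(truth, recon):.4f}")
print(f"  cost fell {trace.cost[0]:.3f} -> {trace.cost[-1]:.3f}, "
      f"residual {trace.residual[-1]:.1e}")
print("\nThe gain over zero-filling is what the second-degree prior")
print("recovers from the missing 70% of k-space.")
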