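"""Box-constrained HDTV2 denoising (the solver's backward step, standalone).

Adds white noise to a piecewise-affine phantom and removes it with the
accelerated dual prox at a few strengths α.  Because the phantom is affine
between creases, the second-degree prior can smooth aggressively without the
blocky staircase artifacts a first-order TV prior would introduce.
"""

import numpy as np

from hdtv2 import ProxConfig, make_phantom, prox_hdtv2, psnr

truth = make_phantom("piecewise_linear", 64, 64, seed=3)
noisy = np.clip(truth + 0.05 * np.random.default_rng(7).standard_normal(truth.shape), 0, 1)
print(f"noisy input PSNR: {psnr(truth, noisy):.2f} dB")

for alpha in (0.01, 0.03, 0.1):
    denoised, diag = prox_hdtv2(noisy, ProxConfig(alpha=alpha, inner_iters=300))
    print(f"alpha={alpha:<5}: PSNR {psnr(truth, denoised):.2f} dB")

print("\nPSNR rises then falls with alpha: too little leaves noise, too much")
print("flattens genuine gradients; the peak marks the right denoising strength.")
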