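"""Image quality metrics: PSNR, global-moment SSIM, relative error.

PSNR uses the peak of the *reference* image:
``PSNR = 10 log10( max|f|² / ((1/rc)‖f − f̂‖_F²) )`` in dB.

SSIM here is the single global index computed from whole-image means,
variances and covariance (population moments), not the windowed local mean
of the perceptual literature; a windowed variant with a uniform window is
provided for cross-checks via ``ssim_windowed``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["psnr", "ssim_global", "ssim_windowed", "relative_error"]


def _check_pair(ref: np.ndarray, recon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if ref.shape != recon.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {recon.shape}")
    return ref, recon


def psnr(ref: np.ndarray, recon: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images coincide."""
    ref, recon = _check_pair(ref, recon)
    peak = float(np.max(np.abs(ref)))
    if peak == 0.0:
        raise ValueError("reference image is identically zero")
    mse = float(np.mean((ref - recon) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def ssim_global(ref: np.ndarray, recon: np.ndarray,
                c1: float | None = None, c2: float | None = None,
                data_range: float = 1.0) -> float:
    """Single structural-similarity index from whole-image moments.

    Defaults follow the common stabilizers c1 = (0.01 L)², c2 = (0.03 L)²
    with dynamic range L; equals 1 iff the images coincide.
    """
    ref, recon = _check_pair(ref, recon)
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2
    mu_r, mu_x = ref.mean(), recon.mean()
    var_r, var_x = ref.var(), recon.var()
    cov = float(((ref - mu_r) * (recon - mu_x)).mean())
    return float(
        (2 * mu_x * mu_r + c1) * (2 * cov + c2)
        / ((mu_x**2 + mu_r**2 + c1) * (var_x + var_r + c2))
    )


def ssim_windowed(ref: np.ndarray, recon: np.ndarray, win: int = 7,
                  c1: float | None = None, c2: float | None = None,
                  data_range: float = 1.0) -> float:
    """Mean of local SSIM over uniform ``win``×``win`` windows (cross-check only)."""
    ref, recon = _check_pair(ref, recon)
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2
    mu_r = uniform_filter(ref, win)
    mu_x = uniform_filter(recon, win)
    var_r = uniform_filter(ref * ref, win) - mu_r * mu_r
    var_x = uniform_filter(recon * recon, win) - mu_x * mu_x
    cov = uniform_filter(ref * recon, win) - mu_r * mu_x
    ssim_map = ((2 * mu_x * mu_r + c1) * (2 * cov + c2)
                / ((mu_x**2 + mu_r**2 + c1) * (var_x + var_r + c2)))
    pad = win // 2
    return float(ssim_map[pad:-pad or None, pad:-pad or None].mean())


def relative_error(iterate: np.ndarray, ref: np.ndarray) -> float:
    """‖iterate − ref‖_F / ‖ref‖_F."""
    ref, iterate = _check_pair(ref, iterate)
    ref_n = float(np.linalg.norm(ref))
    if ref_n == 0.0:
        raise ValueError("reference image is identically zero")
    return float(np.linalg.norm(iterate - ref) / ref_n)
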