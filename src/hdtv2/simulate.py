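"""Synthetic experiment generation: sampling masks, noise, phantoms.

The generator emulates the acquisition protocol of undersampled-Fourier
imaging studies: a variable-density random mask over k-space (biased toward
low frequencies, with DC and a small fully-sampled low-frequency block always
included), complex white Gaussian measurement noise calibrated to a target
SNR in dB, and phantoms with the salient structure of anatomical and
microscopy test images — piecewise-smooth regions with sharp edges, smooth
blobs, and thin elongated filaments.  Everything is deterministic given a
seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .linops import FourierMask, Measurement, forward_model

__all__ = [
    "variable_density_mask",
    "add_noise_snr",
    "make_phantom",
    "simulate_measurement",
    "PHANTOM_KINDS",
]

PHANTOM_KINDS = ("piecewise_linear", "blobs", "filaments")


def _centered_radius(r: int, c: int) -> np.ndarray:
    """Radial frequency magnitude ‖k‖ in the standard DFT layout."""
    ky = np.minimum(np.arange(r), r - np.arange(r))[:, None]
    kx = np.minimum(np.arange(c), c - np.arange(c))[None, :]
    return np.sqrt(ky.astype(float) ** 2 + kx.astype(float) ** 2)


def variable_density_mask(r: int, c: int, ratio: float, decay: float = 2.0,
                          seed: int = 0, center_block: int = 8) -> FourierMask:
    """Random k-space mask with density ∝ (1 + ‖k‖/k_max)^(−decay).

    Exactly ``M = round(ratio·r·c)`` coefficients are selected without
    replacement; the DC coefficient — required for coercivity of the model —
    and a centered ``center_block``² low-frequency block (when M allows) are
    always included.  ``decay = 0`` gives uniform random sampling.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    if decay < 0:
        raise ValueError("decay must be nonnegative")
    N = r * c
    M = int(round(ratio * N))
    if M < 1:
        raise ValueError("ratio too small: no coefficient would be selected")
    if M == N:
        return FourierMask(np.ones((r, c), dtype=bool))

    rng = np.random.default_rng(seed)
    rad = _centered_radius(r, c)
    prob = (1.0 + rad / rad.max()) ** (-decay)

    forced = np.zeros((r, c), dtype=bool)
    forced[0, 0] = True
    half = center_block // 2
    if center_block > 0 and M > center_block * center_block:
        ys = np.arange(-half, center_block - half) % r
        xs = np.arange(-half, center_block - half) % c
        forced[np.ix_(ys, xs)] = True
    n_forced = int(forced.sum())
    if n_forced > M:
        forced[:] = False
        forced[0, 0] = True
        n_forced = 1

    selected = forced.copy()
    free = ~forced
    p = (prob * free).ravel()
    p /= p.sum()
    idx = rng.choice(N, size=M - n_forced, replace=False, p=p)
    selected.ravel()[idx] = True
    return FourierMask(selected)


def add_noise_snr(clean: Measurement, snr_db: float, seed: int = 0) -> Measurement:
    """Add complex white Gaussian noise at a given measurement-domain SNR.

    σ is chosen so that 10·log10(‖g‖² / E‖e‖²) = snr_db, with e having
    i.i.d. complex entries of total variance σ² (σ/√2 per real component).
    ``snr_db = inf`` returns the measurement unchanged.
    """
    power = float(np.vdot(clean.data, clean.data).real)
    if power == 0.0:
        raise ValueError("clean measurement is identically zero")
    if np.isinf(snr_db):
        return clean
    M = clean.M
    sigma = float(np.sqrt(power / (M * 10.0 ** (snr_db / 10.0))))
    rng = np.random.default_rng(seed)
    noise = (sigma / np.sqrt(2.0)) * (rng.standard_normal(M) + 1j * rng.standard_normal(M))
    return Measurement(clean.data + noise, noise_sd=sigma)


def _phantom_piecewise_linear(r: int, c: int, rng: np.random.Generator) -> np.ndarray:
    # continuous piecewise-affine surface: linear interpolation of random
    # node values over a random triangulation.  Exactly affine inside each
    # triangle (zero second differences), with gradient creases — not
    # intensity jumps — along the polygonal partition: the canonical sparse
    # object of a second-degree derivative prior, as piecewise-constant
    # images are for first-order TV.
    from scipy.interpolate import LinearNDInterpolator

    n_nodes = int(rng.integers(8, 16))
    pts = np.vstack([rng.uniform(0, 1, size=(n_nodes, 2)),
                     [[0, 0], [0, 1], [1, 0], [1, 1]]])
    vals = rng.uniform(0.0, 1.0, size=len(pts))
    interp = LinearNDInterpolator(pts, vals)
    yy, xx = np.mgrid[0:r, 0:c]
    img = interp(yy / max(r - 1, 1), xx / max(c - 1, 1))
    return np.clip(img, 0.0, 1.0)


def _phantom_blobs(r: int, c: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:r, 0:c]
    img = np.zeros((r, c))
    for _ in range(int(rng.integers(4, 8))):  # smooth Gaussian bumps
        cy, cx = rng.uniform(0.15, 0.85) * r, rng.uniform(0.15, 0.85) * c
        sy, sx = rng.uniform(0.05, 0.2) * r, rng.uniform(0.05, 0.2) * c
        img += rng.uniform(0.3, 0.8) * np.exp(
            -0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    for _ in range(int(rng.integers(2, 5))):  # sharp-edged ellipses
        cy, cx = rng.uniform(0.2, 0.8) * r, rng.uniform(0.2, 0.8) * c
        sy, sx = rng.uniform(0.04, 0.12) * r, rng.uniform(0.04, 0.12) * c
        inside = ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2 <= 1.0
        img[inside] += rng.uniform(0.2, 0.5)
    peak = img.max()
    return img / peak if peak > 0 else img


def _phantom_filaments(r: int, c: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((r, c))
    n_strokes = int(rng.integers(6, 12))
    for _ in range(n_strokes):
        # random quadratic Bezier stroke rasterized onto the grid
        pts = rng.uniform(0, 1, size=(3, 2)) * [r - 1, c - 1]
        t = np.linspace(0.0, 1.0, 4 * max(r, c))[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1] + t**2 * pts[2])
        on = np.zeros((r, c), dtype=bool)
        iy = np.clip(np.round(curve[:, 0]).astype(int), 0, r - 1)
        ix = np.clip(np.round(curve[:, 1]).astype(int), 0, c - 1)
        on[iy, ix] = True
        width = rng.uniform(0.5, 1.5)  # stroke half-width, 1-3 px full width
        dist = ndimage.distance_transform_edt(~on)
        stroke = np.clip(1.0 - dist / (width + 0.5), 0.0, 1.0)  # anti-aliased falloff
        img = np.maximum(img, rng.uniform(0.5, 1.0) * stroke)
    return np.clip(img, 0.0, 1.0)


def make_phantom(kind: str, r: int, c: int, seed: int = 0) -> np.ndarray:
    """Deterministic phantom in [0,1] emulating a class of test-image structure.

    ``piecewise_linear``: continuous piecewise-affine surface over a random
    triangulation (the sparse class of the second-degree prior).  ``blobs``:
    smooth bumps plus sharp ellipses (anatomy-like piecewise-smooth regions
    with edges).  ``filaments``: thin anti-aliased curved strokes (elongated
    features of microscopy images).
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if r < 32 or c < 32:
        raise ValueError("phantoms need at least a 32x32 grid")
    rng = np.random.default_rng(seed)
    if kind == "piecewise_linear":
        return _phantom_piecewise_linear(r, c, rng)
    if kind == "blobs":
        return _phantom_blobs(r, c, rng)
    return _phantom_filaments(r, c, rng)


def simulate_measurement(img: np.ndarray, mask: FourierMask, snr_db: float = 30.0,
                         seed: int = 0) -> Measurement:
    """g = A f + e: undersampled unitary DFT of the image plus calibrated noise."""
    return add_noise_snr(forward_model(img, mask), snr_db, seed=seed)
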