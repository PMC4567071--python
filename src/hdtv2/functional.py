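"""The second-degree total variation (HDTV2) functional.

HDTV2 penalizes second *directional* derivatives across all orientations:
per pixel it takes the L2 norm over the angle θ of the second directional
derivative, and sums (L1) over pixels.  Because the directional derivative is
a fixed trigonometric combination ``S2(θ)ᵀ G2`` of the three second partial
derivatives ``G2 = (f_xx, f_xy, f_yy)``, the angular integral collapses to a
quadratic form with the constant 3×3 Gram matrix

    C2(i, j) = (1/2π) ∫ S2⁽ⁱ⁾(θ) S2⁽ʲ⁾(θ) dθ,   S2(θ) = (cos²θ, 2cosθsinθ, sin²θ),

so HDTV2(f) = Σ_pixels √(G2ᵀ C2 G2) = Σ_pixels ‖W2 G2‖₂ with W2 the symmetric
PSD square root of C2.  Both forms are implemented; the directional
quadrature form serves as an independent cross-check of the weighted form.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import eigh

from .linops import apply_V2, apply_weighting

__all__ = [
    "steering_vector",
    "second_directional_derivative",
    "build_C2",
    "spectral_sqrt",
    "default_W2",
    "hdtv2_value_weighted",
    "hdtv2_value_directional",
]


def steering_vector(theta):
    """S2(θ) = (cos²θ, 2 cosθ sinθ, sin²θ), vectorized over θ."""
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    return np.stack([c * c, 2.0 * c * s, s * s], axis=-1)


def second_directional_derivative(g2, theta: float) -> float:
    """Second derivative along the unit direction (cosθ, sinθ): S2(θ)ᵀ g2."""
    g2 = np.asarray(g2, dtype=float)
    return float(steering_vector(theta) @ g2)


def _nodes(n: int) -> np.ndarray:
    if n < 8:
        raise ValueError(f"need at least 8 quadrature nodes, got {n}")
    # uniform midpoint rule on [0, 2π): exact for trig polynomials of degree < n
    return (np.arange(n) + 0.5) * (2.0 * np.pi / n)


@lru_cache(maxsize=8)
def build_C2(quadrature_nodes: int = 360) -> np.ndarray:
    """Gram matrix C2 of the steering functions by midpoint quadrature.

    The entries are trigonometric polynomials of degree 4, so any ``n ≥ 8``
    uniform nodes integrate them exactly (to rounding); the result equals
    (1/8)·[[3,0,1],[0,4,0],[1,0,3]].
    """
    S = steering_vector(_nodes(quadrature_nodes))  # (n, 3)
    C = (S.T @ S) / quadrature_nodes
    C.setflags(write=False)
    return C


def spectral_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; W = Q D^{1/2} Qᵀ."""
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("expected a symmetric 3x3 matrix")
    evals, Q = eigh(C)
    if evals.min() < -1e-12:
        raise ValueError("matrix is not positive semidefinite")
    return (Q * np.sqrt(np.clip(evals, 0.0, None))) @ Q.T


@lru_cache(maxsize=1)
def default_W2() -> np.ndarray:
    """The weighting matrix W2 = sqrt(C2) used throughout the solvers."""
    W = spectral_sqrt(build_C2(360))
    W.setflags(write=False)
    return W


def hdtv2_value_weighted(img: np.ndarray, W: np.ndarray | None = None) -> float:
    """HDTV2(f) = Σ_pixels ‖W2 (V2 f)_i‖₂ (the weighted L1-L2 mixed norm)."""
    if W is None:
        W = default_W2()
    weighted = apply_weighting(apply_V2(img), W)
    return float(np.sqrt((weighted * weighted).sum(axis=0)).sum())


def hdtv2_value_directional(img: np.ndarray, quadrature_nodes: int = 360) -> float:
    """HDTV2(f) from its defining angular integral, by midpoint quadrature.

    Per pixel: sqrt of the mean over θ of the squared second directional
    derivative, summed over pixels.  Independent of the spectral
    factorization, hence usable as an oracle for the weighted form.
    """
    S = steering_vector(_nodes(quadrature_nodes))  # (n, 3)
    g2 = apply_V2(img)  # (3, r, c)
    proj = np.tensordot(S, g2, axes=([1], [0]))  # (n, r, c)
    mean_sq = (proj * proj).mean(axis=0)
    return float(np.sqrt(mean_sq).sum())
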