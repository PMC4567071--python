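"""Discrete differential and Fourier operators with exact adjoints.

The image unknown is a real ``(r, c)`` array (row-major scan order is used
whenever pixels are enumerated; the math is order-invariant).  Second-degree
derivatives are discretized as compositions of first-degree *forward*
differences with a Neumann (reflexive) boundary convention: the difference at
the trailing boundary is zero.  With this convention each first-difference
operator has norm at most 2, hence every second-difference operator has norm
at most 4 — the bound the dual-ascent step size relies on.

Conventions
-----------
* ``x`` runs along columns (axis 1), ``y`` along rows (axis 0).
* A *derivative field* is a ``(3, r, c)`` array stacking ``(xx, xy, yy)``
  components; its inner product is the plain Euclidean one on the flat array
  (equivalently, the sum over pixels of per-pixel 3-vector dot products).
* The sensing operator is ``A = P F`` with ``F`` the **unitary** 2-D DFT
  (``norm="ortho"``), so ``‖A‖ ≤ 1`` and the forward-backward step size
  interval is ``τ ∈ (0, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FourierMask",
    "Measurement",
    "second_difference",
    "second_difference_adjoint",
    "apply_V2",
    "apply_V2_adjoint",
    "apply_weighting",
    "apply_weighting_adjoint",
    "apply_H2",
    "apply_H2_adjoint",
    "forward_model",
    "forward_adjoint",
    "normal_op",
    "operator_norm_estimate",
]

_AXIS_PAIRS = ("xx", "xy", "yy")

# x = axis 1 (columns), y = axis 0 (rows)
_AXIS_OF = {"x": 1, "y": 0}


def _check_grid(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"expected a 2-D grid of size at least 3x3, got shape {img.shape}")
    return img


def _fwd_diff(u: np.ndarray, axis: int) -> np.ndarray:
    """First forward difference, zero at the trailing boundary (Neumann)."""
    d = np.zeros_like(u)
    sl_head = [slice(None)] * u.ndim
    sl_head[axis] = slice(None, -1)
    d[tuple(sl_head)] = np.diff(u, axis=axis)
    return d


def _fwd_diff_adjoint(p: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_fwd_diff` (negative backward difference)."""
    out = np.zeros_like(p)
    head = [slice(None)] * p.ndim
    head[axis] = slice(None, -1)
    tail = [slice(None)] * p.ndim
    tail[axis] = slice(1, None)
    out[tuple(head)] -= p[tuple(head)]
    out[tuple(tail)] += p[tuple(head)]
    return out


def second_difference(img: np.ndarray, axis_pair: str) -> np.ndarray:
    """Apply the second-degree forward difference Δ_{axis_pair}.

    ``Δxx = Dx∘Dx``, ``Δyy = Dy∘Dy``, ``Δxy = Dy∘Dx`` where ``D`` is the
    forward difference with zero trailing boundary.  Linear in ``img``.
    """
    img = _check_grid(img)
    if axis_pair not in _AXIS_PAIRS:
        raise ValueError(f"axis_pair must be one of {_AXIS_PAIRS}, got {axis_pair!r}")
    first, second = axis_pair[0], axis_pair[1]
    # apply the first letter's difference first; D_x and D_y commute
    out = _fwd_diff(img.astype(float, copy=False), _AXIS_OF[first])
    return _fwd_diff(out, _AXIS_OF[second])


def second_difference_adjoint(field: np.ndarray, axis_pair: str) -> np.ndarray:
    """Exact adjoint of :func:`second_difference` under the Euclidean inner product."""
    field = _check_grid(field)
    if axis_pair not in _AXIS_PAIRS:
        raise ValueError(f"axis_pair must be one of {_AXIS_PAIRS}, got {axis_pair!r}")
    first, second = axis_pair[0], axis_pair[1]
    out = _fwd_diff_adjoint(field.astype(float, copy=False), _AXIS_OF[second])
    return _fwd_diff_adjoint(out, _AXIS_OF[first])


def apply_V2(img: np.ndarray) -> np.ndarray:
    """Stack the three second differences into a ``(3, r, c)`` derivative field."""
    img = _check_grid(img)
    return np.stack([second_difference(img, p) for p in _AXIS_PAIRS])


def apply_V2_adjoint(field: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_V2`: sum of the three component adjoints."""
    field = np.asarray(field)
    if field.ndim != 3 or field.shape[0] != 3:
        raise ValueError(f"expected a (3, r, c) derivative field, got shape {field.shape}")
    return sum(second_difference_adjoint(field[k], p) for k, p in enumerate(_AXIS_PAIRS))


def _check_weight(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (3, 3):
        raise ValueError(f"weighting matrix must be 3x3, got shape {W.shape}")
    return W


def apply_weighting(field: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Multiply each pixel's 3-vector by ``W`` (the operator Λ2 for ``W = W2``)."""
    W = _check_weight(W)
    return np.einsum("ab,b...->a...", W, np.asarray(field, dtype=float))


def apply_weighting_adjoint(field: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_weighting`; applies ``Wᵀ`` per pixel."""
    return apply_weighting(field, _check_weight(W).T)


def apply_H2(img: np.ndarray, W: np.ndarray) -> np.ndarray:
    """H2 = Λ2 V2: derivative stack followed by per-pixel weighting."""
    return apply_weighting(apply_V2(img), W)


def apply_H2_adjoint(field: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_H2`: ``V2ᵀ Λ2ᵀ``."""
    return apply_V2_adjoint(apply_weighting_adjoint(field, W))


@dataclass(frozen=True)
class FourierMask:
    """Boolean selection of 2-D DFT coefficients, DC (0,0) always included.

    ``selected`` uses the standard DFT layout (DC at index ``[0, 0]``);
    measurements are ordered by the row-major scan of ``selected``.
    """

    selected: np.ndarray

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=bool)
        if sel.ndim != 2:
            raise ValueError("mask must be a 2-D boolean grid")
        if not sel[0, 0]:
            raise ValueError("the DC (0,0) Fourier coefficient must be selected")
        if not sel.any():
            raise ValueError("mask selects no coefficients")
        object.__setattr__(self, "selected", sel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.selected.shape

    @property
    def M(self) -> int:
        """Number of selected coefficients."""
        return int(self.selected.sum())

    @property
    def N(self) -> int:
        return int(self.selected.size)


@dataclass(frozen=True)
class Measurement:
    """Complex Fourier measurements ``g`` in the mask's scan order."""

    data: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex).ravel()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "data", data)

    @property
    def M(self) -> int:
        return self.data.size


def forward_model(img: np.ndarray, mask: FourierMask) -> Measurement:
    """A f: selected coefficients of the unitary 2-D DFT of a real image."""
    img = _check_grid(img)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} does not match mask shape {mask.shape}")
    coeffs = np.fft.fft2(img, norm="ortho")
    return Measurement(coeffs[mask.selected])


def forward_adjoint(meas: Measurement, mask: FourierMask) -> np.ndarray:
    """Aᵀ g: embed at selected frequencies, inverse unitary DFT, real part.

    The real-part extraction makes this the exact adjoint of the
    real-to-complex map under the real inner product:
    ``ℜ⟨A f, g⟩_ℂ = ⟨f, Aᵀ g⟩_ℝ``.
    """
    if meas.M != mask.M:
        raise ValueError(f"measurement length {meas.M} does not match mask M={mask.M}")
    full = np.zeros(mask.shape, dtype=complex)
    full[mask.selected] = meas.data
    return np.real(np.fft.ifft2(full, norm="ortho"))


def normal_op(img: np.ndarray, mask: FourierMask) -> np.ndarray:
    """Aᵀ A f without forming the intermediate measurement vector."""
    coeffs = np.fft.fft2(img, norm="ortho")
    coeffs[~mask.selected] = 0.0
    return np.real(np.fft.ifft2(coeffs, norm="ortho"))


def operator_norm_estimate(op, op_adjoint, shape, iters: int = 100, seed: int = 0) -> float:
    """Estimate the operator norm of a linear map by power iteration on LᵀL.

    Parameters
    ----------
    op, op_adjoint : callables mapping arrays to arrays (exact adjoint pair).
    shape : domain shape of ``op``.
    iters : number of power iterations.
    seed : seed for the random starting vector.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape)
    nv = np.linalg.norm(v)
    if nv == 0:
        return 0.0
    v /= nv
    sigma2 = 0.0
    for _ in range(iters):
        w = op_adjoint(op(v))
        sigma2 = float(np.vdot(v, w).real)  # Rayleigh quotient of LᵀL
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
    return float(np.sqrt(max(sigma2, 0.0)))
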