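"""Proximal map of the box-constrained HDTV2 denoising problem.

The backward step of the reconstruction loop solves

    f⁺ = argmin_{f ∈ [a,b]^N}  ½‖f − z‖² + α ‖Λ2 V2 f‖_{1,2}

by projected, Nesterov-accelerated ascent on the dual problem.  Writing
H2 = Λ2 V2 and using ‖·‖_{∞,2} duality, the dual objective
h(ω) = E(P_S(z − α H2ᵀω), ω) has gradient ∇h(ω) = α H2 P_S(z − α H2ᵀω) with
Lipschitz constant L(h) ≤ α²‖H2‖² ≤ 24α², so the guaranteed dual ascent
update is ω ← P_B2(v + (1/(24α)) H2 P_S(z − α H2ᵀ v)) with the standard
momentum sequence t⁺ = (1 + √(1 + 4t²))/2.  The primal solution is recovered
as f⁺ = P_S(z − α H2ᵀ ω).

The inner loop is written generically over the analysis operator so the
first-order TV baseline reuses it with the gradient operator and dual step
1/(8α) (‖div‖² ≤ 8 in 2-D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional import default_W2
from .linops import apply_H2, apply_H2_adjoint

__all__ = [
    "ProxConfig",
    "ProxDiagnostics",
    "project_box",
    "project_ball",
    "dual_gradient",
    "prox_hdtv2",
    "accelerated_dual_prox",
]

#: Lipschitz bound for ‖H2‖² = ‖Λ2V2‖² with the forward-difference stencils.
H2_LIPSCHITZ_BOUND = 24.0


@dataclass
class ProxConfig:
    """Settings for the dual inner solver.

    alpha
        Denoising strength α = τλ (outer step size times regularization
        weight); α = 0 degenerates to plain box projection.
    inner_iters
        Number of dual ascent iterations (``Iter``).  15 is enough for the
        inexact prox inside the outer loop; oracle-grade calls raise it.
    bounds
        Box constraint (a, b) with a < b.
    dual_step
        Coefficient of the dual gradient step; ``None`` means the guaranteed
        1/(24α).
    """

    alpha: float
    inner_iters: int = 15
    bounds: tuple[float, float] = (0.0, 1.0)
    dual_step: float | None = None
    record_objective: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be at least 1")
        a, b = self.bounds
        if not a < b:
            raise ValueError(f"bounds must satisfy a < b, got ({a}, {b})")


@dataclass
class ProxDiagnostics:
    """Per-call record: final dual variable and (optionally) the primal objective."""

    omega: np.ndarray
    objective: list[float] = field(default_factory=list)


def project_box(img: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Orthogonal projection onto the box S = {f : f_i ∈ [a, b]}."""
    a, b = bounds
    if not a < b:
        raise ValueError(f"bounds must satisfy a < b, got ({a}, {b})")
    return np.clip(img, a, b)


def project_ball(field: np.ndarray) -> np.ndarray:
    """Per-pixel projection onto unit Euclidean balls (the l∞-l2 ball B2).

    The vector components are along axis 0; each per-pixel vector is scaled
    by 1/max(1, ‖·‖₂).
    """
    field = np.asarray(field, dtype=float)
    norms = np.sqrt((field * field).sum(axis=0, keepdims=True))
    return field / np.maximum(1.0, norms)


def dual_gradient(omega: np.ndarray, z: np.ndarray, cfg: ProxConfig,
                  W: np.ndarray | None = None) -> np.ndarray:
    """∇h(ω) = α H2 P_S(z − α H2ᵀ ω); Lipschitz with constant ≤ 24α²."""
    if W is None:
        W = default_W2()
    a = cfg.alpha
    if a == 0.0:
        return np.zeros_like(np.asarray(omega, dtype=float))
    inner = project_box(z - a * apply_H2_adjoint(omega, W), cfg.bounds)
    return a * apply_H2(inner, W)


def _mixed_norm(field: np.ndarray) -> float:
    return float(np.sqrt((field * field).sum(axis=0)).sum())


def accelerated_dual_prox(
    z: np.ndarray,
    alpha: float,
    op,
    op_adj,
    dual_step: float,
    bounds: tuple[float, float],
    iters: int,
    omega0: np.ndarray | None = None,
    record_objective: bool = False,
) -> tuple[np.ndarray, ProxDiagnostics]:
    """Generic accelerated projected dual ascent for ½‖f−z‖² + α‖op f‖_{1,2} on a box.

    ``op`` maps an image to a vector field (components on axis 0); ``op_adj``
    is its exact adjoint.  ``dual_step`` multiplies ``op P_S(·)`` directly
    (i.e. it already includes the 1/α factor of the 1/L gradient step).
    """
    z = np.asarray(z, dtype=float)
    if alpha == 0.0:
        f = project_box(z, bounds)
        return f, ProxDiagnostics(omega=np.zeros_like(op(z)))

    omega_prev = np.zeros_like(op(z)) if omega0 is None else np.asarray(omega0, dtype=float)
    v = omega_prev.copy()
    t = 1.0
    objective: list[float] = []
    omega = omega_prev
    for _ in range(iters):
        inner = project_box(z - alpha * op_adj(v), bounds)
        omega = project_ball(v + dual_step * op(inner))
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        v = omega + ((t - 1.0) / t_next) * (omega - omega_prev)
        t = t_next
        omega_prev = omega
        if record_objective:
            f = project_box(z - alpha * op_adj(omega), bounds)
            objective.append(0.5 * float(((f - z) ** 2).sum()) + alpha * _mixed_norm(op(f)))
    f = project_box(z - alpha * op_adj(omega), bounds)
    return f, ProxDiagnostics(omega=omega, objective=objective)


def prox_hdtv2(
    z: np.ndarray,
    cfg: ProxConfig,
    W: np.ndarray | None = None,
    omega0: np.ndarray | None = None,
) -> tuple[np.ndarray, ProxDiagnostics]:
    """Box-constrained HDTV2 proximal map by accelerated dual ascent.

    Runs exactly ``cfg.inner_iters`` dual iterations from ω = v = 0 (or from
    ``omega0`` when warm-starting) and returns P_S(z − α H2ᵀ ω) together with
    diagnostics.  With the default dual step 1/(24α) the primal objective is
    non-increasing up to small tolerance.
    """
    if W is None:
        W = default_W2()
    step = cfg.dual_step if cfg.dual_step is not None else (
        1.0 / (H2_LIPSCHITZ_BOUND * cfg.alpha) if cfg.alpha > 0 else 0.0)
    return accelerated_dual_prox(
        z,
        cfg.alpha,
        op=lambda u: apply_H2(u, W),
        op_adj=lambda p: apply_H2_adjoint(p, W),
        dual_step=step,
        bounds=cfg.bounds,
        iters=cfg.inner_iters,
        omega0=omega0,
        record_objective=cfg.record_objective,
    )
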