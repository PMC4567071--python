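# Methods

## Model and discretization

The package reconstructs a real image `f ∈ [a,b]^N` (default box `[0,1]`,
the normalized intensity range) from undersampled Fourier data by
minimizing `R(f) = ½‖g − Af‖² + λ·HDTV2(f)`.

**Sensing operator.** `A = P F` with `F` the *unitary* 2-D DFT
(`norm="ortho"`) and `P` a boolean coefficient selection that always
contains the DC term. Unitarity makes `‖A‖ ≤ 1`, so the forward-backward
step-size condition `τ ∈ (0, 2/‖A‖²)` becomes the concrete interval
`τ ∈ (0, 2)`; `τ = 1` is the default. Because `f` is real while `g` is
complex, the adjoint `Aᵀ` embeds the measurements, applies the inverse
unitary DFT and takes the real part — the exact adjoint of the
real-to-complex map under the real inner product.

**Second differences.** `Δxx`, `Δxy`, `Δyy` are compositions of first-degree
forward differences with a Neumann convention (the difference at the
trailing boundary is zero). Each first difference has norm ≤ 2, hence each
second difference has norm ≤ 4 — the ingredient of the dual Lipschitz bound
below. Pixel scan order is row-major throughout; the math is
order-invariant. `x` runs along columns, `y` along rows.

**The functional.** The angular L2 norm of the second directional
derivative collapses to the quadratic form `√(G₂ᵀC₂G₂)` per pixel, with
`C₂(i,j) = (1/2π)∫ S₂⁽ⁱ⁾S₂⁽ʲ⁾ dθ`. `C₂` is computed by uniform midpoint
quadrature on `[0, 2π)`: the integrands are trigonometric polynomials of
degree 4, so any `n ≥ 8` nodes are exact to rounding (the code defaults to
360 and the tests confirm node-count independence). `W₂ = C₂^{1/2}` is
computed by eigendecomposition rather than hard-coded, so the printed closed
form remains an independent check in the tests.

## Solvers

**HDTV2-FBS (primary).** Forward step `z = f − τAᵀ(Af − g)`, backward step
the box-constrained prox of `α‖Λ₂V₂·‖₁,₂` with `α = τλ`. The prox is solved
in the dual: the dual objective has gradient `∇h(ω) = αH₂P_S(z − αH₂ᵀω)`
with Lipschitz constant ≤ `24α²` (because `‖H₂‖² ≤ 24`), giving the fixed
ascent step `1/(24α)` combined with the Nesterov momentum sequence
`t⁺ = (1+√(1+4t²))/2`. Defaults: 15 inner iterations per outer step
(inexact prox — the cheapness of the inner loop is the point of the method),
`max_outer = 200`, stop when the relative image change drops below `1e−5`.
The dual variable is re-initialized at zero each outer step by default,
matching the printed algorithm; a `warm_start` flag carries it across outer
steps instead. Warm-starting makes the backward step effectively exact along
the outer trajectory at no extra cost — with it the outer cost sequence is
numerically monotone, whereas cold restarts leave ripples of order `1e−5`
relative; theory-grade tests use the flag or raise the inner count.

**HDTV2-MM (baseline).** Iteratively reweighted majorization: per-pixel
weights `C₂ / (2√(G₂ᵀC₂G₂ + ε))` with smoothing guard `ε = 1e−8` (the
weight expression has a literal division by zero at flat pixels), then a
matrix-free conjugate-gradient solve of `(AᵀA + 2λV₂ᵀEV₂)f = Aᵀg`
(relative residual `1e−6`, cap 50, warm-started from the current iterate).
The model here is unconstrained; the returned image is clipped to the box,
and the convergence trace reports the cost of the *projected* iterate so
the three methods' traces refer to the same constrained solution class. An
unconstrained iterate can otherwise undercut the constrained optimum and
make the curves incomparable.

**TV-FISTA (baseline).** Monotone FISTA on the isotropic first-order TV
model, reusing the same accelerated dual prox machinery with the gradient
operator (dual step `1/(8α)`, since the 2-D divergence norm is ≤ √8) and
the same box projection. The monotone variant keeps the best-cost iterate,
so its cost trace never increases.

λ is problem-dependent; comparisons pick each method's best-PSNR λ from a
log grid, which is the standard protocol when methods have different
optimal regularization weights. The benchmark driver automates this.

## Synthetic data

The simulator emulates variable-density random Fourier acquisition:
selection probability `∝ (1 + ‖k‖/k_max)^(−decay)` with `decay = 2` and a
fully-sampled centered 8×8 low-frequency block by default, DC always
included (required for coercivity of the objective — without the DC row a
constant shift is invisible to both terms). Noise is complex white Gaussian
calibrated in the measurement domain: `σ² = ‖Af‖²/(M·10^{SNR/10})`,
default 30 dB.

Three phantom kinds cover the structural regimes of the intended test
images at 64–256 px scale:

- `piecewise_linear` — a continuous piecewise-affine surface (linear
  interpolation of random node values over a random triangulation). This is
  the sparse class of the second-degree prior — gradient creases, no
  intensity jumps — exactly as piecewise-constant phantoms are the sparse
  class of TV. It is the staircase-avoidance probe: slopes are O(1) per
  unit length so the gradient content stands well above the 30 dB noise
  floor. A jump-dominated variant would instead probe edge fidelity, where
  first-order TV is at least as good.
- `blobs` — smooth Gaussian bumps plus sharp-edged ellipses
  (piecewise-smooth anatomy-like regions with edges).
- `filaments` — thin anti-aliased Bézier strokes of 1–3 px width
  (elongated structures of microscopy images).

What the phantoms do **not** emulate: complex-valued object phase, coil
sensitivities, anisotropic resolution, textured backgrounds, or the
intensity statistics of any particular anatomy. Passing tests therefore
demonstrate correctness of the operators and solvers and the qualitative
behavior of the priors on their intended structure classes — not clinical
performance on real acquisitions.

## Numerical choices

- Power-iteration operator-norm estimates use a seeded random start and a
  fixed iteration count (deterministic given the seed); 300–500 iterations
  resolve the second-difference norms to ~1e−3.
- The prox inner loop follows the momentum recursion literally, including
  `ω⁽⁰⁾ = v⁽¹⁾ = 0` and `t⁽¹⁾ = 1`; accelerated ascent is not strictly
  monotone, so transient objective ripples of order `1e−4` relative are
  expected and tested as such.
- `α = 0` degenerates the prox to plain box projection; `λ = 0` solvers
  reduce to (clipped) zero-filled reconstruction, and the MM loop then
  stops after its single least-squares solve.
- Test problem sizes: operators are validated on grids from 4×4 to 128×96;
  solver behavior on 64×64 instances at 20–50% sampling, chosen as the
  smallest scale at which variable-density sampling and the convergence
  phenomena of interest are well separated from boundary effects.
- The prox is cross-checked against an independent box-constrained
  quasi-Newton solver on a smoothed objective (`√(‖·‖² + ε²)`, `ε = 1e−9`),
  whose objective bias `≤ Nαε` is negligible at the 1e−4 comparison
  tolerance.

## Known limitations

- No backtracking or restart schemes: step sizes are the guaranteed
  constants, so convergence speed is not tuned per instance.
- The MM baseline's behavior depends on its CG budget; at small grids a
  warm-started CG makes MM more competitive per outer iteration than its
  reputation at larger scales suggests.
- SSIM is the single global-moment index by default (a windowed uniform
  variant exists for cross-checks); global SSIM saturates near 1 more
  easily than windowed SSIM.
- Gray-scale 2-D images only; no 3-D volumes, color, or non-Fourier
  sensing.
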