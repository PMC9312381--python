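# Methods

This note documents the algorithms, parameter choices and numerical
decisions in `irtr`, and what the synthetic fixtures do and do not emulate.

## Objective model

The package minimizes the Gaussian negative log-likelihood

J(θ) = ½ Σₘ [ log(2π σₘ²(θ)) + rₘ²(θ) ],  rₘ = (ȳₘ − yₘ(θ)) / σₘ(θ),

over a box `l < θ < u` (bounds may be infinite). The ½ prefactor is part of
the contract: the Gauss-Newton product, the consistency threshold `τ = 2`
and all reported objective values assume this scaling. Measurements are
indexed flat; nothing downstream needs the (observable, timepoint)
structure. An objective may report failure (non-finite value/gradient or a
user signal such as an ODE integrator error); the optimizer treats failed
trials as rejected steps with a radius shrink, never as exceptions.

## Trust-region iteration

Each iteration builds the quadratic model `m(p) = f + gᵀp + ½ pᵀBp`,
minimizes it over `‖p‖ ≤ Δ` in scaled coordinates (below), evaluates the
trial point, and computes the ratio ρ of actual to predicted decrease.
Rules, with defaults:

- acceptance: `ρ > μ`, `μ = 0` — accept exactly when the true objective
  decreased and the model predicted a decrease. When the predicted decrease
  is non-positive (possible once the boundary augmentation enters the
  model), ρ is set to 0, preventing spurious acceptance when both
  quantities are negative.
- radius: doubled when `ρ > 0.75` **and** the step presses the trust region
  (`‖p‖ > 0.9 Δ` in scaled norm); shrunk to `min(Δ, ‖p‖)/4` when `ρ < 0.25`
  or the trial evaluation failed; unchanged in the middle band. All
  inequalities are strict. The "radius updated" flag (any change, either
  direction) feeds the hybrid scheme's stall counter.
- termination: accepted step norm `< 1e-6` (step tolerance), iteration cap
  `1e5`, or radius underflow below `1e-16` (failure status — typically a
  boundary-constrained stall where the interior method cannot make an
  accepted step).
- initial radius `Δ₀ = 1` in scaled coordinates (configurable).

One full (value + gradient) objective evaluation is spent per iteration, at
the trial point; on rejection the evaluation at the current iterate is
reused from cache. The gradient-evaluation count therefore equals the
iteration count, which is the denominator convention of the `ν = 1/n_grad`
metric. Update vectors for iterative schemes (`s = Δθ`, `z = g₊ − g`) are
formed over accepted iterates only.

Every iteration appends a trace record: objective values, ‖g‖, Δ, ρ, step
norm and kind, acceptance, radius/Hessian update flags, and three
numerical-health flags — transformed-Hessian singularity
(`cond(B̂) > 1/ε`), a negative eigenvalue of the raw approximation beyond
noise (`λ_min < −ε·|λ_max|`, `ε = spacing(1)`), and trial-evaluation
failure.

## Subproblem solvers

**ND (full space).** Eigendecompose `B`; if `B ≻ 0` and the Newton point is
inside the ball, return it. Otherwise solve the secular equation
`‖p(λ)‖ = Δ`, `p(λ)ᵢ = −ĝᵢ/(λᵢ + λ)`, for the multiplier
`λ ≥ max(0, −λ_min)` by bracketed root-finding (Brent, relative tolerance a
few ε; the boundary norm is honored to 1e-10). In the hard case — gradient
orthogonal to the bottom eigenspace with the limiting step interior — the
step is padded along the bottom eigenvector to the boundary. Two
degeneracies get the same padding treatment: a bracket that collapses to the
floating-point granularity of the multiplier bound, and a secular root
falling between adjacent floats because a bottom-eigenspace gradient
component is a few ulp above zero (uniformly rescaling the mis-rooted step
was measurably suboptimal, ~1% in model value, on randomized instances).
Dense eigensolvers are used throughout; for simulation-dominated objectives
their cost is negligible below ~10³ parameters.

**2D (subspace).** Exact solve of the projected 2×2 problem over
span{g, d_N} with the Newton direction `d_N` computed as the minimum-norm
least-squares solution of `B d = −g` (LAPACK gelsd pseudoinverse). When `B`
has a negative eigenvalue beyond noise, the second basis vector is instead
the eigenvector of the most negative eigenvalue (signed non-ascending);
when the two spanning vectors are parallel the problem degenerates to a
line and is solved there. Because the gradient lies in the subspace, the 2D
value never exceeds the Cauchy-point value, and it can never beat ND.

## Boundary handling

Coleman–Li affine scaling: per coordinate, `v` is the (signed) distance to
the bound the gradient points toward when that bound is finite, and ±1 on
the infinite-bound branches; `D = diag(|v|^½)`. The transformed model is
`B̂ = D B D + diag(g)·∇|v|`, `ĝ = D g`. The derivative is taken of `|v|`
(entries 0, ±1), which makes the augmentation `diag(g)∇|v| = diag(|g|)` on
bounded coordinates — positive semi-definite, a mild regularization of the
subproblem. (Taking the derivative of `v` itself would flip the sign on
upper-bound branches and demonstrably destabilizes bounded runs.) The trust
region lives in the scaled coordinates; steps map back through `D` before
boundary geometry is applied, and predicted decreases are evaluated on the
augmented model, in line with the transformation-aware prediction the
interior-reflective framework calls for.

If a proposal leaves the box, three candidates are built on the augmented
model and the lowest model value wins (ties: longer step, then reflected >
truncated > Cauchy):

- **reflection** — walk the folded path of total length ‖p‖, flipping the
  direction component of each coordinate at its bound; minimize the model
  analytically on every linear segment; stop at the first segment with a
  strictly interior minimizer ("first local minimum along the path"), at
  the reflection cap (`max_reflections=1` reproduces the single-reflection
  variant of other implementations; `None` means unlimited, with a safety
  cap of 100·n reflections against degenerate cycling), or when the length
  is exhausted; return the best point seen. Because the single-reflection
  walk is a prefix of the multi-reflection walk, multi is never worse.
- **truncation** — largest `α ∈ [0,1]` keeping `θ + αp` in the box.
- **constrained Cauchy** — minimize the model along the scaled
  steepest-descent direction `−D ĝ`, limited by the trust region and the
  box; closed form under positive curvature, boundary value otherwise.

Every candidate is backed off strictly inside the box by the relative
factor `1 − 1e-10` (the iterate must stay interior for the scaling to be
defined).

## Hessian approximation schemes

All schemes are symmetric by construction (symmetrized after every update).
Standardized residuals make the Gauss-Newton product `B = JrᵀJr`, the exact
Hessian of the residual part for affine residuals. For parameter-dependent
noise, GNe adds the error-residual correction
`Σₘ (∇σₘ)(∇σₘ)ᵀ / (σₘ²(2 log σₘ + C))` with `C = 50`; the condition
`2 log σₘ + C > 0` is enforced with a per-residual error message, and the
correction vanishes for constant noise and as `C → ∞`.

Iterative updates, with relative safeguards (the literature specifies only
"denominator non-zero"):

- **BFGS** `M + zzᵀ/zᵀs − (Ms)(Ms)ᵀ/sᵀMs`, performed only when
  `zᵀs > ε·‖z‖‖s‖`; preserves PSD from a PSD start. For PSD `M` with
  `Ms = 0` the second term vanishes in the limit and is dropped (this lets
  corrections grow from a zero initialization); a degenerate denominator
  with `Ms ≠ 0` (only possible for indefinite `M`) skips with a warning.
- **SR1** rank-one update, skipped when
  `|(z − Ms)ᵀs| ≤ 1e-8·‖s‖‖z − Ms‖`; can and should go indefinite to
  capture negative curvature.

Structured schemes combine a pointwise GNe core (they require least-squares
structure; `C = 50`) with an iterative correction `A` for the
residual-curvature term `Σ rₘ ∇²rₘ` that GN drops:

- **SSM** `B = GNe + A`, `A ← A + Δ_BFGS(s, z#, GNe + A)` with
  `z# = (Jr₊ − Jr)ᵀ r₊`; not PSD-preserving (the expansion point changes
  every iteration).
- **TSSM** `B = GNe + ‖r₊‖·A`; the inner update uses
  `z† = GNe·s + z#·(‖r₊‖/‖r‖)`, expands around `GNe + ‖r₊‖A`, and the
  `A`-increment is scaled by `1/‖r₊‖`. Falls back to plain GNe when either
  residual norm vanishes (the scaling is undefined there).
- **FX** keeps a carried matrix: BFGS-update it when the normalized
  residual-norm decrease `(‖r‖ − ‖r₊‖)/‖r‖` falls below `ε_FX = 0.2`
  (stagnation ⇒ non-zero-residual regime), otherwise re-anchor at a fresh
  GNe. Always PSD.
- **GNSBFGS** uses `z◊ = z#·‖r₊‖/‖r‖`: when `z◊ᵀs/sᵀs > ε = 1e-6` the
  correction `A` is BFGS-updated around itself (keeping `A`, hence
  `GNe + A`, PSD); otherwise `B = GNe + ‖r₊‖·I` and `A` is untouched.
  `A` starts at zero; the first matrix (no update data yet) uses the
  fallback form `GNe + ‖r₀‖·I`.

**Hybrid switching** (`HYBRID`): return the pointwise GN(e) matrix while
BFGS-updating a shadow matrix (identity start) on every accepted step. A
stall counter increments each iteration the radius was not updated and
resets on any change; at `n_hybrid` consecutive stalls the scheme switches
to the shadow matrix permanently. Default `n_hybrid = 50`, the
best-performing value in the benchmark study this scheme comes from. The
pointwise half is GNe, which coincides with GN for constant noise and keeps
the scheme defined for parameter-dependent noise. Rationale: GN's basin of
attraction behavior is most valuable early; once the radius stalls, the GN
model quality is limiting and a secant approximation converges faster
locally.

An `EXACT` scheme passes through a user-supplied Hessian, mainly for
testing against analytic references.

## Multistart metrics

For a study of `R` runs with total gradient evaluations `n_grad`:
`γ = #{runs with f_final − min f_final < τ}` (non-finite finals count as
unsuccessful but their evaluations count in `n_grad`), `ν = 1/n_grad`,
`φ = γ/n_grad = γ·ν`. Default `τ = 2`, the largest objective difference at
which a model cannot be rejected under the AIC given the ½-scaled
likelihood; `τ = 0.05` and `τ = 5` are the conventional sensitivity checks
(γ is monotone in τ). Start-point overlap between two settings is scored
with the Jaccard index of their successful start-index sets (0 for two
empty sets), an interpretation chosen here since no closed formula is
standard.

## Synthetic fixtures

`make_nls(n_par, n_res, residual_norm_at_opt, spectrum_decades, …)` builds
residuals `r(θ) = M·sinh(θ − θ*) + r₀` with `MᵀM` eigenvalues spaced
logarithmically over the requested decades, and `r₀` orthogonal to the
columns of `M` with prescribed norm. Consequences, all by construction: θ*
is the unique global minimizer, the gradient vanishes there exactly, the GN
eigenspread at θ* is exact, and with `r₀ = 0` GN is the exact Hessian at
θ*. A `linear` warp yields affine residuals (convex quadratic objective).
Defaults for the study-scale experiments: 5 parameters, 12 residuals,
bounds θ* ± 2, residual norm 2 and 6 decades of sloppiness for the
"hard" fixture, 100 uniform starts.

Limitation to keep in mind: because `r₀ ⟂ range(M)` globally, the
residual-curvature coupling `Σ rₘ∇²rₘ` vanishes *at* the optimum (though
not away from it), so GN performs better on this fixture family than on
real non-zero-residual calibration problems, and the hybrid switch rarely
fires at the default stall budget on runs this short (~30 iterations).
Passing multistart comparisons here demonstrates correct mechanics and
"hybrid never degrades GN", not the full performance advantage reported on
realistic ODE benchmark corpora. The switch mechanics themselves are
exercised with scripted stall sequences and small `n_hybrid`.

The conversion model is the smallest mass-action system with a non-trivial
likelihood: `x₁ ⇌ x₂` with rates `k₁, k₂`, conserved total `T`, observable
`y = x₂(t) = x₂_eq + (x₂(0) − x₂_eq)e^{−(k₁+k₂)t}`, `x₂_eq = k₁T/(k₁+k₂)`,
with analytic parameter derivatives. Defaults: `k₁ = 2, k₂ = 1` (relaxation
time ⅓), `x₀ = (1, 0)`, ten observation times on `[0, 3]` covering
transient and plateau, noise scale `σ = 0.02` (2% of total abundance),
bounds `[10⁻³, 10²]` per rate. With `estimate_sigma=True` the noise scale
becomes a third estimated parameter, which makes the noise
parameter-dependent and exercises the GNe correction. Data are drawn with
the counter-based Philox generator keyed by the seed, so fixtures are
bit-reproducible across platforms. What this fixture does not emulate:
stiffness, integration error and failure regions of real ODE solvers
(failure handling is tested with synthetic failure regions instead),
multiple observables, and structural non-identifiability.

## Numerical choices and degenerate inputs

- Secular root tolerance: boundary norm to 1e-10; feasibility always
  enforced to `‖p‖ ≤ Δ(1 + 1e-9)`.
- Zero gradient at an iterate: the 2D solver returns the zero step (the
  iteration then terminates via the step tolerance if accepted, or shrinks
  the radius to underflow at a saddle).
- `sᵀMs`/curvature guards as listed per scheme above.
- Matrix symmetry is asserted on solver entry (tolerance 1e-8 relative) and
  enforced after every scheme update.
- Reflection cap 100·n against degenerate zero-length segment cycling at
  corners.
- All randomness in fixtures and sampling flows through
  `numpy.random.Philox` keyed by user seeds.

## Known limitations

- No sparse or iterative subproblem path: dense eigendecomposition bounds
  practical problem size to a few thousand parameters.
- The interior method cannot terminate cleanly on a minimum situated
  exactly on a bound: such runs end in radius-underflow failure, which the
  multistart layer treats as data.
- No line-search globalization or Wolfe-condition machinery; BFGS updates
  are simply skipped when curvature fails, which weakens its theoretical
  convergence guarantees (a known trade-off of trust-region BFGS).
- Multistart runs execute sequentially; outputs are start-index ordered and
  seed-deterministic by design.
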