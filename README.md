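# irtr — interior-reflective trust-region optimization for likelihood fits

`irtr` is a Python toolbox for bound-constrained maximum-likelihood
estimation of the kind that arises when calibrating mechanistic models —
e.g. mass-action ODE models of biochemical networks — against noisy,
indirect measurements. These problems are typically *sloppy* (the objective
Hessian has eigenvalues spread over many decades, so parameters are poorly
identifiable) and *non-zero residual* (the data are noisy and the model is
imperfect, so residuals stay large even at the optimum). Both properties
degrade standard optimizers, and which Hessian approximation the optimizer
uses turns out to matter as much as the algorithm itself.

The package provides:

- a **trust-region loop** with the Coleman–Li interior treatment of box
  constraints: affine rescaling of variables near bounds, a transformed
  model `B̂ = D B D + diag(g) ∇|v|`, and stepback by reflection at the
  boundary, truncation, or a constrained Cauchy step — selecting the
  candidate with the lowest model value;
- **exact subproblem solvers**: the full-space minimizer of
  `m(p) = f + gᵀp + ½ pᵀBp` over `‖p‖ ≤ Δ` via eigendecomposition and a
  safeguarded secular-equation solve (hard case included), and the classical
  two-dimensional subspace variant spanned by the gradient and Newton
  directions;
- **nine Hessian approximation schemes** behind one interface: pointwise
  Gauss-Newton (`GN`), Gauss-Newton with error residuals for
  parameter-dependent noise (`GNe`), iterative `BFGS` and `SR1`, the
  structured secant methods `SSM` and `TSSM`, the Fletcher–Xu hybrid `FX`,
  the Gauss-Newton structured BFGS `GNSBFGS`, and a **hybrid switching
  scheme** (`HYBRID`) that runs GN while silently maintaining a BFGS shadow
  matrix and switches to it permanently after `n_hybrid` consecutive
  iterations without a trust-region radius change;
- **multistart machinery and diagnostics**: uniform start-point sampling,
  per-iteration trace records with numerical-health flags (singular
  transformed Hessian, negative eigenvalues, failed evaluations,
  boundary-constrained steps), waterfall data, and the performance metrics
  `γ` (success count below a consistency threshold `τ`), `ν = 1/n_grad`
  (convergence rate) and `φ = γ/n_grad = γ·ν`;
- **synthetic problem generators** — least-squares problems with a
  constructible optimum, prescribed residual norm at the optimum, and a
  prescribed Gauss-Newton eigenvalue spread, plus a closed-form two-species
  conversion model with Gaussian noise — so the entire stack is testable
  without any external data or ODE integrator.

The objective contract is the Gaussian negative log-likelihood

```
J(θ) = ½ Σₘ [ log(2π σₘ²(θ)) + ( (ȳₘ − yₘ(θ)) / σₘ(θ) )² ]
```

over a flat measurement index `m`; schemes that need least-squares structure
consume the standardized residuals `r = (ȳ − y)/σ` and their Jacobian.
Objectives may signal evaluation failure (e.g. an integrator error); the
loop treats a failed trial like a poor step and shrinks the radius to
`min(Δ, ‖p‖)/4`.

## Worked example

Minimize the Rosenbrock valley in least-squares form on `[-2, 2]²` with a
Gauss-Newton Hessian:

```python
import numpy as np
from irtr import minimize, OptimizerOptions
from irtr.problems import rosenbrock_problem
from irtr.diagnostics import trace_statistics

objective, domain, theta_min = rosenbrock_problem()
res = minimize(objective, np.array([-1.2, 1.0]), domain,
               OptimizerOptions(scheme="GN"))
print(res.status, res.n_iter, res.fval, res.theta)
print(trace_statistics(res))
```

prints

```
step_tolerance 27 0.0 [1. 1.]
{'n_iterations': 27, 'frac_singular_transformed_hessian': 0.0,
 'frac_negative_eigenvalue': 0.0, 'frac_no_delta_update': 0.593,
 'frac_no_hessian_update': 0.0, 'frac_eval_failed': 0.0,
 'frac_boundary_constrained': 0.0, 'frac_cauchy_steps': 0.0,
 'frac_accepted': 0.852}
```

i.e. the run terminated on the step-size tolerance after 27 iterations at
the exact minimum `(1, 1)` with objective 0; 85% of proposed steps were
accepted and none of the numerical-health flags fired.

A multistart study from the command line — 25 starts of the hybrid scheme
on the simulated two-species conversion model:

```sh
irtr run --problem conversion --scheme HYBRID --n-starts 25 --seed 4 --out out/
```

```
tau=2: gamma=11 nu=2.049e-03 phi=2.254e-02
outputs written to out/
```

Eleven of the 25 runs finished within `τ = 2` log-likelihood units of the
best final value (the remainder stalled against the rate bounds — failed
runs are data, not errors); 488 gradient evaluations were spent in total,
giving convergence rate `ν = 1/488 ≈ 2.05·10⁻³` and performance
`φ = γ·ν ≈ 2.25·10⁻²`. The output directory contains `metrics.csv` (one row
per `τ`), `waterfall.csv` (sorted final values), and `summary.json`;
`irtr metrics` recomputes `γ/ν/φ` from a stored waterfall at new thresholds,
and `irtr fixture` serializes a conversion-model fixture to a plain-text
parameter file plus CSV data table.

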