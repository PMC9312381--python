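"""The interior-reflective trust-region iteration.

Each iteration builds the Coleman-Li scaled quadratic model at the current
iterate, solves the trust-region subproblem over the full space or the 2D
subspace, falls back to reflection/truncation/constrained-Cauchy stepback
when the proposal leaves the box, evaluates the trial point, and accepts the
step when the ratio ``rho`` of actual to predicted decrease exceeds the
threshold ``mu`` (default 0, i.e. any true decrease with a positive
prediction).  The radius doubles when the model is accurate (``rho > 0.75``)
and the step presses against the trust region (``|p| > 0.9 Delta`` in scaled
coordinates), and shrinks to ``min(Delta, |p|)/4`` when the prediction is
poor (``rho < 0.25``) or the objective could not be evaluated.

One gradient evaluation is spent per iteration (at the trial point); rejected
steps keep the cached evaluation at the current iterate, so the gradient
count equals the iteration count.

Every iteration appends a trace record with the numerical-health flags used
for post-hoc analysis: whether the transformed Hessian was numerically
singular, whether the raw approximation had a negative eigenvalue beyond
noise, whether the trial evaluation failed, whether stepback was needed, and
whether radius and Hessian were updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .bounds import (
    augmented_model,
    constrained_cauchy,
    make_scaling,
    reflect_step,
    select_step,
    truncate_step,
)
from .diagnostics import has_negative_eigenvalue, is_singular
from .hessians import HessianScheme, make_scheme
from .objective import Evaluation, Objective, SearchDomain
from .subproblem import QuadraticModel, solve_2d, solve_nd

__all__ = [
    "OptimizerOptions",
    "OptimizerResult",
    "step_ratio",
    "update_radius",
    "check_convergence",
    "minimize",
    "TRACE_COLUMNS",
]

#: trace schema, one row per iteration
TRACE_COLUMNS = (
    "iteration",
    "fval",
    "fval_trial",
    "gnorm",
    "delta",
    "rho",
    "step_norm",
    "step_norm_scaled",
    "accepted",
    "step_kind",
    "delta_updated",
    "hessian_updated",
    "singular_transformed_hessian",
    "negative_eigenvalue",
    "eval_failed",
    "boundary_constrained",
)


@dataclass
class OptimizerOptions:
    """Tunable settings of the trust-region loop.

    ``scheme`` may be a scheme name (see :func:`irtr.hessians.make_scheme`)
    or a ready :class:`~irtr.hessians.HessianScheme` instance.  ``subspace``
    selects the exact full-space subproblem solver (``"ND"``) or the
    two-dimensional subspace solver (``"2D"``).  ``max_reflections=None``
    allows arbitrarily many reflections up to the first local minimum along
    the reflected path; ``1`` reproduces the single-reflection variant.
    """

    scheme: Union[str, HessianScheme] = "GN"
    subspace: str = "2D"
    max_reflections: Optional[int] = None
    mu: float = 0.0
    ratio_low: float = 0.25
    ratio_high: float = 0.75
    boundary_fraction: float = 0.9
    expand_factor: float = 2.0
    shrink_factor: float = 0.25
    step_tol: float = 1e-6
    max_iter: int = 10**5
    delta_init: float = 1.0
    delta_min: float = 1e-16
    scheme_options: dict = field(default_factory=dict)
    record_theta: bool = True

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("acceptance threshold mu must be >= 0")
        if not 0 < self.ratio_low < self.ratio_high < 1:
            raise ValueError("need 0 < ratio_low < ratio_high < 1")
        if self.subspace.upper() not in ("2D", "ND"):
            raise ValueError("subspace must be '2D' or 'ND'")

    def build_scheme(self) -> HessianScheme:
        if isinstance(self.scheme, HessianScheme):
            return self.scheme
        return make_scheme(self.scheme, **self.scheme_options)


@dataclass
class OptimizerResult:
    """Final iterate plus the complete per-iteration trace."""

    theta: np.ndarray
    fval: float
    grad: Optional[np.ndarray]
    status: str  # step_tolerance | max_iterations | failure
    n_iter: int
    n_grad: int
    trace: pd.DataFrame
    theta_trace: Optional[np.ndarray] = None

    @property
    def converged(self) -> bool:
        return self.status == "step_tolerance"

    def trace_to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)

    def trace_to_hdf5(self, path, key: str = "trace") -> None:
        import h5py

        with h5py.File(path, "a") as h5:
            grp = h5.require_group(key)
            for col in self.trace.columns:
                data = self.trace[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                if col in grp:
                    del grp[col]
                grp.create_dataset(col, data=data)
            if self.theta_trace is not None:
                if "theta" in grp:
                    del grp["theta"]
                grp.create_dataset("theta", data=self.theta_trace)


def step_ratio(actual_decrease: float, predicted_decrease: float) -> float:
    """Ratio of actual to predicted decrease; 0 for non-positive predictions.

    A non-positive predicted decrease (possible once the boundary
    augmentation enters the model) would otherwise let a simultaneous
    decrease of both quantities masquerade as an accurate model; forcing the
    ratio to zero blocks spurious acceptance and radius growth.
    """
    if not (np.isfinite(actual_decrease) and np.isfinite(predicted_decrease)):
        raise ValueError("step ratio requires finite decreases")
    if predicted_decrease <= 0.0:
        return 0.0
    return actual_decrease / predicted_decrease


def update_radius(
    delta: float,
    rho: float,
    step_norm: float,
    eval_failed: bool,
    options: Optional[OptimizerOptions] = None,
) -> tuple[float, bool]:
    """Trust-region radius update; returns ``(delta_new, updated)``.

    Doubles the radius for accurate predictions with a boundary step, shrinks
    to ``min(delta, |p|)/4`` for poor predictions or failed evaluations,
    leaves it unchanged in the middle band.  The ``updated`` flag feeds the
    hybrid scheme's stall counter.
    """
    opt = options or OptimizerOptions()
    if eval_failed:
        new = min(delta, step_norm) * opt.shrink_factor
    elif rho < opt.ratio_low:
        new = min(delta, step_norm) * opt.shrink_factor
    elif rho > opt.ratio_high and step_norm > opt.boundary_fraction * delta:
        new = opt.expand_factor * delta
    else:
        new = delta
    return new, new != delta


def check_convergence(
    step_norm: float, iteration: int, options: OptimizerOptions
) -> Optional[str]:
    """Termination status after an accepted step, or None to continue."""
    if step_norm < options.step_tol:
        return "step_tolerance"
    if iteration >= options.max_iter:
        return "max_iterations"
    return None


def minimize(
    objective: Objective,
    theta0: np.ndarray,
    domain: SearchDomain,
    options: Optional[OptimizerOptions] = None,
) -> OptimizerResult:
    """Run the bound-constrained trust-region iteration from ``theta0``."""
    opt = options or OptimizerOptions()
    theta = np.array(theta0, dtype=float)
    if theta.shape != domain.lb.shape:
        raise ValueError("start point and domain dimensions differ")
    if not domain.contains(theta, strict=True):
        raise ValueError("start point must lie strictly inside the domain")

    rows: list[dict] = []
    thetas: list[np.ndarray] = []

    ev = objective(theta)
    if not ev.ok:
        return OptimizerResult(
            theta=theta,
            fval=np.nan,
            grad=None,
            status="failure",
            n_iter=0,
            n_grad=1,
            trace=pd.DataFrame(columns=list(TRACE_COLUMNS)),
            theta_trace=np.empty((0, theta.size)),
        )

    scheme = opt.build_scheme()
    if scheme.requires_residuals and not ev.has_residuals:
        raise ValueError(
            f"scheme {scheme.name} requires residuals and a residual Jacobian"
        )
    scheme.initialize(theta.size, ev)
    B = scheme.current()

    delta = float(opt.delta_init)
    solver = solve_nd if opt.subspace.upper() == "ND" else solve_2d
    status = "max_iterations"
    n_grad = 0
    iteration = 0

    while iteration < opt.max_iter:
        iteration += 1
        scaling = make_scaling(theta, ev.g, B, domain)
        aug = augmented_model(ev.f, ev.g, B, scaling)
        model_hat = QuadraticModel(f=ev.f, g=scaling.g_hat, B=scaling.B_hat)
        sol = solver(model_hat, delta)
        p = scaling.d * sol.p
        step_kind = sol.kind
        model_value = aug.value(p)
        boundary_constrained = not domain.contains(theta + p, strict=True)
        if boundary_constrained:
            cands = [
                truncate_step(aug, p, theta, domain),
                constrained_cauchy(aug, scaling, theta, domain, delta),
            ]
            if np.linalg.norm(p) > 0:
                cands.insert(
                    0,
                    reflect_step(aug, p, theta, domain, opt.max_reflections),
                )
            chosen = select_step(cands)
            p = chosen.p
            step_kind = chosen.kind
            model_value = chosen.model_value

        with np.errstate(divide="ignore", invalid="ignore"):
            step_norm_scaled = float(np.linalg.norm(p / scaling.d))
        step_norm = float(np.linalg.norm(p))
        predicted = ev.f - model_value

        trial = objective(theta + p)
        n_grad += 1
        eval_failed = not trial.ok
        if eval_failed:
            rho = 0.0
            accepted = False
            delta_new = min(delta, step_norm_scaled) * opt.shrink_factor
            delta_updated = delta_new != delta
        else:
            rho = step_ratio(ev.f - trial.f, predicted)
            accepted = rho > opt.mu
            delta_new, delta_updated = update_radius(
                delta, rho, step_norm_scaled, False, opt
            )
        scheme.notify_radius(delta_updated)

        hessian_updated = True
        if accepted:
            scheme.update(p, trial.g - ev.g, trial, ev)
            hessian_updated = scheme.last_update_performed

        rows.append(
            {
                "iteration": iteration,
                "fval": ev.f,
                "fval_trial": trial.f if trial.ok else np.nan,
                "gnorm": float(np.linalg.norm(ev.g)),
                "delta": delta,
                "rho": rho,
                "step_norm": step_norm,
                "step_norm_scaled": step_norm_scaled,
                "accepted": accepted,
                "step_kind": step_kind,
                "delta_updated": delta_updated,
                "hessian_updated": hessian_updated,
                "singular_transformed_hessian": is_singular(scaling.B_hat),
                "negative_eigenvalue": has_negative_eigenvalue(B),
                "eval_failed": eval_failed,
                "boundary_constrained": boundary_constrained,
            }
        )
        if opt.record_theta:
            thetas.append(theta.copy())

        if accepted:
            theta = theta + p
            ev = trial
            B = scheme.current()
            term = check_convergence(step_norm, iteration, opt)
            if term == "step_tolerance":
                status = term
                delta = delta_new
                break
        delta = delta_new
        if delta < opt.delta_min:
            status = "failure"
            break

    trace = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    return OptimizerResult(
        theta=theta,
        fval=ev.f,
        grad=ev.g,
        status=status,
        n_iter=iteration,
        n_grad=n_grad,
        trace=trace,
        theta_trace=np.array(thetas) if opt.record_theta else None,
    )
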