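"""Numerical trace statistics and multistart performance metrics.

A multistart study summarizes its runs by three numbers for a consistency
threshold ``tau``: the success count ``gamma`` (runs whose final objective
lies within ``tau`` of the best final value), the convergence rate
``nu = 1/n_grad`` with ``n_grad`` the total number of gradient evaluations
across all runs, and the performance ``phi = gamma/n_grad = gamma * nu``.
The default ``tau = 2`` corresponds to the largest objective-function
difference at which a model cannot be rejected under the AIC.

Per-run trace statistics quantify numerical health: fractions of iterations
with a numerically singular transformed Hessian, with negative-eigenvalue
approximations, without radius or Hessian updates, with failed objective
evaluations, with boundary-constrained proposals, and with constrained
Cauchy fallback steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "is_singular",
    "has_negative_eigenvalue",
    "compute_metrics",
    "trace_statistics",
    "startpoint_overlap",
    "MultistartResult",
]

_EPS = float(np.spacing(1.0))


def is_singular(B_hat: np.ndarray) -> bool:
    """Numerical singularity: condition number above ``1/spacing(1)``."""
    B_hat = np.asarray(B_hat, dtype=float)
    if B_hat.ndim != 2 or B_hat.shape[0] != B_hat.shape[1]:
        raise ValueError("expected a square matrix")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        cond = np.linalg.cond(B_hat)
    return bool(not np.isfinite(cond) or cond > 1.0 / _EPS)


def has_negative_eigenvalue(B: np.ndarray) -> bool:
    """Negative eigenvalue beyond noise: ``lam_min < -eps * |lam_max|``."""
    B = np.asarray(B, dtype=float)
    lam = np.linalg.eigvalsh(0.5 * (B + B.T))
    lam_max_abs = float(np.abs(lam).max(initial=0.0))
    return bool(lam[0] < -_EPS * lam_max_abs)


def compute_metrics(
    final_values: Sequence[float],
    n_grad_total: int,
    tau: float = 2.0,
) -> tuple[int, float, float]:
    """Success count, convergence rate and performance ``(gamma, nu, phi)``.

    ``gamma`` counts runs with ``f_final - min(f_final) < tau`` over the
    finite final values; non-finite entries (failed runs) count as
    unsuccessful but their gradient evaluations are included in
    ``n_grad_total`` by the caller.
    """
    finals = np.asarray(list(final_values), dtype=float)
    if finals.size == 0:
        raise ValueError("need at least one finished run")
    finite = finals[np.isfinite(finals)]
    if finite.size == 0:
        gamma = 0
    else:
        gamma = int(np.sum(finite - finite.min() < tau))
    if n_grad_total <= 0:
        raise ValueError("total gradient evaluations must be positive")
    nu = 1.0 / n_grad_total
    return gamma, nu, gamma * nu


def trace_statistics(result) -> dict:
    """Per-run iteration fractions from an optimizer trace.

    Accepts an :class:`~irtr.optimizer.OptimizerResult` or its trace
    DataFrame.  All fractions lie in [0, 1]; the Cauchy-step fraction is
    relative to all iterations and can never exceed the boundary-constrained
    fraction (Cauchy steps only arise from stepback).
    """
    trace = result if isinstance(result, pd.DataFrame) else result.trace
    n = len(trace)
    if n == 0:
        raise ValueError("empty optimizer trace")

    def frac(col: str, invert: bool = False) -> float:
        vals = trace[col].to_numpy(dtype=bool)
        return float((~vals if invert else vals).mean())

    return {
        "n_iterations": n,
        "frac_singular_transformed_hessian": frac(
            "singular_transformed_hessian"
        ),
        "frac_negative_eigenvalue": frac("negative_eigenvalue"),
        "frac_no_delta_update": frac("delta_updated", invert=True),
        "frac_no_hessian_update": frac("hessian_updated", invert=True),
        "frac_eval_failed": frac("eval_failed"),
        "frac_boundary_constrained": frac("boundary_constrained"),
        "frac_cauchy_steps": float(
            (trace["step_kind"].to_numpy() == "cauchy").mean()
        ),
        "frac_accepted": frac("accepted"),
    }


def startpoint_overlap(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard overlap of two sets of successful start indices.

    Two empty sets overlap perfectly in the degenerate sense; by convention
    the score is 0 there so schemes with no successes never look similar.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class MultistartResult:
    """Aggregated outcome of a multistart study for one optimizer setting.

    Holds per-run final values, iteration counts, exit statuses and start
    points; metrics are derived lazily for any threshold ``tau``.
    """

    final_values: np.ndarray
    n_iterations: np.ndarray
    statuses: list
    start_points: np.ndarray
    tau: float = 2.0
    traces: Optional[list] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.final_values = np.asarray(self.final_values, dtype=float)
        self.n_iterations = np.asarray(self.n_iterations, dtype=int)

    @property
    def n_runs(self) -> int:
        return self.final_values.size

    @property
    def n_grad_total(self) -> int:
        """One gradient evaluation per iteration, summed over runs."""
        return int(self.n_iterations.sum())

    def metrics(self, tau: Optional[float] = None) -> dict:
        tau = self.tau if tau is None else tau
        gamma, nu, phi = compute_metrics(
            self.final_values, self.n_grad_total, tau
        )
        return {
            "tau": tau,
            "gamma": gamma,
            "nu": nu,
            "phi": phi,
            "n_runs": self.n_runs,
            "n_grad_total": self.n_grad_total,
        }

    def success_indices(self, tau: Optional[float] = None) -> set:
        """Start indices of successful runs (for overlap scores)."""
        tau = self.tau if tau is None else tau
        finite = self.final_values[np.isfinite(self.final_values)]
        if finite.size == 0:
            return set()
        best = finite.min()
        return {
            int(i)
            for i, f in enumerate(self.final_values)
            if np.isfinite(f) and f - best < tau
        }

    def waterfall(self) -> np.ndarray:
        """Final objective values sorted ascending (waterfall-plot data)."""
        return np.sort(self.final_values)
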