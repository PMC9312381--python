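"""Objective-function contract shared by the optimizer and all Hessian schemes.

The optimizer treats the objective as a black box that, at a parameter vector
``theta``, returns the scalar objective value and its gradient, and — for
least-squares aware Hessian schemes — the standardized residual vector, its
Jacobian, and optionally the noise scales and their parameter gradients.

The canonical objective is the negative log-likelihood of independent
Gaussian measurements with noise scales ``sigma`` (possibly parameter
dependent),

    J(theta) = 1/2 * sum_m [ log(2 pi sigma_m^2) + ((ybar_m - y_m)/sigma_m)^2 ]

where the sum runs over a flat index ``m`` enumerating all
(observable, timepoint) pairs.  The factor 1/2 is part of the contract: all
downstream quantities (Gauss-Newton products, success thresholds) assume this
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Evaluation",
    "SearchDomain",
    "Objective",
    "nll_from_residuals",
    "residual_objective",
]


@dataclass
class Evaluation:
    """Result of evaluating an objective at a single parameter vector.

    ``ok=False`` signals an evaluation failure (e.g. a non-finite value or a
    user-reported simulation failure); callers must ignore all other fields in
    that case.  ``r`` holds standardized residuals ``(ybar - y)/sigma`` as a
    flat vector, ``jac`` its Jacobian with shape ``(n_res, n_par)``.
    ``sigma``/``dsigma`` carry the noise scales and their parameter gradients
    (shape ``(n_res,)`` and ``(n_res, n_par)``) for schemes that need the
    error-residual correction.  ``hess`` may carry a user-supplied exact
    Hessian.
    """

    f: float
    g: Optional[np.ndarray] = None
    r: Optional[np.ndarray] = None
    jac: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    dsigma: Optional[np.ndarray] = None
    hess: Optional[np.ndarray] = None
    ok: bool = True

    def __post_init__(self) -> None:
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float)
        # non-finite value or gradient is treated like any other failure
        if self.ok:
            if not np.isfinite(self.f):
                self.ok = False
            elif self.g is not None and not np.all(np.isfinite(self.g)):
                self.ok = False

    @property
    def has_residuals(self) -> bool:
        return self.r is not None and self.jac is not None


# the callable type every scheme and the loop consume
Objective = Callable[[np.ndarray], Evaluation]


@dataclass(frozen=True)
class SearchDomain:
    """Box domain ``l_i < theta_i < u_i``; entries may be infinite."""

    lb: np.ndarray
    ub: np.ndarray

    def __init__(self, lb, ub) -> None:
        lb = np.atleast_1d(np.asarray(lb, dtype=float))
        ub = np.atleast_1d(np.asarray(ub, dtype=float))
        if lb.shape != ub.shape:
            raise ValueError("lower and upper bounds must have equal length")
        if not np.all(lb < ub):
            raise ValueError("bounds must satisfy l_i < u_i for all i")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @classmethod
    def unbounded(cls, n: int) -> "SearchDomain":
        return cls(np.full(n, -np.inf), np.full(n, np.inf))

    @property
    def n_par(self) -> int:
        return self.lb.size

    def contains(self, theta: np.ndarray, strict: bool = True) -> bool:
        theta = np.asarray(theta, dtype=float)
        if strict:
            return bool(np.all(theta > self.lb) and np.all(theta < self.ub))
        return bool(np.all(theta >= self.lb) and np.all(theta <= self.ub))

    def clip_interior(self, theta: np.ndarray, rel: float = 1e-10) -> np.ndarray:
        """Project ``theta`` strictly inside the box (used for start points)."""
        theta = np.array(theta, dtype=float)
        width = np.where(
            np.isfinite(self.lb) & np.isfinite(self.ub), self.ub - self.lb, 1.0
        )
        eps = rel * np.maximum(width, 1.0)
        lo = np.where(np.isfinite(self.lb), self.lb + eps, -np.inf)
        hi = np.where(np.isfinite(self.ub), self.ub - eps, np.inf)
        return np.clip(theta, lo, hi)


def nll_from_residuals(ybar, y, sigma) -> float:
    """Gaussian negative log-likelihood of data ``ybar`` under model ``y``.

    Returns ``1/2 sum [log(2 pi sigma^2) + ((ybar - y)/sigma)^2]``.
    """
    ybar = np.asarray(ybar, dtype=float)
    y = np.asarray(y, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if not (ybar.shape == y.shape == sigma.shape):
        raise ValueError("ybar, y and sigma must have equal shapes")
    if np.any(sigma <= 0):
        raise ValueError("noise scales sigma must be strictly positive")
    res = (ybar - y) / sigma
    return float(0.5 * np.sum(np.log(2.0 * np.pi * sigma**2) + res**2))


def residual_objective(
    ybar: np.ndarray,
    model: Callable[[np.ndarray], tuple],
    sigma_fun: Optional[Callable[[np.ndarray], tuple]] = None,
    sigma: Optional[np.ndarray] = None,
) -> Objective:
    """Assemble a full likelihood :data:`Objective` from model callables.

    Parameters
    ----------
    ybar
        Flat data vector.
    model
        ``theta -> (y, dy)`` with ``y`` shape ``(n_res,)`` and ``dy`` shape
        ``(n_res, n_par)``.
    sigma_fun
        Optional ``theta -> (sigma, dsigma)`` for parameter-dependent noise;
        mutually exclusive with the constant ``sigma``.
    sigma
        Constant noise-scale vector (or scalar broadcast over residuals).

    The returned objective reports the standardized residuals
    ``r = (ybar - y)/sigma`` and their full Jacobian
    ``dr/dtheta = -dy/sigma - r * dsigma/sigma``, together with the gradient

        g = Jr^T r + sum_m (dsigma_m / sigma_m),

    where the second term is the gradient of the ``log sigma`` part of the
    likelihood.  Any non-finite model output flags the evaluation as failed.
    """
    ybar = np.asarray(ybar, dtype=float)
    if (sigma_fun is None) == (sigma is None):
        raise ValueError("provide exactly one of sigma_fun or sigma")
    if sigma is not None:
        sigma_const = np.broadcast_to(
            np.asarray(sigma, dtype=float), ybar.shape
        ).copy()
        if np.any(sigma_const <= 0):
            raise ValueError("noise scales sigma must be strictly positive")

    def evaluate(theta: np.ndarray) -> Evaluation:
        theta = np.asarray(theta, dtype=float)
        n_par = theta.size
        try:
            y, dy = model(theta)
        except FloatingPointError:
            return Evaluation(f=np.nan, ok=False)
        y = np.asarray(y, dtype=float)
        dy = np.asarray(dy, dtype=float)
        if sigma_fun is not None:
            sig, dsig = sigma_fun(theta)
            sig = np.broadcast_to(np.asarray(sig, dtype=float), ybar.shape).copy()
            dsig = np.broadcast_to(
                np.asarray(dsig, dtype=float), (ybar.size, n_par)
            ).copy()
        else:
            sig = sigma_const
            dsig = np.zeros((ybar.size, n_par))
        if (
            not np.all(np.isfinite(y))
            or not np.all(np.isfinite(dy))
            or not np.all(np.isfinite(sig))
            or np.any(sig <= 0)
        ):
            return Evaluation(f=np.nan, ok=False)
        r = (ybar - y) / sig
        jac = -dy / sig[:, None] - (r / sig)[:, None] * dsig
        f = nll_from_residuals(ybar, y, sig)
        g = jac.T @ r + (dsig / sig[:, None]).sum(axis=0)
        return Evaluation(f=f, g=g, r=r, jac=jac, sigma=sig, dsigma=dsig)

    return evaluate
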