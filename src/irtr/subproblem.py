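"""Exact solvers for the trust-region subproblem.

Minimize the local quadratic model ``m(p) = f + g^T p + 1/2 p^T B p`` subject
to ``|p| <= Delta``, either over the full parameter space (ND; eigenvalue
decomposition of ``B`` with a safeguarded secular-equation solve, including
the hard case) or over the two-dimensional subspace spanned by the gradient
and the Newton direction (2D; the projected 2x2 problem is solved exactly by
the same machinery).  Dense eigensolvers are used throughout: for likelihood
fits dominated by model simulation the decomposition cost is negligible below
roughly a thousand parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import brentq

__all__ = [
    "QuadraticModel",
    "StepCandidate",
    "newton_direction",
    "negative_curvature_direction",
    "solve_nd",
    "solve_2d",
]

_EPS = float(np.finfo(float).eps)
_BOUNDARY_TOL = 1e-10  # tolerance on | |p| - Delta | for boundary solutions


@dataclass(frozen=True)
class QuadraticModel:
    """Local quadratic model around the current iterate."""

    f: float
    g: np.ndarray
    B: np.ndarray

    def value(self, p: np.ndarray) -> float:
        p = np.asarray(p, dtype=float)
        return float(self.f + self.g @ p + 0.5 * p @ (self.B @ p))


@dataclass
class StepCandidate:
    """A proposed step with its provenance and quadratic-model value."""

    p: np.ndarray
    kind: str  # subspace2d | exactND | reflected | truncated | cauchy
    model_value: float
    norm: float

    @classmethod
    def from_model(
        cls, p: np.ndarray, kind: str, model: QuadraticModel
    ) -> "StepCandidate":
        p = np.asarray(p, dtype=float)
        return cls(
            p=p,
            kind=kind,
            model_value=model.value(p),
            norm=float(np.linalg.norm(p)),
        )


def _check_symmetric(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    scale = max(1.0, float(np.abs(B).max(initial=0.0)))
    if not np.allclose(B, B.T, atol=1e-8 * scale):
        raise ValueError("model Hessian must be symmetric")
    return 0.5 * (B + B.T)


def newton_direction(B: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solution of ``B d = -g`` (pseudoinverse)."""
    B = _check_symmetric(B)
    g = np.asarray(g, dtype=float)
    d, *_ = scipy.linalg.lstsq(B, -g, lapack_driver="gelsd")
    return d


def negative_curvature_direction(
    B: np.ndarray, g: np.ndarray | None = None
) -> np.ndarray | None:
    """Unit eigenvector of the most negative eigenvalue, or None.

    Fires only when the smallest eigenvalue is negative beyond numerical
    noise, ``lambda_min < -spacing(1) * |lambda_max|``.  When a gradient is
    supplied the sign is chosen so the direction is non-ascending,
    ``g^T v <= 0``.
    """
    B = _check_symmetric(B)
    lam, Q = np.linalg.eigh(B)
    lam_min = lam[0]
    lam_max_abs = float(np.abs(lam).max())
    if lam_min >= -np.spacing(1.0) * lam_max_abs:
        return None
    v = Q[:, 0]
    if g is not None and float(np.asarray(g) @ v) > 0:
        v = -v
    return v


def _secular_step(lam: np.ndarray, gt: np.ndarray, mu: float) -> np.ndarray:
    return -gt / (lam + mu)


def solve_nd(model: QuadraticModel, delta: float) -> StepCandidate:
    """Global minimizer of the model over the ball ``|p| <= Delta``.

    Eigendecomposition approach: in the eigenbasis the boundary solution is
    ``p_i = -g_i / (lambda_i + mu)`` with the multiplier ``mu >= max(0,
    -lambda_min)`` chosen so ``|p(mu)| = Delta``; found by bracketed
    root-finding on the secular equation ``1/|p(mu)| = 1/Delta``.  In the hard
    case (gradient orthogonal to the bottom eigenspace and the limiting step
    interior) an eigenvector component fills the step up to the boundary.
    """
    if delta <= 0:
        raise ValueError("trust-region radius must be positive")
    B = _check_symmetric(model.B)
    g = np.asarray(model.g, dtype=float)
    lam, Q = np.linalg.eigh(B)
    gt = Q.T @ g
    lam_min = float(lam[0])
    scale = max(1.0, float(np.abs(lam).max()))

    def finish(pt: np.ndarray) -> StepCandidate:
        return StepCandidate.from_model(Q @ pt, "exactND", model)

    # interior Newton point for positive definite B
    if lam_min > _EPS * scale:
        pt = _secular_step(lam, gt, 0.0)
        if np.linalg.norm(pt) <= delta:
            return finish(pt)

    mu_lb = max(0.0, -lam_min)
    # pseudoinverse (limiting) step at the lower multiplier bound
    shifted = lam + mu_lb
    active = shifted > _EPS * max(scale, mu_lb)
    p0 = np.zeros_like(gt)
    p0[active] = -gt[active] / shifted[active]
    blowup = bool(np.any(~active & (np.abs(gt) > _EPS * max(1.0, np.linalg.norm(gt)))))

    if not blowup and np.linalg.norm(p0) <= delta:
        if mu_lb == 0.0:
            # singular PSD B with consistent gradient: interior minimizer
            return finish(p0)
        # hard case: pad with a bottom eigenvector up to the boundary
        tau = np.sqrt(max(delta**2 - float(p0 @ p0), 0.0))
        e = np.zeros_like(gt)
        e[0] = tau
        return finish(p0 + e)

    # boundary solution: root of the secular equation in (mu_lb, inf)
    def phi(mu: float) -> float:
        with np.errstate(divide="ignore", over="ignore"):
            nrm = float(np.linalg.norm(_secular_step(lam, gt, mu)))
        return 1.0 / nrm - 1.0 / delta

    lo = mu_lb + max(_EPS * max(scale, mu_lb), 1e-300)
    for _ in range(120):
        if phi(lo) < 0.0:
            break
        lo_new = mu_lb + 0.5 * (lo - mu_lb)
        if lo_new <= mu_lb or lo_new >= lo:
            break
        lo = lo_new
    if phi(lo) >= 0.0:
        # the multiplier is mu_lb to machine precision: treat as hard case,
        # padding the active-only limiting step along the bottom eigenvector
        nrm = float(np.linalg.norm(p0))
        if nrm >= delta:
            return finish(p0 * (delta / nrm))
        tau = np.sqrt(max(delta**2 - nrm**2, 0.0))
        e = np.zeros_like(gt)
        e[0] = tau if gt[0] <= 0 else -tau
        return finish(p0 + e)
    hi = max(mu_lb + np.linalg.norm(gt) / delta, lo * 2 + 1.0)
    while phi(hi) <= 0.0:
        hi = 2.0 * hi + 1.0
    mu = brentq(phi, lo, hi, xtol=1e-300, rtol=8 * _EPS, maxiter=200)
    pt = _secular_step(lam, gt, mu)
    nrm = float(np.linalg.norm(pt))
    if abs(nrm - delta) > _BOUNDARY_TOL * max(1.0, delta):
        # near-hard case: the secular root falls between adjacent floats and
        # the bottom eigencomponent jumps across it; the correct limit is the
        # active-only step padded along the bottom eigenvector
        nrm0 = float(np.linalg.norm(p0))
        if nrm0 >= delta:
            return finish(p0 * (delta / nrm0))
        tau = np.sqrt(max(delta**2 - nrm0**2, 0.0))
        e = np.zeros_like(gt)
        e[0] = tau if gt[0] <= 0 else -tau
        return finish(p0 + e)
    return finish(pt)


def solve_2d(model: QuadraticModel, delta: float) -> StepCandidate:
    """Exact solve over the plane spanned by gradient and Newton direction.

    For an indefinite model Hessian the Newton direction is replaced by the
    direction of strongest negative curvature; when the two spanning vectors
    are parallel the problem degenerates to a line and is solved there.  The
    returned candidate's model value never exceeds that of the Cauchy point
    (the gradient lies in the subspace).
    """
    if delta <= 0:
        raise ValueError("trust-region radius must be positive")
    B = _check_symmetric(model.B)
    g = np.asarray(model.g, dtype=float)
    n = g.size
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0.0:
        return StepCandidate.from_model(np.zeros(n), "subspace2d", model)

    v_neg = negative_curvature_direction(B, g)
    second = v_neg if v_neg is not None else newton_direction(B, g)

    basis = [g / gnorm]
    if second is not None and np.linalg.norm(second) > 0:
        w = second - (second @ basis[0]) * basis[0]
        wn = float(np.linalg.norm(w))
        if wn > 1e-12 * float(np.linalg.norm(second)):
            basis.append(w / wn)
    Qb = np.stack(basis, axis=1)  # (n, k), k in {1, 2}

    sub_model = QuadraticModel(f=model.f, g=Qb.T @ g, B=Qb.T @ B @ Qb)
    sub = solve_nd(sub_model, delta)
    p = Qb @ sub.p
    return StepCandidate.from_model(p, "subspace2d", model)
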