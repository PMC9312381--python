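"""Interior box-constraint handling: affine scaling and stepback strategies.

Near a bound the optimization variables are rescaled by the distance to the
bound the gradient points toward (Coleman-Li affine scaling).  The scaling
vector ``v`` and the diagonal ``dv`` of its derivative define the transformed
model

    B_hat = D B D + diag(g) dv,      g_hat = D g,      D = diag(|v|^(1/2)),

whose second, elementwise non-negative term also regularizes the subproblem.
The trust region lives in the scaled coordinates ``p_hat = D^{-1} p``; in the
original coordinates the same model reads

    m(p) = f + g^T p + 1/2 p^T (B + diag(g * dv / |v|)) p,

which is the "augmented" model used to compare all step candidates and to
compute the predicted decrease.

When a proposed step leaves the box, three fallback candidates are built and
the one with the lowest augmented-model value is taken: the proposal
reflected at the boundary (single or arbitrarily many reflections up to the
first local minimum along the folded path), the proposal truncated at the
boundary, and the constrained Cauchy step (the model minimizer along the
scaled steepest-descent direction truncated at the boundary).  Every
candidate is backed off to be strictly interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objective import SearchDomain
from .subproblem import QuadraticModel, StepCandidate

__all__ = [
    "ScalingData",
    "scaling_vector",
    "transform_model",
    "make_scaling",
    "augmented_model",
    "reflect_step",
    "truncate_step",
    "constrained_cauchy",
    "select_step",
]

_THETA_EPS = 1e-10  # relative strict-interior backoff
_KIND_ORDER = {"reflected": 0, "truncated": 1, "cauchy": 2}


def scaling_vector(
    theta: np.ndarray, g: np.ndarray, domain: SearchDomain
) -> tuple[np.ndarray, np.ndarray]:
    """Coleman-Li scaling vector ``v`` and the diagonal ``dv`` of its Jacobian.

    Per coordinate: distance to the upper bound when the gradient is negative
    and the upper bound finite; distance to the lower bound when the gradient
    is non-negative and the lower bound finite; constant -1 / +1 for the
    respective infinite-bound branches.  ``dv`` is the diagonal of the
    Jacobian of ``|v|`` with entries in {0, +1, -1}: +1 on the lower-bound
    branch (v > 0), -1 on the upper-bound branch (v < 0), 0 on the constant
    branches.  This sign convention makes the model augmentation
    ``diag(g) dv = diag(|g|)`` on bounded coordinates, hence positive
    semi-definite.
    """
    theta = np.asarray(theta, dtype=float)
    g = np.asarray(g, dtype=float)
    if not domain.contains(theta, strict=True):
        raise ValueError("scaling requires a strictly interior point")
    v = np.empty_like(theta)
    dv = np.zeros_like(theta)
    down = g < 0
    up_fin = np.isfinite(domain.ub)
    lo_fin = np.isfinite(domain.lb)

    sel = down & up_fin
    v[sel] = theta[sel] - domain.ub[sel]
    dv[sel] = -1.0
    sel = ~down & lo_fin
    v[sel] = theta[sel] - domain.lb[sel]
    dv[sel] = 1.0
    v[down & ~up_fin] = -1.0
    v[~down & ~lo_fin] = 1.0
    return v, dv


def transform_model(
    B: np.ndarray, g: np.ndarray, v: np.ndarray, dv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transformed Hessian, gradient and scaling diagonal.

    Returns ``(B_hat, g_hat, d)`` with ``B_hat = D B D + diag(g * dv)``,
    ``g_hat = D g`` and ``d = |v|^(1/2)`` the diagonal of ``D``.
    """
    B = np.asarray(B, dtype=float)
    g = np.asarray(g, dtype=float)
    d = np.sqrt(np.abs(v))
    B_hat = d[:, None] * B * d[None, :] + np.diag(g * dv)
    return 0.5 * (B_hat + B_hat.T), d * g, d


@dataclass
class ScalingData:
    """Scaling state at the current iterate."""

    v: np.ndarray
    dv: np.ndarray
    d: np.ndarray  # diagonal of D = diag(|v|^1/2)
    B_hat: np.ndarray
    g_hat: np.ndarray


def make_scaling(
    theta: np.ndarray, g: np.ndarray, B: np.ndarray, domain: SearchDomain
) -> ScalingData:
    v, dv = scaling_vector(theta, g, domain)
    B_hat, g_hat, d = transform_model(B, g, v, dv)
    return ScalingData(v=v, dv=dv, d=d, B_hat=B_hat, g_hat=g_hat)


def augmented_model(
    f: float, g: np.ndarray, B: np.ndarray, scaling: ScalingData
) -> QuadraticModel:
    """Quadratic model in original coordinates including the scaling term."""
    aug = np.zeros_like(np.asarray(g, dtype=float))
    finite = scaling.dv != 0
    aug[finite] = g[finite] * scaling.dv[finite] / np.abs(scaling.v[finite])
    return QuadraticModel(f=float(f), g=np.asarray(g, dtype=float), B=B + np.diag(aug))


def _interior_backoff(
    p: np.ndarray, theta: np.ndarray, domain: SearchDomain
) -> np.ndarray:
    """Shrink a step touching a bound so the endpoint is strictly interior."""
    p = np.array(p, dtype=float)
    for _ in range(64):
        if domain.contains(theta + p, strict=True):
            return p
        p *= 1.0 - _THETA_EPS
    # pathological scale: fall back to hard clipping inside the box
    return domain.clip_interior(theta + p, rel=_THETA_EPS) - theta


def _max_feasible_scale(
    p: np.ndarray, theta: np.ndarray, domain: SearchDomain
) -> float:
    """Largest ``alpha`` in [0, 1] with ``theta + alpha p`` inside the box."""
    with np.errstate(divide="ignore", invalid="ignore"):
        to_ub = np.where(p > 0, (domain.ub - theta) / p, np.inf)
        to_lb = np.where(p < 0, (domain.lb - theta) / p, np.inf)
    return float(min(1.0, np.min(np.minimum(to_ub, to_lb), initial=np.inf)))


def truncate_step(
    model: QuadraticModel,
    p: np.ndarray,
    theta: np.ndarray,
    domain: SearchDomain,
) -> StepCandidate:
    """Scale the proposal back to the boundary, then strictly interior."""
    p = np.asarray(p, dtype=float)
    alpha = _max_feasible_scale(p, theta, domain)
    s = _interior_backoff(alpha * p, theta, domain)
    return StepCandidate.from_model(s, "truncated", model)


def reflect_step(
    model: QuadraticModel,
    p: np.ndarray,
    theta: np.ndarray,
    domain: SearchDomain,
    max_reflections: int | None = None,
) -> StepCandidate:
    """Reflect the proposal at the box boundary and minimize along the path.

    The folded path has total length ``|p|``; each boundary crossing flips
    the sign of the violated coordinate's direction component.  The model is
    minimized analytically on every linear segment; the walk stops at the
    first segment with a strictly interior minimizer (the first local minimum
    along the path), when the reflection budget is exhausted
    (``max_reflections=1`` reproduces the single-reflection variant), or when
    the path length is used up.  The best point seen over the explored path is
    returned, backed off strictly interior.
    """
    theta = np.asarray(theta, dtype=float)
    p = np.asarray(p, dtype=float)
    length = float(np.linalg.norm(p))
    if length == 0.0:
        raise ValueError("reflection requires a nonzero proposal")
    cap = max_reflections if max_reflections is not None else 100 * theta.size

    d = p / length
    s0 = np.zeros_like(p)  # step accumulated up to the current segment start
    remaining = length
    best_s = s0.copy()
    best_val = model.value(s0)
    n_reflections = 0

    for _ in range(100 * theta.size + 2):
        x = theta + s0
        # distance to the first boundary crossing along d
        with np.errstate(divide="ignore", invalid="ignore"):
            to_ub = np.where(d > 0, (domain.ub - x) / d, np.inf)
            to_lb = np.where(d < 0, (domain.lb - x) / d, np.inf)
        dist = np.minimum(to_ub, to_lb)
        t_cross = float(np.min(dist, initial=np.inf))
        t_cross = max(t_cross, 0.0)
        seg_len = min(t_cross, remaining)

        # analytic minimum of the quadratic model on [0, seg_len]
        grad0 = model.g + model.B @ s0
        b = float(grad0 @ d)
        a = 0.5 * float(d @ (model.B @ d))
        interior_min = None
        if a > 0:
            t_star = -b / (2.0 * a)
            if 0.0 < t_star < seg_len:
                interior_min = t_star
        candidates_t = [seg_len] if interior_min is None else [interior_min]
        for t in candidates_t:
            val = model.value(s0 + t * d)
            if val < best_val:
                best_val = val
                best_s = s0 + t * d

        if interior_min is not None:
            break  # first local minimum along the path
        remaining -= seg_len
        if remaining <= 1e-15 * length:
            break  # path length used up
        # boundary hit: reflect every coordinate that reached its bound
        s0 = s0 + seg_len * d
        hit = dist <= t_cross * (1.0 + 1e-12)
        d = np.where(hit, -d, d)
        n_reflections += 1
        if n_reflections > cap:
            break

    s = _interior_backoff(best_s, theta, domain)
    return StepCandidate.from_model(s, "reflected", model)


def constrained_cauchy(
    model: QuadraticModel,
    scaling: ScalingData,
    theta: np.ndarray,
    domain: SearchDomain,
    delta: float,
) -> StepCandidate:
    """Model minimizer along the scaled steepest-descent direction.

    The direction is ``-D g_hat`` mapped to the original coordinates; the step
    length is limited by the trust-region radius (measured in scaled
    coordinates) and truncated at the box boundary.  Positive curvature along
    the direction gives the closed-form interior minimizer; otherwise the step
    extends to the limiting boundary.
    """
    theta = np.asarray(theta, dtype=float)
    gh_norm = float(np.linalg.norm(scaling.g_hat))
    if gh_norm == 0.0:
        raise ValueError("constrained Cauchy step requires a nonzero gradient")
    d_hat = -scaling.g_hat / gh_norm  # unit direction in scaled coordinates
    d = scaling.d * d_hat  # original coordinates; |p_hat| = t for p = t*d
    with np.errstate(divide="ignore", invalid="ignore"):
        to_ub = np.where(d > 0, (domain.ub - theta) / d, np.inf)
        to_lb = np.where(d < 0, (domain.lb - theta) / d, np.inf)
    t_box = float(np.min(np.minimum(to_ub, to_lb), initial=np.inf))
    t_max = min(delta, t_box)
    b = float(model.g @ d)
    a = 0.5 * float(d @ (model.B @ d))
    if a > 0:
        t_star = min(max(-b / (2.0 * a), 0.0), t_max)
    else:
        t_star = t_max
    if not np.isfinite(t_star):
        t_star = delta
    s = _interior_backoff(t_star * d, theta, domain)
    return StepCandidate.from_model(s, "cauchy", model)


def select_step(candidates: list[StepCandidate]) -> StepCandidate:
    """Lowest augmented-model value wins; ties prefer the longer step, then
    the fixed order reflected > truncated > cauchy."""
    if not candidates:
        raise ValueError("no step candidates to select from")
    return min(
        candidates,
        key=lambda c: (
            c.model_value,
            -c.norm,
            _KIND_ORDER.get(c.kind, 99),
        ),
    )
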