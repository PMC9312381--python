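"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
import scipy.optimize


def tr_oracle(model, delta: float, seed: int = 0, n_dir: int = 4096) -> float:
    """Brute-force reference value of the trust-region subproblem.

    Independent of the package's solvers: scans a dense set of random
    directions with the analytic 1-D minimum along each ray (covering the
    interior) plus the ball boundary, then polishes the best few candidates
    with SLSQP under the norm constraint.  Returns the best model value
    found; by construction an upper bound on the true minimum that is tight
    to high accuracy after polishing.
    """
    g, B, f = model.g, model.B, model.f
    n = g.size
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n_dir, n))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    a = 0.5 * np.einsum("nd,de,ne->n", d, B, d)
    b = d @ g
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(a > 0, np.clip(-b / (2 * a), 0.0, delta), delta)
    vals_ray = b * t + a * t * t
    vals_edge = b * delta + a * delta**2
    pts = [t[np.argmin(vals_ray)] * d[np.argmin(vals_ray)],
           delta * d[np.argmin(vals_edge)],
           np.zeros(n)]

    def mval(p):
        return float(g @ p + 0.5 * p @ (B @ p))

    best = min(mval(p) for p in pts)
    cons = ({"type": "ineq", "fun": lambda p: delta**2 - p @ p},)
    for p0 in pts:
        res = scipy.optimize.minimize(
            mval, p0, constraints=cons, method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.fun < best and np.linalg.norm(res.x) <= delta * (1 + 1e-9):
            best = float(res.fun)
    return f + best


def random_quadratic_model(rng, n=None, kind="generic"):
    """Random quadratic model instance; kinds: generic, indefinite, hard."""
    from irtr.subproblem import QuadraticModel

    n = int(rng.integers(2, 5)) if n is None else n
    A = rng.standard_normal((n, n))
    B = 0.5 * (A + A.T)
    if kind == "indefinite":
        B = B - np.eye(n) * float(np.abs(np.linalg.eigvalsh(B)).max()) * 0.5
        g = rng.standard_normal(n)
    elif kind == "hard":
        # gradient orthogonal to the bottom eigenspace
        lam, Q = np.linalg.eigh(B)
        g = Q[:, 1:] @ rng.standard_normal(n - 1)
    else:
        g = rng.standard_normal(n)
    return QuadraticModel(f=float(rng.standard_normal()), g=g, B=B)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
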