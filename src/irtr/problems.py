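"""Synthetic fixtures: constructible-optimum least-squares problems and a
closed-form two-species conversion model.

``make_nls`` builds nonlinear least-squares problems whose optimum, residual
norm at the optimum, and Gauss-Newton eigenvalue spread ("sloppiness") are
all prescribed by construction: residuals are an affine map with chosen
singular values composed with a smooth coordinate-wise warp that is the
identity to first order at the optimum, plus a residual offset orthogonal to
the Jacobian column space so the gradient vanishes exactly at the target
parameters.

``conversion_model`` is the smallest mass-action system with a non-trivial
likelihood: two species interconverting with rates ``k1`` (forward) and
``k2`` (backward).  The total abundance is conserved, so the observed second
species follows a single closed-form exponential relaxation; data are drawn
with additive i.i.d. Gaussian noise, optionally with the noise scale itself
an estimated parameter (which exercises the error-residual Hessian
correction).

All randomness uses the counter-based Philox generator keyed by the seed, so
fixtures are platform-stable and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .objective import Evaluation, Objective, SearchDomain, residual_objective

__all__ = [
    "SyntheticNLSProblem",
    "ConversionModelFixture",
    "make_nls",
    "conversion_model",
    "rosenbrock_problem",
    "sample_startpoints",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed)))


@dataclass
class SyntheticNLSProblem:
    """A least-squares problem with a fully prescribed optimum.

    ``objective`` evaluates ``f = 1/2 |r|^2`` (unit noise scales; the
    constant likelihood offset is dropped) with analytic residual Jacobian.
    """

    objective: Objective
    theta_true: np.ndarray
    domain: SearchDomain
    residual_norm_at_opt: float
    spectrum_decades: float
    seed: int
    n_par: int
    n_res: int
    _M: np.ndarray = field(repr=False, default=None)
    _r0: np.ndarray = field(repr=False, default=None)

    def gauss_newton_at_optimum(self) -> np.ndarray:
        return self._M.T @ self._M


def make_nls(
    n_par: int,
    n_res: int,
    residual_norm_at_opt: float = 0.0,
    spectrum_decades: float = 0.0,
    domain: Optional[SearchDomain] = None,
    seed: int = 0,
    warp: str = "sinh",
) -> SyntheticNLSProblem:
    """Generate a synthetic nonlinear least-squares problem.

    Residuals are ``r(theta) = M w(theta - theta_true) + r0`` with ``M`` a
    random map whose Gauss-Newton product ``M^T M`` has eigenvalues spaced
    logarithmically over ``spectrum_decades`` decades, ``w`` a coordinate-wise
    warp (``sinh``, identity-to-first-order, or ``linear`` for affine
    residuals), and ``r0`` orthogonal to the columns of ``M`` with
    ``|r0| = residual_norm_at_opt``.  By construction ``theta_true`` is the
    unique global minimizer, the gradient there vanishes, and with zero
    residual norm the Gauss-Newton product is the exact Hessian at the
    optimum.
    """
    if n_par < 1 or n_res < n_par:
        raise ValueError("need n_res >= n_par >= 1")
    if residual_norm_at_opt < 0:
        raise ValueError("residual norm at the optimum must be >= 0")
    if residual_norm_at_opt > 0 and n_res == n_par:
        raise ValueError(
            "a nonzero residual norm requires n_res > n_par (the offset must "
            "be orthogonal to the Jacobian columns)"
        )
    if spectrum_decades < 0 or spectrum_decades > -np.log10(np.finfo(float).eps):
        raise ValueError("requested eigenvalue spread is numerically infeasible")
    if warp not in ("sinh", "linear"):
        raise ValueError("warp must be 'sinh' or 'linear'")

    rng = _rng(seed)
    if domain is None:
        theta_true = rng.uniform(-1.0, 1.0, n_par)
        domain = SearchDomain(theta_true - 2.0, theta_true + 2.0)
    else:
        if domain.n_par != n_par:
            raise ValueError("domain dimension does not match n_par")
        width = domain.ub - domain.lb
        if not np.all(np.isfinite(width)):
            raise ValueError("make_nls requires finite bounds")
        theta_true = domain.lb + width * rng.uniform(0.3, 0.7, n_par)

    # eigenvalues of M^T M spaced over the requested decades
    if n_par == 1:
        eigs = np.array([1.0])
    else:
        eigs = np.logspace(0.0, spectrum_decades, n_par)
    sv = np.sqrt(eigs)
    U, _ = np.linalg.qr(rng.standard_normal((n_res, n_par)))
    V, _ = np.linalg.qr(rng.standard_normal((n_par, n_par)))
    M = U @ (sv[:, None] * V.T)

    if residual_norm_at_opt > 0:
        b = rng.standard_normal(n_res)
        b -= U @ (U.T @ b)
        nb = np.linalg.norm(b)
        while nb < 1e-8:  # pragma: no cover - essentially impossible
            b = rng.standard_normal(n_res)
            b -= U @ (U.T @ b)
            nb = np.linalg.norm(b)
        r0 = b * (residual_norm_at_opt / nb)
    else:
        r0 = np.zeros(n_res)

    ones = np.ones(n_res)
    zeros = np.zeros((n_res, n_par))

    def objective(theta: np.ndarray) -> Evaluation:
        u = np.asarray(theta, dtype=float) - theta_true
        if warp == "sinh":
            w, dw = np.sinh(u), np.cosh(u)
        else:
            w, dw = u, np.ones_like(u)
        r = M @ w + r0
        jac = M * dw[None, :]
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(jac)):
            return Evaluation(f=np.nan, ok=False)
        return Evaluation(
            f=0.5 * float(r @ r),
            g=jac.T @ r,
            r=r,
            jac=jac,
            sigma=ones,
            dsigma=zeros,
        )

    return SyntheticNLSProblem(
        objective=objective,
        theta_true=theta_true,
        domain=domain,
        residual_norm_at_opt=residual_norm_at_opt,
        spectrum_decades=spectrum_decades,
        seed=seed,
        n_par=n_par,
        n_res=n_res,
        _M=M,
        _r0=r0,
    )


@dataclass
class ConversionModelFixture:
    """Two-species conversion model with simulated Gaussian data.

    Species interconvert as ``x1 <-> x2`` with mass-action rates ``k1``
    (forward) and ``k2`` (backward); the total ``T = x1 + x2`` is conserved
    and the observable is ``y = x2``:

        x2(t) = x2_eq + (x2(0) - x2_eq) exp(-(k1+k2) t),
        x2_eq = k1 T / (k1 + k2).

    With ``estimate_sigma`` the noise scale becomes a third estimated
    parameter, making the noise parameter-dependent.
    """

    objective: Objective
    theta_true: np.ndarray
    domain: SearchDomain
    times: np.ndarray
    data: np.ndarray
    x0: np.ndarray
    sigma_true: float
    estimate_sigma: bool
    seed: int

    def trajectory(self, theta: np.ndarray, times=None) -> np.ndarray:
        times = self.times if times is None else np.asarray(times, dtype=float)
        y, _ = _conversion_observable(theta[:2], self.x0, times)
        return y

    def ode_residual(self, theta: np.ndarray, t: float, h: float = 1e-6) -> float:
        """|dx2/dt - (k1 x1 - k2 x2)| at time t (closed-form consistency)."""
        k1, k2 = float(theta[0]), float(theta[1])
        y = lambda tt: _conversion_observable(
            np.array([k1, k2]), self.x0, np.array([tt])
        )[0][0]
        dydt = (y(t + h) - y(t - h)) / (2.0 * h)
        x2 = y(t)
        x1 = float(self.x0.sum()) - x2
        return abs(dydt - (k1 * x1 - k2 * x2))

    def save(self, directory: Union[str, Path]) -> None:
        """Serialize to a plain-text parameter file plus a CSV data table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        params = {
            "k1": float(self.theta_true[0]),
            "k2": float(self.theta_true[1]),
            "x0": [float(v) for v in self.x0],
            "sigma": float(self.sigma_true),
            "estimate_sigma": bool(self.estimate_sigma),
            "seed": int(self.seed),
            "lb": [float(v) for v in self.domain.lb],
            "ub": [float(v) for v in self.domain.ub],
        }
        with open(directory / "fixture.yaml", "w") as fh:
            yaml.safe_dump(params, fh)
        pd.DataFrame(
            {
                "time": self.times,
                "measurement": self.data,
                "sigma": np.full(self.times.size, self.sigma_true),
            }
        ).to_csv(directory / "data.csv", index=False)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "ConversionModelFixture":
        directory = Path(directory)
        with open(directory / "fixture.yaml") as fh:
            params = yaml.safe_load(fh)
        table = pd.read_csv(directory / "data.csv")
        fixture = conversion_model(
            rates=(params["k1"], params["k2"]),
            x0=params["x0"],
            times=table["time"].to_numpy(),
            sigma=params["sigma"],
            estimate_sigma=params["estimate_sigma"],
            seed=params["seed"],
            domain=SearchDomain(params["lb"], params["ub"]),
        )
        # use the stored data verbatim (robust to generator changes)
        return _rebuild_conversion(fixture, table["measurement"].to_numpy())


def _conversion_observable(
    rates: np.ndarray, x0: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form observable ``y = x2`` and its Jacobian wrt ``(k1, k2)``."""
    k1, k2 = float(rates[0]), float(rates[1])
    T = float(np.sum(x0))
    s = k1 + k2
    x2_eq = k1 * T / s
    amp = float(x0[1]) - x2_eq
    e = np.exp(-s * times)
    y = x2_eq + amp * e
    deq_dk1 = T * k2 / s**2
    deq_dk2 = -T * k1 / s**2
    dy_dk1 = deq_dk1 * (1.0 - e) + amp * (-times) * e
    dy_dk2 = deq_dk2 * (1.0 - e) + amp * (-times) * e
    return y, np.stack([dy_dk1, dy_dk2], axis=1)


def conversion_model(
    rates: Sequence[float] = (2.0, 1.0),
    x0: Sequence[float] = (1.0, 0.0),
    times: Optional[Sequence[float]] = None,
    sigma: float = 0.02,
    estimate_sigma: bool = False,
    seed: int = 0,
    domain: Optional[SearchDomain] = None,
) -> ConversionModelFixture:
    """Build the conversion-model fixture with simulated data.

    Defaults emulate a well-resolved small-scale calibration: rates
    ``k1 = 2``, ``k2 = 1`` (relaxation time 1/3), all mass initially in the
    first species, ten observation times covering the transient and the
    plateau, and a noise scale of 2% of the total abundance.
    """
    k1, k2 = float(rates[0]), float(rates[1])
    if k1 <= 0 or k2 <= 0:
        raise ValueError("conversion rates must be strictly positive")
    x0 = np.asarray(x0, dtype=float)
    if times is None:
        times = np.linspace(0.0, 3.0, 10)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("observation times must be non-negative")
    if sigma <= 0:
        raise ValueError("noise scale must be strictly positive")

    rng = _rng(seed)
    y_true, _ = _conversion_observable(np.array([k1, k2]), x0, times)
    data = y_true + sigma * rng.standard_normal(times.size)

    if domain is None:
        if estimate_sigma:
            domain = SearchDomain(
                [1e-3, 1e-3, 1e-4], [1e2, 1e2, 1.0]
            )
        else:
            domain = SearchDomain([1e-3, 1e-3], [1e2, 1e2])

    local_times = times.copy()

    if estimate_sigma:

        def model(theta):
            y, dy = _conversion_observable(theta[:2], x0, local_times)
            return y, np.column_stack([dy, np.zeros(local_times.size)])

        def sigma_fun(theta):
            sig = np.full(local_times.size, float(theta[2]))
            dsig = np.zeros((local_times.size, 3))
            dsig[:, 2] = 1.0
            return sig, dsig

        objective = residual_objective(data, model, sigma_fun=sigma_fun)
        theta_true = np.array([k1, k2, sigma])
    else:

        def model(theta):
            return _conversion_observable(theta[:2], x0, local_times)

        objective = residual_objective(data, model, sigma=sigma)
        theta_true = np.array([k1, k2])

    return ConversionModelFixture(
        objective=objective,
        theta_true=theta_true,
        domain=domain,
        times=times,
        data=data,
        x0=x0,
        sigma_true=sigma,
        estimate_sigma=estimate_sigma,
        seed=seed,
    )


def _rebuild_conversion(
    fixture: ConversionModelFixture, data: np.ndarray
) -> ConversionModelFixture:
    """Re-assemble a fixture around stored (rather than re-drawn) data."""
    x0 = fixture.x0
    local_times = fixture.times.copy()
    if fixture.estimate_sigma:

        def model(theta):
            y, dy = _conversion_observable(theta[:2], x0, local_times)
            return y, np.column_stack([dy, np.zeros(local_times.size)])

        def sigma_fun(theta):
            sig = np.full(local_times.size, float(theta[2]))
            dsig = np.zeros((local_times.size, 3))
            dsig[:, 2] = 1.0
            return sig, dsig

        objective = residual_objective(data, model, sigma_fun=sigma_fun)
    else:

        def model(theta):
            return _conversion_observable(theta[:2], x0, local_times)

        objective = residual_objective(data, model, sigma=fixture.sigma_true)
    fixture.objective = objective
    fixture.data = np.asarray(data, dtype=float)
    return fixture


def rosenbrock_problem(
    bound: float = 2.0,
) -> tuple[Objective, SearchDomain, np.ndarray]:
    """Rosenbrock valley in least-squares form on the box [-bound, bound]^2.

    ``r = (10 (theta2 - theta1^2), 1 - theta1)``, ``f = 1/2 |r|^2``; the
    unique minimum ``f = 0`` sits at ``(1, 1)``.  Returns
    ``(objective, domain, theta_min)``.
    """
    ones = np.ones(2)
    zeros = np.zeros((2, 2))

    def objective(theta: np.ndarray) -> Evaluation:
        t1, t2 = float(theta[0]), float(theta[1])
        r = np.array([10.0 * (t2 - t1**2), 1.0 - t1])
        jac = np.array([[-20.0 * t1, 10.0], [-1.0, 0.0]])
        return Evaluation(
            f=0.5 * float(r @ r),
            g=jac.T @ r,
            r=r,
            jac=jac,
            sigma=ones,
            dsigma=zeros,
        )

    domain = SearchDomain([-bound, -bound], [bound, bound])
    return objective, domain, np.array([1.0, 1.0])


def sample_startpoints(
    domain: SearchDomain, n_starts: int, seed: int = 0
) -> np.ndarray:
    """Uniform start points, strictly interior, reproducible by seed."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not (np.all(np.isfinite(domain.lb)) and np.all(np.isfinite(domain.ub))):
        raise ValueError(
            "uniform start-point sampling requires finite bounds; supply an "
            "explicit sampling box for unbounded coordinates"
        )
    rng = _rng(seed)
    pts = rng.uniform(domain.lb, domain.ub, size=(n_starts, domain.n_par))
    return np.vstack([domain.clip_interior(p) for p in pts])
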