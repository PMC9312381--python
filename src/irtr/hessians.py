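"""Hessian approximation schemes for trust-region maximum-likelihood fits.

Pointwise schemes (GN, GNe) are rebuilt from the residual Jacobian at every
iterate; iterative schemes (BFGS, SR1) recur over accepted steps; structured
schemes (SSM, TSSM, FX, GNSBFGS) combine a pointwise GNe core with an
iteratively updated correction that models the residual-curvature term of the
true Hessian, which the plain Gauss-Newton product drops.  The hybrid
switching scheme starts from GN while silently maintaining a BFGS shadow
matrix and switches to the shadow permanently once the trust-region radius
has not changed for ``n_hybrid`` consecutive iterations — the signature that
the Gauss-Newton model quality has become limiting.

Scaling convention: for standardized residuals ``r`` with Jacobian ``Jr`` the
Gauss-Newton product is ``B = Jr^T Jr``, which is the exact Hessian of the
residual part of the objective for affine residuals.

Update vectors are formed over accepted iterates only: ``s`` is the accepted
step and ``z`` the gradient difference across it.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .objective import Evaluation

__all__ = [
    "gauss_newton",
    "gauss_newton_e",
    "bfgs_update",
    "sr1_update",
    "HessianScheme",
    "GN",
    "GNE",
    "BFGS",
    "SR1",
    "SSM",
    "TSSM",
    "FX",
    "GNSBFGS",
    "HybridSwitch",
    "ExactHessian",
    "make_scheme",
    "SCHEME_NAMES",
]

_EPS = float(np.finfo(float).eps)


def _symmetrize(B: np.ndarray) -> np.ndarray:
    return 0.5 * (B + B.T)


def gauss_newton(jac: np.ndarray) -> np.ndarray:
    """Gauss-Newton product ``sum_m grad(r_m) grad(r_m)^T = Jr^T Jr``.

    Symmetric positive semi-definite by construction; exact for affine
    residuals, ignores the residual-curvature term otherwise.
    """
    jac = np.asarray(jac, dtype=float)
    if not np.all(np.isfinite(jac)):
        raise ValueError("residual Jacobian contains non-finite entries")
    return _symmetrize(jac.T @ jac)


def gauss_newton_e(
    jac: np.ndarray,
    sigma: np.ndarray,
    dsigma: np.ndarray,
    C: float = 50.0,
) -> np.ndarray:
    """Gauss-Newton product with error-residual correction for sigma(theta).

    For parameter-dependent noise scales the log(sigma) likelihood term breaks
    the least-squares structure.  Introducing per-measurement error residuals
    ``sqrt(2 log sigma_m + C)`` restores it, at the price of an offset
    constant ``C`` chosen large enough that ``2 log sigma_m + C > 0``; the
    correction added to the plain GN product is

        sum_m dsigma_m dsigma_m^T / (sigma_m^2 (2 log sigma_m + C)).

    The correction vanishes for constant noise and as ``C -> inf``, where the
    scheme reduces to plain GN.
    """
    jac = np.asarray(jac, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    dsigma = np.asarray(dsigma, dtype=float)
    B = gauss_newton(jac)
    if dsigma.size == 0 or not np.any(dsigma):
        return B
    denom = sigma**2 * (2.0 * np.log(sigma) + C)
    bad = np.nonzero(2.0 * np.log(sigma) + C <= 0)[0]
    if bad.size:
        raise ValueError(
            f"error-residual condition 2*log(sigma)+C > 0 violated for "
            f"residual index {bad[0]} (sigma={sigma[bad[0]]:.3g}, C={C})"
        )
    scaled = dsigma / np.sqrt(denom)[:, None]
    return _symmetrize(B + scaled.T @ scaled)


def _bfgs_delta(
    M: np.ndarray, s: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, bool]:
    """BFGS increment ``z z^T/(z^T s) - (M s)(M s)^T/(s^T M s)``.

    Returns ``(delta, performed)``.  The update is rejected when the curvature
    condition ``z^T s > eps*|z||s|`` fails.  For positive semi-definite ``M``
    with ``M s = 0`` the second term vanishes in the limit and is dropped; a
    genuinely indefinite degenerate denominator (``s^T M s ~ 0`` with
    ``M s != 0``) skips the update with a warning.
    """
    zs = float(z @ s)
    ns, nz = float(np.linalg.norm(s)), float(np.linalg.norm(z))
    if ns == 0.0:
        raise ValueError("BFGS update requires a nonzero step")
    if zs <= _EPS * ns * nz:
        return np.zeros_like(M), False
    Ms = M @ s
    sMs = float(s @ Ms)
    delta = np.outer(z, z) / zs
    if abs(sMs) <= _EPS * ns * float(np.linalg.norm(Ms)) or sMs == 0.0:
        if np.linalg.norm(Ms) > 1e2 * _EPS * ns * max(
            1.0, float(np.linalg.norm(M))
        ):
            warnings.warn(
                "BFGS update skipped: degenerate denominator s^T M s ~ 0 "
                "with M s != 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return np.zeros_like(M), False
        # M s = 0: the (Ms)(Ms)^T / s^T M s term vanishes
        return _symmetrize(delta), True
    return _symmetrize(delta - np.outer(Ms, Ms) / sMs), True


def bfgs_update(
    M: np.ndarray, s: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Apply a curvature-guarded BFGS update; returns ``(M', performed)``."""
    M = np.asarray(M, dtype=float)
    s = np.asarray(s, dtype=float)
    z = np.asarray(z, dtype=float)
    delta, performed = _bfgs_delta(M, s, z)
    if not performed:
        return M.copy(), False
    return _symmetrize(M + delta), True


def sr1_update(
    M: np.ndarray, s: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Symmetric rank-one update; returns ``(M', performed)``.

    ``M' = M + (z - Ms)(z - Ms)^T / ((z - Ms)^T s)`` unless the denominator is
    numerically zero relative to ``|s| |z - Ms|``, in which case the update is
    skipped.  Can produce indefinite matrices, i.e. capture negative
    curvature.
    """
    M = np.asarray(M, dtype=float)
    s = np.asarray(s, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.linalg.norm(s) == 0.0:
        raise ValueError("SR1 update requires a nonzero step")
    w = z - M @ s
    denom = float(w @ s)
    if abs(denom) <= 1e-8 * float(np.linalg.norm(s)) * float(np.linalg.norm(w)):
        return M.copy(), False
    return _symmetrize(M + np.outer(w, w) / denom), True


class HessianScheme:
    """Base class: stateful Hessian approximation consumed by the loop.

    Lifecycle: ``initialize(n_par, ev0)`` once, then per iteration
    ``notify_radius(updated)`` (every iteration) and
    ``update(s, z, ev_new, ev_old)`` (accepted iterations only), with
    ``current()`` yielding the matrix used to build the next quadratic model.
    """

    name: str = "base"
    requires_residuals: bool = False

    def __init__(self) -> None:
        self._B: Optional[np.ndarray] = None
        self.last_update_performed: bool = True

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._B = np.eye(n_par)

    def current(self) -> np.ndarray:
        assert self._B is not None, "scheme not initialized"
        return self._B

    def update(
        self,
        s: np.ndarray,
        z: np.ndarray,
        ev_new: Evaluation,
        ev_old: Evaluation,
    ) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def notify_radius(self, updated: bool) -> None:
        pass


class GN(HessianScheme):
    """Pointwise Gauss-Newton approximation ``Jr^T Jr``."""

    name = "GN"
    requires_residuals = True

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._B = gauss_newton(ev0.jac)

    def update(self, s, z, ev_new, ev_old) -> None:
        self._B = gauss_newton(ev_new.jac)
        self.last_update_performed = True


class GNE(HessianScheme):
    """Gauss-Newton with error-residual correction (offset constant ``C``)."""

    name = "GNe"
    requires_residuals = True

    def __init__(self, C: float = 50.0) -> None:
        super().__init__()
        self.C = float(C)

    def _build(self, ev: Evaluation) -> np.ndarray:
        if ev.sigma is None or ev.dsigma is None:
            return gauss_newton(ev.jac)
        return gauss_newton_e(ev.jac, ev.sigma, ev.dsigma, C=self.C)

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._B = self._build(ev0)

    def update(self, s, z, ev_new, ev_old) -> None:
        self._B = self._build(ev_new)
        self.last_update_performed = True


class ExactHessian(HessianScheme):
    """Uses the Hessian supplied by the objective (``Evaluation.hess``)."""

    name = "EXACT"

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        if ev0.hess is None:
            raise ValueError("objective does not supply a Hessian")
        self._B = _symmetrize(np.asarray(ev0.hess, dtype=float))

    def update(self, s, z, ev_new, ev_old) -> None:
        self._B = _symmetrize(np.asarray(ev_new.hess, dtype=float))
        self.last_update_performed = True


class BFGS(HessianScheme):
    """Iterative rank-two update; PSD-preserving under the curvature guard."""

    name = "BFGS"

    def update(self, s, z, ev_new, ev_old) -> None:
        self._B, self.last_update_performed = bfgs_update(self._B, s, z)


class SR1(HessianScheme):
    """Iterative rank-one update; may become indefinite."""

    name = "SR1"

    def update(self, s, z, ev_new, ev_old) -> None:
        self._B, self.last_update_performed = sr1_update(self._B, s, z)


def _structural_z(ev_new: Evaluation, ev_old: Evaluation) -> np.ndarray:
    """Structured secant vector ``z# = (Jr_new - Jr_old)^T r_new``."""
    return (ev_new.jac - ev_old.jac).T @ ev_new.r


class SSM(HessianScheme):
    """Structured secant method: ``B = GNe + A`` with BFGS-updated ``A``.

    The correction ``A`` models the residual-curvature term; its inner BFGS
    update targets the secant vector ``z#`` and expands around the full
    ``GNe + A`` matrix, so positive semi-definiteness is not preserved.
    """

    name = "SSM"
    requires_residuals = True

    def __init__(self, C: float = 50.0) -> None:
        super().__init__()
        self._gne = GNE(C=C)
        self._A: Optional[np.ndarray] = None

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._gne.initialize(n_par, ev0)
        self._A = np.zeros((n_par, n_par))
        self._B = self._gne.current() + self._A

    def update(self, s, z, ev_new, ev_old) -> None:
        self._gne.update(s, z, ev_new, ev_old)
        gne = self._gne.current()
        z_sharp = _structural_z(ev_new, ev_old)
        delta, performed = _bfgs_delta(gne + self._A, s, z_sharp)
        if performed:
            self._A = _symmetrize(self._A + delta)
        self.last_update_performed = performed
        self._B = _symmetrize(gne + self._A)


class TSSM(HessianScheme):
    """Totally structured secant method: ``B = GNe + |r| A``.

    Scales the correction with the residual norm (mimicking the
    residual-times-curvature product structure of the true Hessian) and the
    update to ``A`` with its inverse.  Falls back to plain GNe when either
    residual norm vanishes.
    """

    name = "TSSM"
    requires_residuals = True

    def __init__(self, C: float = 50.0) -> None:
        super().__init__()
        self._gne = GNE(C=C)
        self._A: Optional[np.ndarray] = None

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._gne.initialize(n_par, ev0)
        self._A = np.zeros((n_par, n_par))
        self._B = self._gne.current().copy()

    def update(self, s, z, ev_new, ev_old) -> None:
        self._gne.update(s, z, ev_new, ev_old)
        gne = self._gne.current()
        r_new = float(np.linalg.norm(ev_new.r))
        r_old = float(np.linalg.norm(ev_old.r))
        if r_new == 0.0 or r_old == 0.0:
            self._B = gne.copy()
            self.last_update_performed = True
            return
        z_sharp = _structural_z(ev_new, ev_old)
        z_dag = gne @ s + z_sharp * (r_new / r_old)
        delta, performed = _bfgs_delta(gne + r_new * self._A, s, z_dag)
        if performed:
            self._A = _symmetrize(self._A + delta / r_new)
        self.last_update_performed = performed
        self._B = _symmetrize(gne + r_new * self._A)


class FX(HessianScheme):
    """Fletcher-Xu hybrid: BFGS when residual norms stagnate, GNe otherwise.

    The branch test is the normalized residual-norm decrease
    ``(|r_old| - |r_new|)/|r_old| < eps_fx``; small decreases indicate a
    non-zero-residual regime where the carried matrix is BFGS-updated, large
    decreases re-anchor at a fresh GNe.  Both branches preserve positive
    semi-definiteness.
    """

    name = "FX"
    requires_residuals = True

    def __init__(self, eps_fx: float = 0.2, C: float = 50.0) -> None:
        super().__init__()
        self.eps_fx = float(eps_fx)
        self._gne = GNE(C=C)

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._gne.initialize(n_par, ev0)
        self._B = self._gne.current().copy()

    def update(self, s, z, ev_new, ev_old) -> None:
        self._gne.update(s, z, ev_new, ev_old)
        r_new = float(np.linalg.norm(ev_new.r))
        r_old = float(np.linalg.norm(ev_old.r))
        if r_old > 0.0 and (r_old - r_new) / r_old < self.eps_fx:
            self._B, self.last_update_performed = bfgs_update(self._B, s, z)
        else:
            self._B = self._gne.current().copy()
            self.last_update_performed = True


class GNSBFGS(HessianScheme):
    """Gauss-Newton structured BFGS: PSD-safe structured correction.

    The scaled secant vector ``z<> = z# * |r_new|/|r_old|`` drives both the
    switch test ``z<>^T s / s^T s > eps`` and the inner BFGS update of the
    correction ``A`` (updated around ``A`` itself, keeping it PSD).  When the
    test fails the correction is replaced by the regularizer ``|r_new| I``.
    """

    name = "GNSBFGS"
    requires_residuals = True

    def __init__(self, eps_gnsbfgs: float = 1e-6, C: float = 50.0) -> None:
        super().__init__()
        self.eps = float(eps_gnsbfgs)
        self._gne = GNE(C=C)
        self._A: Optional[np.ndarray] = None

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._gne.initialize(n_par, ev0)
        self._A = np.zeros((n_par, n_par))
        r0 = float(np.linalg.norm(ev0.r))
        self._B = _symmetrize(self._gne.current() + r0 * np.eye(n_par))

    def update(self, s, z, ev_new, ev_old) -> None:
        self._gne.update(s, z, ev_new, ev_old)
        gne = self._gne.current()
        n_par = gne.shape[0]
        r_new = float(np.linalg.norm(ev_new.r))
        r_old = float(np.linalg.norm(ev_old.r))
        if r_old == 0.0:
            self._B = gne.copy()
            self.last_update_performed = True
            return
        z_diamond = _structural_z(ev_new, ev_old) * (r_new / r_old)
        ss = float(s @ s)
        if ss > 0 and float(z_diamond @ s) / ss > self.eps:
            delta, performed = _bfgs_delta(self._A, s, z_diamond)
            if performed:
                self._A = _symmetrize(self._A + delta)
            self.last_update_performed = performed
            self._B = _symmetrize(gne + self._A)
        else:
            self.last_update_performed = True
            self._B = _symmetrize(gne + r_new * np.eye(n_par))


class HybridSwitch(HessianScheme):
    """GN early, BFGS late: switch after ``n_hybrid`` consecutive stalls.

    Maintains a pointwise GN(e) matrix and a silently BFGS-updated shadow
    matrix in parallel.  A stall counter increments on every iteration in
    which the trust-region radius was left unchanged and resets on any radius
    change; once it reaches ``n_hybrid``, the scheme permanently returns the
    shadow BFGS matrix.  Before the switch the returned matrix is exactly the
    GN(e) matrix.
    """

    name = "HYBRID"
    requires_residuals = True

    def __init__(self, n_hybrid: int = 50, C: float = 50.0) -> None:
        super().__init__()
        if n_hybrid < 1:
            raise ValueError("n_hybrid must be >= 1")
        self.n_hybrid = int(n_hybrid)
        self._gn = GNE(C=C)
        self._shadow = BFGS()
        self.stall_counter = 0
        self.switched = False

    def initialize(self, n_par: int, ev0: Evaluation) -> None:
        self._gn.initialize(n_par, ev0)
        self._shadow.initialize(n_par, ev0)
        self.stall_counter = 0
        self.switched = False

    def notify_radius(self, updated: bool) -> None:
        if self.switched:
            return
        if updated:
            self.stall_counter = 0
        else:
            self.stall_counter += 1
            if self.stall_counter >= self.n_hybrid:
                self.switched = True

    def update(self, s, z, ev_new, ev_old) -> None:
        self._shadow.update(s, z, ev_new, ev_old)
        self._gn.update(s, z, ev_new, ev_old)
        self.last_update_performed = (
            self._shadow.last_update_performed
            if self.switched
            else self._gn.last_update_performed
        )

    def current(self) -> np.ndarray:
        return self._shadow.current() if self.switched else self._gn.current()


SCHEME_NAMES = (
    "GN",
    "GNe",
    "BFGS",
    "SR1",
    "SSM",
    "TSSM",
    "FX",
    "GNSBFGS",
    "HYBRID",
    "EXACT",
)


def make_scheme(name: str, **kwargs) -> HessianScheme:
    """Construct a scheme by name (case-insensitive).

    Keyword options: ``C`` (GNe offset, default 50), ``eps_fx`` (FX branch
    tolerance, default 0.2), ``eps_gnsbfgs`` (GNSBFGS switch tolerance,
    default 1e-6), ``n_hybrid`` (hybrid stall budget, default 50).
    """
    key = name.strip().upper()
    table = {
        "GN": lambda: GN(),
        "GNE": lambda: GNE(C=kwargs.get("C", 50.0)),
        "BFGS": lambda: BFGS(),
        "SR1": lambda: SR1(),
        "SSM": lambda: SSM(C=kwargs.get("C", 50.0)),
        "TSSM": lambda: TSSM(C=kwargs.get("C", 50.0)),
        "FX": lambda: FX(
            eps_fx=kwargs.get("eps_fx", 0.2), C=kwargs.get("C", 50.0)
        ),
        "GNSBFGS": lambda: GNSBFGS(
            eps_gnsbfgs=kwargs.get("eps_gnsbfgs", 1e-6),
            C=kwargs.get("C", 50.0),
        ),
        "HYBRID": lambda: HybridSwitch(
            n_hybrid=kwargs.get("n_hybrid", 50), C=kwargs.get("C", 50.0)
        ),
        "EXACT": lambda: ExactHessian(),
    }
    if key not in table:
        raise ValueError(
            f"unknown Hessian scheme {name!r}; choose from {SCHEME_NAMES}"
        )
    return table[key]()
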