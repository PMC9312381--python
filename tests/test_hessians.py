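"""Hessian approximation schemes: update formulas, guards, structure."""

import numpy as np
import pytest

from irtr.hessians import (
    BFGS,
    FX,
    GNE,
    GNSBFGS,
    SR1,
    SSM,
    TSSM,
    HybridSwitch,
    bfgs_update,
    gauss_newton,
    gauss_newton_e,
    make_scheme,
    sr1_update,
)
from irtr.objective import Evaluation

e1 = np.array([1.0, 0.0])
e2 = np.array([0.0, 1.0])


def make_ls_eval(rng, n_par=3, n_res=6, sigma_dep=False):
    """Random least-squares evaluation state."""
    jac = rng.standard_normal((n_res, n_par))
    r = rng.standard_normal(n_res)
    sigma = rng.uniform(0.5, 2.0, n_res)
    dsigma = rng.standard_normal((n_res, n_par)) if sigma_dep else np.zeros((n_res, n_par))
    return Evaluation(
        f=0.5 * float(r @ r), g=jac.T @ r, r=r, jac=jac, sigma=sigma, dsigma=dsigma
    )


class TestGaussNewton:
    def test_identity_jacobian(self):
        assert np.array_equal(gauss_newton(np.eye(3)), np.eye(3))

    def test_rank_one_outer_product(self):
        B = gauss_newton(np.array([[1.0, 2.0]]))
        assert np.allclose(B, [[1.0, 2.0], [2.0, 4.0]])

    def test_affine_residuals_give_exact_hessian(self, rng):
        """For r = A theta - b the GN product equals the finite-difference
        Hessian of 1/2 |r|^2."""
        A = rng.standard_normal((7, 3))
        b = rng.standard_normal(7)
        theta = rng.standard_normal(3)

        def f(th):
            r = A @ th - b
            return 0.5 * float(r @ r)

        h = 1e-5
        H_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
                H_fd[i, j] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h * h)
        assert np.allclose(gauss_newton(A), H_fd, atol=1e-5)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            gauss_newton(np.array([[np.nan, 1.0]]))


class TestGaussNewtonE:
    def test_constant_sigma_reduces_to_gn(self, rng):
        jac = rng.standard_normal((5, 2))
        sigma = rng.uniform(0.5, 2.0, 5)
        B = gauss_newton_e(jac, sigma, np.zeros((5, 2)), C=50.0)
        assert np.allclose(B, gauss_newton(jac))

    def test_large_offset_limit_is_gn(self, rng):
        """As the offset constant grows the correction vanishes."""
        jac = rng.standard_normal((5, 2))
        sigma = rng.uniform(0.5, 2.0, 5)
        dsigma = rng.standard_normal((5, 2))
        gn = gauss_newton(jac)
        gap_small = np.abs(gauss_newton_e(jac, sigma, dsigma, C=50.0) - gn).max()
        gap_large = np.abs(gauss_newton_e(jac, sigma, dsigma, C=1e6) - gn).max()
        assert gap_small > 0
        assert gap_large < 1e-4 * gap_small

    def test_hand_computed_correction(self):
        """Single parameter, sigma(theta) = theta at theta = 1, C = 50, no
        measurement term: correction = 1 / (1 * (0 + 50)) = 0.02."""
        B = gauss_newton_e(
            np.zeros((1, 1)), np.array([1.0]), np.array([[1.0]]), C=50.0
        )
        assert B[0, 0] == pytest.approx(0.02, rel=1e-14)

    def test_realness_condition_violation_names_residual(self):
        with pytest.raises(ValueError, match="index 1"):
            gauss_newton_e(
                np.zeros((2, 1)),
                np.array([1.0, 1e-20]),
                np.array([[1.0], [1.0]]),
                C=50.0,
            )


class TestBfgsUpdate:
    def test_fixed_point(self):
        M, performed = bfgs_update(np.eye(2), e1, e1)
        assert performed and np.allclose(M, np.eye(2))

    def test_secant_by_substitution(self):
        M, performed = bfgs_update(np.eye(2), e1, 2 * e1)
        assert performed
        assert np.allclose(M, np.diag([2.0, 1.0]))
        assert np.allclose(M @ e1, 2 * e1)

    def test_curvature_rejection(self):
        M0 = np.eye(2) + 0.1
        M, performed = bfgs_update(M0, e1, -e1)  # z^T s = -1
        assert not performed
        assert np.array_equal(M, M0)

    def test_degenerate_denominator_indefinite_warns(self):
        # s^T M s = 0 with M s != 0: skip with warning
        M0 = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            M, performed = bfgs_update(M0, e1, e1)
        assert not performed and np.array_equal(M, M0)

    def test_psd_degenerate_denominator_proceeds(self):
        # PSD M with M s = 0: vanishing term dropped, rank-1 growth possible
        M, performed = bfgs_update(np.zeros((2, 2)), e1, 2 * e1)
        assert performed
        assert np.allclose(M, np.diag([2.0, 0.0]))

    def test_secant_condition_randomized(self, rng):
        """B' s = z to machine precision after every performed update."""
        for _ in range(500):
            n = int(rng.integers(2, 6))
            A = rng.standard_normal((n, n))
            M = A @ A.T
            s = rng.standard_normal(n)
            z = rng.standard_normal(n)
            Mp, performed = bfgs_update(M, s, z)
            zs = float(z @ s)
            if performed:
                assert np.allclose(Mp @ s, z, atol=1e-8 * max(1, np.linalg.norm(z)))
            else:
                assert zs <= np.finfo(float).eps * np.linalg.norm(z) * np.linalg.norm(s)
                assert np.array_equal(Mp, M)


class TestSr1Update:
    def test_skip_when_secant_already_holds(self):
        M, performed = sr1_update(np.diag([2.0, 3.0]), e1, 2 * e1)
        assert not performed

    def test_rank_one_growth(self):
        M, performed = sr1_update(np.zeros((2, 2)), e1, e1)
        assert performed
        assert np.allclose(M, np.outer(e1, e1))
        assert np.allclose(M @ e1, e1)

    def test_indefinite_result(self):
        """SR1 can leave the PSD cone: M = I, s = e1, z = -e1."""
        M, performed = sr1_update(np.eye(2), e1, -e1)
        assert performed
        assert np.allclose(M, np.diag([-1.0, 1.0]))
        assert np.linalg.eigvalsh(M)[0] < 0

    def test_secant_condition_randomized(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 6))
            A = rng.standard_normal((n, n))
            M = 0.5 * (A + A.T)
            s = rng.standard_normal(n)
            z = rng.standard_normal(n)
            Mp, performed = sr1_update(M, s, z)
            if performed:
                assert np.allclose(Mp @ s, z, atol=1e-7 * max(1, np.linalg.norm(z)))


def scripted_ssm(evals, steps, C=50.0):
    """Standalone transcription of the SSM recursion (test oracle)."""
    n = evals[0].jac.shape[1]
    A = np.zeros((n, n))
    out = []
    for k, s in enumerate(steps):
        ev_old, ev_new = evals[k], evals[k + 1]
        gne = gauss_newton_e(ev_new.jac, ev_new.sigma, ev_new.dsigma, C)
        z_sharp = (ev_new.jac - ev_old.jac).T @ ev_new.r
        M = gne + A
        zs = float(z_sharp @ s)
        if zs > np.finfo(float).eps * np.linalg.norm(z_sharp) * np.linalg.norm(s):
            Ms = M @ s
            sMs = float(s @ Ms)
            if sMs != 0:
                A = A + np.outer(z_sharp, z_sharp) / zs - np.outer(Ms, Ms) / sMs
                A = 0.5 * (A + A.T)
        out.append(0.5 * ((gne + A) + (gne + A).T))
    return out


class TestStructuredSchemes:
    def test_ssm_zero_structure_reduces_to_gne(self, rng):
        """Identical Jacobians (or zero residuals) give z# = 0, so the
        correction stays zero and the output equals GNe."""
        ev = make_ls_eval(rng)
        scheme = SSM()
        scheme.initialize(3, ev)
        ev2 = Evaluation(f=ev.f, g=ev.g, r=ev.r, jac=ev.jac.copy(),
                         sigma=ev.sigma, dsigma=ev.dsigma)
        scheme.update(np.array([0.1, 0.0, 0.0]), ev2.g - ev.g, ev2, ev)
        assert np.allclose(scheme.current(), gauss_newton(ev.jac))

    def test_ssm_matches_scripted_recursion(self, rng):
        evals = [make_ls_eval(rng) for _ in range(4)]
        steps = [rng.standard_normal(3) for _ in range(3)]
        scheme = SSM()
        scheme.initialize(3, evals[0])
        expect = scripted_ssm(evals, steps)
        for k, s in enumerate(steps):
            scheme.update(s, evals[k + 1].g - evals[k].g, evals[k + 1], evals[k])
            assert np.allclose(scheme.current(), expect[k], atol=1e-10)

    def test_tssm_zero_residual_outputs_gne(self, rng):
        ev = make_ls_eval(rng)
        scheme = TSSM()
        scheme.initialize(3, ev)
        ev_zero = Evaluation(
            f=0.0, g=np.zeros(3), r=np.zeros(6),
            jac=rng.standard_normal((6, 3)),
            sigma=ev.sigma, dsigma=ev.dsigma,
        )
        scheme.update(rng.standard_normal(3), ev_zero.g - ev.g, ev_zero, ev)
        assert np.allclose(scheme.current(), gauss_newton(ev_zero.jac))

    def test_tssm_first_update_structure(self, rng):
        """With A = 0 initially the first output is GNe + |r| * (delta / |r|),
        i.e. GNe plus the performed inner-update increment."""
        evals = [make_ls_eval(rng), make_ls_eval(rng)]
        s = rng.standard_normal(3)
        scheme = TSSM()
        scheme.initialize(3, evals[0])
        scheme.update(s, evals[1].g - evals[0].g, evals[1], evals[0])
        ev = evals[1]
        gne = gauss_newton_e(ev.jac, ev.sigma, ev.dsigma, 50.0)
        r_new = np.linalg.norm(ev.r)
        r_old = np.linalg.norm(evals[0].r)
        z_dag = gne @ s + ((ev.jac - evals[0].jac).T @ ev.r) * (r_new / r_old)
        zs = float(z_dag @ s)
        M = gne  # inner expansion GNe + |r_new| * A with A = 0
        if zs > 0:
            delta = np.outer(z_dag, z_dag) / zs - np.outer(M @ s, M @ s) / float(
                s @ (M @ s)
            )
            expected = gne + r_new * (delta / r_new)
            expected = 0.5 * (expected + expected.T)
            assert np.allclose(scheme.current(), expected, atol=1e-10)

    def test_fx_branch_logic(self, rng):
        ev0 = make_ls_eval(rng)
        scheme = FX(eps_fx=0.2)
        scheme.initialize(3, ev0)
        s = rng.standard_normal(3)

        # large relative decrease (0.5 >= 0.2): fresh GNe
        ev_drop = make_ls_eval(rng)
        ev_drop.r = ev_drop.r / np.linalg.norm(ev_drop.r) * (
            0.5 * np.linalg.norm(ev0.r)
        )
        scheme.update(s, ev_drop.g - ev0.g, ev_drop, ev0)
        assert np.allclose(scheme.current(), gauss_newton(ev_drop.jac))

        # stagnating norm (decrease 0.05 < 0.2): BFGS branch on carried matrix
        carried = scheme.current().copy()
        ev_flat = make_ls_eval(rng)
        ev_flat.r = ev_flat.r / np.linalg.norm(ev_flat.r) * (
            0.95 * np.linalg.norm(ev_drop.r)
        )
        z = ev_flat.g - ev_drop.g
        expected, _ = bfgs_update(carried, s, z)
        scheme.update(s, z, ev_flat, ev_drop)
        assert np.allclose(scheme.current(), expected)

    def test_gnsbfgs_fallback_branch(self, rng):
        """Orthogonal scaled secant (z<>^T s = 0) takes the |r| I branch."""
        ev0 = make_ls_eval(rng)
        scheme = GNSBFGS()
        scheme.initialize(3, ev0)
        ev1 = make_ls_eval(rng)
        ev1.jac = ev0.jac.copy()  # z# = 0 -> z<> = 0 -> test fails -> fallback
        s = rng.standard_normal(3)
        scheme.update(s, ev1.g - ev0.g, ev1, ev0)
        expected = gauss_newton(ev1.jac) + np.linalg.norm(ev1.r) * np.eye(3)
        assert np.allclose(scheme.current(), expected)

    def test_gnsbfgs_zero_residual_reduces_to_gne(self, rng):
        ev0 = make_ls_eval(rng)
        scheme = GNSBFGS()
        scheme.initialize(3, ev0)
        ev1 = make_ls_eval(rng)
        ev1.r = np.zeros(6)
        s = rng.standard_normal(3)
        scheme.update(s, ev1.g - ev0.g, ev1, ev0)
        assert np.allclose(scheme.current(), gauss_newton(ev1.jac))


class TestPsdPreservation:
    @pytest.mark.parametrize("name", ["GN", "GNe", "BFGS", "FX", "GNSBFGS"])
    def test_min_eigenvalue_bound(self, name, rng):
        """PSD schemes never develop negative eigenvalues beyond noise."""
        for _ in range(200):
            ev0 = make_ls_eval(rng, sigma_dep=True)
            scheme = make_scheme(name)
            scheme.initialize(3, ev0)
            ev1 = make_ls_eval(rng, sigma_dep=True)
            s = rng.standard_normal(3)
            scheme.update(s, ev1.g - ev0.g, ev1, ev0)
            lam = np.linalg.eigvalsh(scheme.current())
            assert lam[0] >= -1e-10 * abs(lam[-1])


class TestHybridSwitch:
    def ev(self, rng):
        return make_ls_eval(rng)

    def test_no_stall_no_switch(self, rng):
        scheme = HybridSwitch(n_hybrid=3)
        scheme.initialize(3, self.ev(rng))
        for _ in range(10):
            scheme.notify_radius(True)
        assert not scheme.switched and scheme.stall_counter == 0

    def test_switch_after_consecutive_stalls(self, rng):
        ev0 = self.ev(rng)
        scheme = HybridSwitch(n_hybrid=3)
        scheme.initialize(3, ev0)
        gn_before = []
        for updated in (False, False, False):
            gn_before.append(scheme.current().copy())
            scheme.notify_radius(updated)
        assert scheme.switched
        # pre-switch outputs are bitwise the GN matrix
        gn_ref = gauss_newton(ev0.jac)
        for B in gn_before:
            assert np.array_equal(B, gn_ref)
        # post-switch output is the shadow BFGS matrix and never reverts
        ev1 = self.ev(rng)
        s = rng.standard_normal(3)
        z = ev1.g - ev0.g
        shadow_expect, _ = bfgs_update(np.eye(3), s, z)
        scheme.update(s, z, ev1, ev0)
        assert np.array_equal(scheme.current(), shadow_expect)
        scheme.notify_radius(True)
        assert scheme.switched  # permanent

    def test_counter_resets_on_radius_change(self, rng):
        """Sequence (F,F,T,F,F,F) with n_hybrid=3 switches at step 6."""
        scheme = HybridSwitch(n_hybrid=3)
        scheme.initialize(3, self.ev(rng))
        switched_at = None
        for k, updated in enumerate([False, False, True, False, False, False], 1):
            scheme.notify_radius(updated)
            if scheme.switched and switched_at is None:
                switched_at = k
        assert switched_at == 6
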