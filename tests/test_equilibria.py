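"""Equilibrium location, Jacobians, fractional stability, Hopf thresholds."""

import math

import numpy as np
import pytest

from fracml import (
    OrderSpec,
    classify_equilibrium,
    commensurate_stability_test,
    critical_order_3d,
    cubic_coefficients_3d,
    find_equilibria_2d,
    find_equilibrium_3d,
    gating_functions,
    hopf_threshold_2d,
    incommensurate_stability_test,
    ionic_current,
    jacobian_2d,
    jacobian_3d,
    rhs_2d,
    rhs_3d,
    solve_commensurate,
    solve_incommensurate,
    steady_state_current,
)
from fracml.equilibria import steady_state_critical_points

# fold currents of the class-I set (local max/min of the steady-state
# current), used to choose representative applied currents per regime
CLASS1_IM_MAX = 39.963
CLASS1_IM_MIN = -9.949


def finite_difference_jacobian(fun, x, eps=1e-6):
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        d = np.zeros(n)
        d[j] = eps
        J[:, j] = (np.asarray(fun(x + d)) - np.asarray(fun(x - d))) / (2 * eps)
    return J


class TestSteadyStateCurrent:
    def test_equals_ionic_current_on_gating_nullcline(self, params2d_class1):
        p = params2d_class1
        for u1 in (-60.0, -20.0, 5.0):
            w = gating_functions(u1, p).w_inf
            assert steady_state_current(u1, p) == pytest.approx(
                float(ionic_current(u1, w, p))
            )

    def test_leak_dominated_limits(self, params2d_class1):
        assert steady_state_current(-500.0, params2d_class1) < 0
        assert steady_state_current(500.0, params2d_class1) > 0

    def test_class1_has_exactly_two_critical_points(self, params2d_class1):
        folds = steady_state_critical_points(params2d_class1)
        assert folds is not None
        u1max, u1min = folds
        assert u1max < u1min
        # dense-grid oracle: derivative changes sign exactly twice
        us = np.linspace(-120, 160, 200001)
        vals = steady_state_current(us, params2d_class1)
        signs = np.sign(np.diff(vals))
        changes = np.sum(signs[:-1] != signs[1:])
        assert changes == 2

    def test_class2_is_monotone(self, params2d_class2):
        assert steady_state_critical_points(params2d_class2) is None


class TestEquilibria2D:
    def test_single_state_below_fold_window(self, params2d_class1):
        reps = find_equilibria_2d(params2d_class1, CLASS1_IM_MIN - 10)
        assert len(reps) == 1 and reps[0].branch == 1

    def test_single_state_above_fold_window(self, params2d_class1):
        reps = find_equilibria_2d(params2d_class1, CLASS1_IM_MAX + 5)
        assert len(reps) == 1 and reps[0].branch == 3

    def test_three_states_inside_fold_window(self, params2d_class1):
        reps = find_equilibria_2d(params2d_class1, 20.0)
        assert [r.branch for r in reps] == [1, 2, 3]

    @pytest.mark.parametrize("Im", [-20.0, 0.0, 20.0, 35.0, 43.0])
    def test_matches_brute_force_grid_scan(self, params2d_class1, Im):
        reps = find_equilibria_2d(params2d_class1, Im)
        us = np.linspace(-120, 160, 1_000_001)
        f = steady_state_current(us, params2d_class1) - Im
        idx = np.where(np.sign(f[:-1]) != np.sign(f[1:]))[0]
        assert len(idx) == len(reps)
        grid_roots = np.sort(us[idx])
        found = np.sort([r.location[0] for r in reps])
        np.testing.assert_allclose(found, grid_roots, atol=5e-4)

    def test_gating_coordinate_on_nullcline(self, params2d_class1):
        for rep in find_equilibria_2d(params2d_class1, 20.0):
            u1s, u2s = rep.location
            assert u2s == pytest.approx(
                float(gating_functions(u1s, params2d_class1).w_inf), abs=1e-9
            )

    def test_middle_branch_is_saddle_for_every_order(self, params2d_class1):
        # branch-2 equilibria have negative determinant: saddle no matter
        # the fractional order
        for Im in np.linspace(CLASS1_IM_MIN + 1, CLASS1_IM_MAX - 1, 7):
            reps = find_equilibria_2d(params2d_class1, float(Im))
            mid = [r for r in reps if r.branch == 2]
            assert len(mid) == 1
            assert mid[0].zeta < 0
            for order in (0.1, 0.5, 0.99):
                assert classify_equilibrium(
                    mid[0].eigenvalues, order
                ).startswith("saddle")

    def test_class2_unique_equilibrium_location(self, params2d_class2):
        reps = find_equilibria_2d(params2d_class2, 100.0)
        assert len(reps) == 1
        assert reps[0].location[0] == pytest.approx(-23.09182, abs=1e-4)


class TestEquilibrium3D:
    def test_fast_voltage_pinned_by_slow_offset(self, params3d):
        assert find_equilibrium_3d(params3d["i"]).location[0] == pytest.approx(-0.22)
        assert find_equilibrium_3d(params3d["iii"]).location[0] == pytest.approx(0.0)

    def test_residual_vanishes(self, params3d):
        for g in ("i", "ii", "iii"):
            rep = find_equilibrium_3d(params3d[g])
            assert np.max(np.abs(rhs_3d(rep.location, params3d[g]))) < 1e-9

    def test_assumption_warning(self, params3d):
        import dataclasses

        bad = dataclasses.replace(params3d["i"], F0=1.0)
        with pytest.warns(RuntimeWarning):
            find_equilibrium_3d(bad)


class TestJacobians:
    def test_2d_matches_finite_differences(self, params2d_class1):
        p = params2d_class1
        for rep in find_equilibria_2d(p, 20.0):
            J = jacobian_2d(p, *rep.location)
            Jfd = finite_difference_jacobian(lambda x: rhs_2d(x, p, 20.0), rep.location)
            np.testing.assert_allclose(J, Jfd, atol=1e-6)

    def test_2d_gating_row_closed_form(self, params2d_class1):
        p = params2d_class1
        rep = find_equilibria_2d(p, 43.0)[0]
        u1s, u2s = rep.location
        g = gating_functions(u1s, p)
        dw = 0.5 / p.F4 / math.cosh((u1s - p.F3) / p.F4) ** 2
        J = jacobian_2d(p, u1s, u2s)
        assert J[1, 0] == pytest.approx(p.phi * g.rate * dw, rel=1e-9)
        assert J[1, 1] == pytest.approx(-p.phi * g.rate, rel=1e-12)

    def test_3d_matches_finite_differences(self, params3d):
        for g in ("i", "ii", "iii"):
            p = params3d[g]
            rep = find_equilibrium_3d(p)
            J = jacobian_3d(p, rep.location)
            Jfd = finite_difference_jacobian(lambda x: rhs_3d(x, p), rep.location)
            np.testing.assert_allclose(J, Jfd, atol=1e-6)

    def test_3d_slow_row(self, params3d):
        p = params3d["ii"]
        J = jacobian_3d(p, find_equilibrium_3d(p).location)
        np.testing.assert_allclose(J[2], [p.theta, 0.0, 0.0])

    def test_linear_synthetic_model_exact(self):
        # with flat gating (huge slopes) the 2D field is affine; the
        # Jacobian must then be an exact constant matrix
        from fracml import MLParams2D

        p = MLParams2D(
            C=2.0, WCa=1.0, WK=3.0, WL=0.5,
            FCa=100.0, FK=-80.0, FL=-50.0,
            F1=0.0, F2=1e12, F3=0.0, F4=1e12, phi=0.1,
        )
        J = jacobian_2d(p, 0.0, 0.25)
        # r_inf = w_inf = 1/2, derivatives ~ 0, ell = 1
        expected = np.array(
            [[-(1.0 * 0.5 + 3.0 * 0.25 + 0.5) / 2.0, -3.0 * (0.0 + 80.0) / 2.0],
             [0.1 * 0.0, -0.1]]
        )
        np.testing.assert_allclose(J, expected, atol=1e-10)


class TestHopfThreshold2D:
    @pytest.mark.parametrize(
        "chi,zeta,expected",
        [(0.0, 1.0, 1.0), (2.0, 1.0, 0.0), (math.sqrt(2.0), 1.0, 0.5)],
    )
    def test_arccos_formula(self, chi, zeta, expected):
        value, _ = hopf_threshold_2d(chi, zeta)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_negative_trace_stable_for_all_orders(self):
        assert hopf_threshold_2d(-0.5, 1.0) == (1.0, "stable-for-all-orders")

    def test_saddle_has_no_threshold(self):
        value, flag = hopf_threshold_2d(0.3, -1.0)
        assert value is None and flag == "saddle"

    def test_classification_flips_exactly_at_threshold(self, params2d_class2):
        # bisection in the order: Matignon label changes at the arccos value
        rep = find_equilibria_2d(params2d_class2, 100.0)[0]
        theta_star = rep.hopf_order
        lo, hi = 0.01, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if classify_equilibrium(rep.eigenvalues, mid) == "stable":
                lo = mid
            else:
                hi = mid
        assert 0.5 * (lo + hi) == pytest.approx(theta_star, abs=1e-6)


class TestCubic3D:
    def test_known_characteristic_polynomial(self):
        w1, w2, w3, _ = cubic_coefficients_3d(np.diag([-1.0, -2.0, -3.0]))
        assert (w1, w2, w3) == pytest.approx((6.0, 11.0, 6.0))

    def test_eigenvalue_roundtrip(self, params3d):
        for g in ("i", "ii", "iii"):
            rep = find_equilibrium_3d(params3d[g])
            w1, w2, w3 = rep.cubic
            for lam in rep.eigenvalues:
                res = lam**3 + w1 * lam**2 + w2 * lam + w3
                assert abs(res) < 1e-8

    def test_groups_i_ii_are_rank_two_saddles(self, params3d):
        for g in ("i", "ii"):
            rep = find_equilibrium_3d(params3d[g])
            assert rep.discriminant > 0          # three real eigenvalues
            ev = np.sort(rep.eigenvalues.real)
            assert ev[0] < 0 < ev[1] <= ev[2]
            assert classify_equilibrium(rep.eigenvalues, 0.9) == "saddle-rank-2"

    def test_group_iii_has_unstable_complex_pair(self, params3d):
        rep = find_equilibrium_3d(params3d["iii"])
        assert rep.discriminant < 0
        cplx = rep.eigenvalues[np.abs(rep.eigenvalues.imag) > 1e-12]
        assert len(cplx) == 2
        assert np.all(cplx.real > 0)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            cubic_coefficients_3d(np.eye(2))


class TestClassification:
    def test_negative_real_eigenvalues_always_stable(self):
        for order in (0.2, 0.7, 1.0):
            assert classify_equilibrium([-1.0, -2.0], order) == "stable"

    def test_complex_pair_stable_below_angle(self):
        # arg = pi/4 > 0.4 * pi/2
        assert classify_equilibrium([1 + 1j, 1 - 1j], 0.4) == "stable"
        assert classify_equilibrium([1 + 1j, 1 - 1j], 0.6) == "unstable"

    def test_saddle_rank_one(self):
        assert classify_equilibrium([2.0, -1.0, -1.0], 0.9) == "saddle-rank-1"

    def test_boundary_flag(self):
        lam = complex(math.cos(0.3 * math.pi / 2), math.sin(0.3 * math.pi / 2))
        assert classify_equilibrium([lam], 0.3) == "hopf-boundary"


class TestCriticalOrder3D:
    def test_unit_complex_pair(self):
        J = np.array([[1.0, -1.0, 0], [1.0, 1.0, 0], [0, 0, -5.0]])
        value, flag = critical_order_3d(J)  # eigenvalues 1 +- i, -5
        assert value == pytest.approx(0.5)
        assert flag == "hopf"

    def test_pure_imaginary_pair(self):
        J = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, -1.0]])
        value, _ = critical_order_3d(J)
        assert value == pytest.approx(1.0)

    def test_hurwitz_matrix_stable_for_all_orders(self):
        assert critical_order_3d(np.diag([-1.0, -2.0, -3.0])) == (
            1.0, "stable-for-all-orders",
        )

    def test_group_iii_threshold(self, params3d):
        rep = find_equilibrium_3d(params3d["iii"])
        assert rep.hopf_order == pytest.approx(0.75170, abs=1e-4)


class TestDiscreteStabilityRegions:
    def test_real_negative_eigenvalue_admissible(self):
        # |arg| = pi >= pi/4 and modulus bound 2**0.5 ~ 1.414 >= 1
        assert commensurate_stability_test([-1.0], 0.5)

    def test_positive_real_axis_always_unstable(self):
        for order in (0.2, 0.5, 0.9):
            assert not commensurate_stability_test([0.5], order)

    def test_verdict_matches_simulated_decay(self):
        traj = solve_commensurate(lambda x: -0.8 * x, 0.7, [1.0], 8000)
        assert commensurate_stability_test([-0.8], 0.7)
        assert abs(traj.states[-1, 0]) < 1e-3

    def test_euler_limit_of_modulus_bound(self):
        # just inside/outside the order->1 Euler circle on the real axis
        assert commensurate_stability_test([-1.9], 0.999)
        assert not commensurate_stability_test([-2.1], 0.999)

    def test_incommensurate_lcm(self):
        spec = OrderSpec.from_orders([0.5, 1 / 3])
        assert spec.lcm_denominator == 6

    def test_equal_orders_agree_with_commensurate(self, rng):
        spec = OrderSpec.from_orders([0.5, 0.5])
        for _ in range(8):
            A = rng.uniform(-0.7, 0.7, (2, 2))
            verdict, _ = incommensurate_stability_test(A, spec)
            assert verdict == commensurate_stability_test(np.linalg.eigvals(A), 0.5)

    def test_diagonal_stable_system(self):
        J = np.diag([-0.1, -0.1])
        spec = OrderSpec.from_orders([0.5, 1 / 3])
        verdict, roots = incommensurate_stability_test(J, spec)
        assert verdict
        traj = solve_incommensurate(lambda x: J @ x, (0.5, 1 / 3), [1.0, 1.0], 4000)
        amp = np.abs(traj.states).max(axis=1)
        assert amp[-100:].max() < amp[:100].max()

    def test_requires_rational_forms(self):
        with pytest.raises(ValueError):
            incommensurate_stability_test(
                np.eye(2), OrderSpec(orders=(0.5, 1 / 3))
            )

    def test_degree_cap(self):
        spec = OrderSpec.from_orders([0.5, 340 / 341])
        with pytest.raises(ValueError):
            incommensurate_stability_test(np.eye(2), spec, degree_cap=100)


class TestStabilityReport:
    def test_2d_report_scans_currents(self):
        from fracml import stability_report

        rep = stability_report("i", 2, currents=[43.0, 50.0, 90.0])
        thresholds = [
            c["equilibria"][0]["hopf_order"] for c in rep["currents"]
        ]
        assert thresholds[0] == pytest.approx(0.77598, abs=1e-4)
        assert thresholds[1] == pytest.approx(0.81547, abs=1e-4)
        assert thresholds[2] == pytest.approx(0.97647, abs=1e-4)

    def test_3d_report(self):
        from fracml import stability_report

        rep = stability_report("iii", 3)
        assert rep["equilibrium"]["hopf_order"] == pytest.approx(0.7517, abs=1e-3)
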