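"""Equilibria, Jacobians, fractional stability tests, and Hopf thresholds.

For the fractional-order linearisation the stability boundary is angular:
an equilibrium is asymptotically stable when every Jacobian eigenvalue
satisfies ``|arg(lambda)| > order * pi / 2`` (Matignon criterion).  For a
2D equilibrium with trace chi and determinant zeta > 0 this gives the Hopf
threshold in the *order* parameter,

.. math::

    \\vartheta^* = \\frac{2}{\\pi}
        \\arccos\\!\\left( \\frac{\\chi}{2\\sqrt{\\zeta}} \\right),

so the equilibrium is stable for orders below ``\\vartheta^*`` and a
Hopf-type bifurcation (onset of sustained oscillation) occurs as the order
crosses it.  The discrete-map refinements (the commensurate modulus bound
and the incommensurate root test on the expanded characteristic polynomial)
are provided alongside; the Matignon test is the default classifier since
it is what determines the reported thresholds.

Jacobians are differentiated analytically from the implemented vector
fields rather than transcribed, so they stay consistent with the dynamics
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .frac_calculus import OrderSpec
from .ml_models import (
    MLParams2D,
    MLParams3D,
    gating_functions,
    gating_functions_3d,
    ionic_current,
    rhs_2d,
    rhs_3d,
)

__all__ = [
    "EquilibriumReport",
    "steady_state_current",
    "steady_state_critical_points",
    "find_equilibria_2d",
    "find_equilibrium_3d",
    "jacobian_2d",
    "jacobian_3d",
    "hopf_threshold_2d",
    "cubic_coefficients_3d",
    "classify_equilibrium",
    "critical_order_3d",
    "commensurate_stability_test",
    "incommensurate_stability_test",
    "stability_report",
]

_BOUNDARY_TOL = 1e-9


@dataclass
class EquilibriumReport:
    """Everything the stability analysis knows about one equilibrium."""

    location: tuple
    branch: Optional[int]            # 1/2/3 for 2D, None for the unique 3D point
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    chi: Optional[float] = None      # 2D trace
    zeta: Optional[float] = None     # 2D determinant
    cubic: Optional[tuple] = None    # 3D (w1, w2, w3)
    discriminant: Optional[float] = None
    hopf_order: Optional[float] = None
    hopf_flag: str = ""
    classification: str = ""
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "location": [float(v) for v in self.location],
            "branch": self.branch,
            "jacobian": self.jacobian.tolist(),
            "eigenvalues": [[ev.real, ev.imag] for ev in np.atleast_1d(self.eigenvalues)],
            "chi": self.chi,
            "zeta": self.zeta,
            "cubic": list(self.cubic) if self.cubic is not None else None,
            "discriminant": self.discriminant,
            "hopf_order": self.hopf_order,
            "hopf_flag": self.hopf_flag,
            "classification": self.classification,
        }


# ---------------------------------------------------------------------------
# 2D steady states


def steady_state_current(u1, params: MLParams2D):
    """Im_inf(u1) = Ibar(u1, w_inf(u1)): the current that holds u1 steady."""
    w = gating_functions(u1, params).w_inf
    return ionic_current(u1, w, params)


def _dIinf(u1: float, params: MLParams2D) -> float:
    """Analytic derivative of the steady-state current."""
    g = gating_functions(u1, params)
    dr = 0.5 / params.F2 * (1.0 / np.cosh((u1 - params.F1) / params.F2)) ** 2
    dw = 0.5 / params.F4 * (1.0 / np.cosh((u1 - params.F3) / params.F4)) ** 2
    return (
        params.WCa * (dr * (u1 - params.FCa) + g.r_inf)
        + params.WK * (dw * (u1 - params.FK) + g.w_inf)
        + params.WL
    )


def steady_state_critical_points(
    params: MLParams2D, u_range: Tuple[float, float] = (-120.0, 160.0)
) -> Optional[Tuple[float, float]]:
    """Fold points of Im_inf: (u1_max, u1_min) with u1_max < u1_min.

    The steady-state current is leak-dominated at both ends (slope > 0).
    Class-I-type sets dip once in between, giving a local maximum followed
    by a local minimum; the two sign changes of the analytic derivative
    are bracketed on a dense grid and polished by brentq.  Class-II-type
    sets are monotone increasing and return None (single branch, unique
    equilibrium for every applied current).
    """
    us = np.linspace(*u_range, 20001)
    d = np.array([_dIinf(u, params) for u in us])
    idx = np.where(np.sign(d[:-1]) != np.sign(d[1:]))[0]
    crit = [brentq(lambda u: _dIinf(u, params), us[i], us[i + 1]) for i in idx]
    if len(crit) == 0:
        return None
    if len(crit) != 2:
        raise RuntimeError(
            f"expected zero or two critical points of Im_inf, found {len(crit)}"
        )
    return min(crit), max(crit)


def find_equilibria_2d(
    params: MLParams2D,
    Im: float,
    order: float = 1.0,
    u_range: Tuple[float, float] = (-120.0, 160.0),
) -> List[EquilibriumReport]:
    """All equilibria of the 2D model at applied current Im.

    Im_inf is monotone on the three branches cut by its critical points, so
    each branch is searched by bracketed root-finding; depending on where
    Im sits relative to the fold currents there are one, two, or three
    steady states.  Each report carries the branch label, analytic
    Jacobian, trace/determinant, Hopf threshold and Matignon
    classification at the given order.
    """
    folds = steady_state_critical_points(params, u_range)
    f = lambda u: float(steady_state_current(u, params) - Im)
    brackets = []
    if folds is None:
        # monotone Im_inf: unique equilibrium on the single branch
        if f(u_range[0]) * f(u_range[1]) > 0:
            raise RuntimeError(
                f"Im = {Im} outside the steady-state current range on {u_range}"
            )
        brackets.append((u_range[0], u_range[1], 1))
    else:
        u1max, u1min = folds
        Imax = float(steady_state_current(u1max, params))
        Imin = float(steady_state_current(u1min, params))
        # branch 1: increasing on (-inf, u1max]
        if f(u_range[0]) < 0 <= f(u1max) or f(u_range[0]) > 0 >= f(u1max):
            brackets.append((u_range[0], u1max, 1))
        # branch 2: decreasing on (u1max, u1min)
        if Imin < Im < Imax:
            brackets.append((u1max, u1min, 2))
        # branch 3: increasing on [u1min, inf)
        if f(u1min) < 0 <= f(u_range[1]) or f(u1min) > 0 >= f(u_range[1]):
            brackets.append((u1min, u_range[1], 3))

    reports = []
    seen: list = []
    for lo, hi, branch in brackets:
        try:
            u1s = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
        except ValueError as exc:
            raise RuntimeError(
                f"root bracketing failed on branch {branch} [{lo}, {hi}]: {exc}"
            ) from exc
        if any(abs(u1s - u) < 1e-8 for u in seen):
            continue  # double root at a fold current
        seen.append(u1s)
        reports.append(_report_2d(u1s, branch, params, Im, order))
    return reports


def jacobian_2d(params: MLParams2D, u1: float, u2: float) -> np.ndarray:
    """Analytic Jacobian of the 2D vector field at (u1, u2)."""
    g = gating_functions(u1, params)
    sech1 = 1.0 / np.cosh((u1 - params.F1) / params.F2)
    sech3 = 1.0 / np.cosh((u1 - params.F3) / params.F4)
    dr = 0.5 / params.F2 * sech1**2
    dw = 0.5 / params.F4 * sech3**2
    dell = np.sinh((u1 - params.F3) / (2.0 * params.F4)) / (2.0 * params.F4)
    dIbar_du1 = (
        params.WCa * (dr * (u1 - params.FCa) + g.r_inf)
        + params.WK * u2
        + params.WL
    )
    dIbar_du2 = params.WK * (u1 - params.FK)
    return np.array(
        [
            [-dIbar_du1 / params.C, -dIbar_du2 / params.C],
            [
                params.phi * (dell * (g.w_inf - u2) + g.rate * dw),
                -params.phi * g.rate,
            ],
        ]
    )


def _report_2d(
    u1s: float, branch: int, params: MLParams2D, Im: float, order: float
) -> EquilibriumReport:
    u2s = float(gating_functions(u1s, params).w_inf)
    J = jacobian_2d(params, u1s, u2s)
    ev = np.linalg.eigvals(J)
    chi = float(np.trace(J))
    zeta = float(np.linalg.det(J))
    hopf = hopf_threshold_2d(chi, zeta)
    rep = EquilibriumReport(
        location=(u1s, u2s),
        branch=branch,
        jacobian=J,
        eigenvalues=ev,
        chi=chi,
        zeta=zeta,
        hopf_order=hopf[0],
        hopf_flag=hopf[1],
        classification=classify_equilibrium(ev, order),
    )
    res = rhs_2d((u1s, u2s), params, Im)
    rep.extras["residual"] = float(np.max(np.abs(res)))
    return rep


# ---------------------------------------------------------------------------
# 3D steady state


def find_equilibrium_3d(
    params: MLParams3D, order: float = 1.0, u3_bracket: Tuple[float, float] = (-100.0, 100.0)
) -> EquilibriumReport:
    """The unique equilibrium of the slow-fast model.

    The slow equation pins u1* = -F0; u3* is the unique root of the
    strictly decreasing map u3 -> Im(u3) - Ibar(-F0, w_bar(-F0, u3)),
    found by bracketed bisection, and u2* = w_bar(u1*, u3*).  The working
    assumption F0 + FK < 0 (so the K+ driving force at rest is positive)
    is checked and reported, not enforced.
    """
    import warnings

    if params.F0 + params.FK >= 0:
        warnings.warn(
            "F0 + FK >= 0: the monotonicity argument for a unique slow "
            "equilibrium is not guaranteed",
            RuntimeWarning,
        )
    u1s = -params.F0

    def g(u3):
        w = gating_functions_3d(u1s, u3, params).w_inf
        return params.applied_current(u3) - ionic_current(u1s, w, params)

    lo, hi = u3_bracket
    if g(lo) * g(hi) > 0:
        raise RuntimeError(
            f"no sign change for the slow-variable root in [{lo}, {hi}]"
        )
    u3s = brentq(g, lo, hi, xtol=1e-14)
    u2s = float(gating_functions_3d(u1s, u3s, params).w_inf)

    J = jacobian_3d(params, (u1s, u2s, u3s))
    ev = np.linalg.eigvals(J)
    w1, w2, w3, D = cubic_coefficients_3d(J)
    crit = critical_order_3d(J)
    rep = EquilibriumReport(
        location=(u1s, u2s, u3s),
        branch=None,
        jacobian=J,
        eigenvalues=ev,
        cubic=(w1, w2, w3),
        discriminant=D,
        hopf_order=crit[0],
        hopf_flag=crit[1],
        classification=classify_equilibrium(ev, order),
    )
    rep.extras["residual"] = float(np.max(np.abs(rhs_3d((u1s, u2s, u3s), params))))
    return rep


def jacobian_3d(params: MLParams3D, state: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian of the 3D vector field; third row is (theta, 0, 0).

    The slow variable enters the fast subsystem only through
    F3(u3) = F3_base - u3, so every u3-derivative of a gating factor equals
    the corresponding u1-derivative (chain rule with dF3/du3 = -1).
    """
    u1, u2, u3 = state
    g = gating_functions_3d(u1, u3, params)
    F3 = float(params.F3(u3))
    z = u1 - F3
    sech1 = 1.0 / np.cosh((u1 - params.F1) / params.F2)
    sechw = 1.0 / np.cosh(z / params.F4)
    dr = 0.5 / params.F2 * sech1**2
    dw = 0.5 / params.F4 * sechw**2
    if params.rate_scaling == "amplitude":
        dell = np.sinh(z) / (2.0 * params.F4)
    else:
        dell = np.sinh(z / (2.0 * params.F4)) / (2.0 * params.F4)
    dIbar_du1 = (
        params.WCa * (dr * (u1 - 1.0) + g.r_inf) + params.WK * u2 + params.WL
    )
    dIbar_du2 = params.WK * (u1 - params.FK)
    f2_u1 = params.phi * (dell * (g.w_inf - u2) + g.rate * dw)
    return np.array(
        [
            [-dIbar_du1 / params.C, -dIbar_du2 / params.C, params.Im_slope / params.C],
            [f2_u1, -params.phi * g.rate, f2_u1],
            [params.theta, 0.0, 0.0],
        ]
    )


# ---------------------------------------------------------------------------
# stability machinery


def hopf_threshold_2d(chi: float, zeta: float) -> Tuple[Optional[float], str]:
    """Critical order from the trace/determinant of a 2D Jacobian.

    Returns (order, flag): 1.0 with flag "stable-for-all-orders" when
    chi < 0; the arccos threshold when 0 <= chi < 2 sqrt(zeta); 0.0 with
    "unstable-for-all-orders" when chi >= 2 sqrt(zeta); (None, "saddle")
    when zeta <= 0, where no angular threshold exists.
    """
    if zeta <= 0:
        return None, "saddle"
    root = 2.0 * math.sqrt(zeta)
    if chi < 0:
        return 1.0, "stable-for-all-orders"
    if chi >= root:
        return 0.0, "unstable-for-all-orders"
    return 2.0 / math.pi * math.acos(chi / root), "hopf"


def cubic_coefficients_3d(J: np.ndarray) -> Tuple[float, float, float, float]:
    """(w1, w2, w3, D): monic characteristic cubic and its discriminant.

    lambda^3 + w1 lambda^2 + w2 lambda + w3 with w1 = -tr(J), w2 = sum of
    principal 2x2 minors, w3 = -det(J); D > 0 means three distinct real
    eigenvalues, D < 0 one real eigenvalue and a complex pair.
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got {J.shape}")
    tr = np.trace(J)
    w1 = -tr
    w2 = 0.5 * (tr**2 - np.trace(J @ J))
    w3 = -np.linalg.det(J)
    D = (
        18.0 * w1 * w2 * w3
        - 4.0 * w1**3 * w3
        + w1**2 * w2**2
        - 4.0 * w2**3
        - 27.0 * w3**2
    )
    return float(w1), float(w2), float(w3), float(D)


def classify_equilibrium(
    eigenvalues: Sequence[complex], order: float, tol: float = _BOUNDARY_TOL
) -> str:
    """Matignon classification at the given fractional order.

    stable iff every eigenvalue's argument exceeds order*pi/2 in absolute
    value; the count of violating eigenvalues gives the saddle rank; exact
    boundary eigenvalues (within tol) flag a Hopf boundary.
    """
    ev = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if not (0.0 < order <= 1.0):
        raise ValueError("order must lie in (0, 1]")
    half = order * math.pi / 2.0
    args = np.abs(np.angle(ev))
    if np.any(np.abs(args - half) < tol):
        return "hopf-boundary"
    n_unstable = int(np.sum(args < half))
    if n_unstable == 0:
        return "stable"
    if n_unstable == ev.size:
        return "unstable"
    return f"saddle-rank-{n_unstable}"


def critical_order_3d(J: np.ndarray) -> Tuple[float, str]:
    """Matignon boundary order of a 3D Jacobian.

    With an unstable complex pair the threshold is (2/pi) times the
    smallest eigenvalue argument: stable below, unstable above.  All
    eigenvalues in the open left half-plane return 1.0 (stable for every
    admissible order); an unstable *real* eigenvalue returns 0.0 (no
    stabilising order exists).
    """
    ev = np.linalg.eigvals(np.asarray(J, dtype=float))
    args = np.abs(np.angle(ev))
    if np.all(ev.real < 0):
        return 1.0, "stable-for-all-orders"
    if np.any((ev.real >= 0) & (np.abs(ev.imag) < 1e-14)):
        return 0.0, "unstable-for-all-orders"
    return float(2.0 / math.pi * np.min(args[ev.real >= 0])), "hopf"


def commensurate_stability_test(
    eigenvalues: Sequence[complex], order: float
) -> bool:
    """Discrete-map stability region for a commensurate system.

    An eigenvalue w is admissible iff
    ``|w| <= (2 cos((|arg w| - pi)/(2 - order)))**order`` and
    ``|arg w| >= order*pi/2``; the system is asymptotically stable iff
    every eigenvalue is admissible.  The order -> 1 limit recovers the
    explicit-Euler stability disc ``|1 + w| < 1`` boundary on the real
    axis (|w| < 2 at arg = pi), which pins down the constant in front of
    the cosine.
    """
    if not (0.0 < order < 1.0):
        raise ValueError("order must lie in (0, 1)")
    ev = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    for w in ev:
        a = abs(np.angle(w))
        if a < order * math.pi / 2.0:
            return False
        inner = 2.0 * math.cos((a - math.pi) / (2.0 - order))
        if inner < 0:
            return False
        if abs(w) > inner**order:
            return False
    return True


def _in_unstable_region(w: complex, xi: float, tol: float = _BOUNDARY_TOL) -> bool:
    """Membership in the instability set K^xi of the incommensurate test."""
    a = abs(np.angle(w))
    if a > xi * math.pi / 2.0 + tol:
        return False
    inner = 2.0 * math.cos(a / xi) if a / xi <= math.pi / 2.0 else 0.0
    if inner <= 0:
        return abs(w) <= tol
    return abs(w) <= inner**xi + tol


def incommensurate_stability_test(
    jacobian: np.ndarray,
    orders: OrderSpec,
    degree_cap: int = 600,
) -> Tuple[bool, np.ndarray]:
    """Root test for a system with distinct rational orders.

    Expands ``det(diag(p^(H v1), ..., p^(H vn)) - (1 - p^H) J)`` into a
    univariate polynomial in p (sympy, exact integer exponents H*v_i),
    finds all roots through the companion matrix, and declares stability
    iff every root lies outside the instability set K^(1/H).  Returns
    (verdict, roots).
    """
    import sympy as sp

    J = np.asarray(jacobian, dtype=float)
    n = J.shape[0]
    if J.shape != (n, n):
        raise ValueError("jacobian must be square")
    if orders.rational_forms is None:
        raise ValueError(
            "orders must carry rational forms; build the spec with "
            "OrderSpec.from_orders to rationalise them"
        )
    if len(orders.orders) != n:
        raise ValueError("one order per state dimension required")
    H = orders.lcm_denominator
    exps = [H * p // q for p, q in orders.rational_forms]
    deg = max(max(exps), n * H)
    if deg > degree_cap:
        raise ValueError(
            f"stability polynomial degree {deg} exceeds cap {degree_cap}; "
            "use smaller denominators"
        )
    rho = sp.symbols("rho")
    M = sp.zeros(n, n)
    one_minus = 1 - rho**H
    for i in range(n):
        for j in range(n):
            M[i, j] = -one_minus * sp.Float(J[i, j], 17)
        M[i, i] = M[i, i] + rho ** exps[i]
    poly = sp.Poly(sp.expand(M.det()), rho)
    coeffs = np.array([float(c) for c in poly.all_coeffs()], dtype=float)
    roots = np.roots(coeffs)
    xi = 1.0 / H
    stable = not any(_in_unstable_region(w, xi) for w in roots)
    return stable, roots


# ---------------------------------------------------------------------------
# aggregate report


def stability_report(
    group_id: str,
    model_dim: int,
    currents: Optional[Sequence[float]] = None,
    order: float = 1.0,
) -> dict:
    """JSON-ready stability summary for a parameter group.

    For 2D groups every requested applied current is analysed (default:
    the group's printed currents), so the report doubles as a scan that
    records which current carries which critical order.  For 3D groups the
    unique equilibrium is reported.
    """
    from .ml_models import parameter_registry

    fx = parameter_registry(group_id, model_dim)
    out = {"group": group_id, "model_dim": model_dim, "order": order}
    if model_dim == 2:
        scan = []
        for Im in currents if currents is not None else fx.applied_currents:
            reps = find_equilibria_2d(fx.params, float(Im), order=order)
            scan.append(
                {"Im": float(Im), "equilibria": [r.as_dict() for r in reps]}
            )
        out["currents"] = scan
    else:
        out["equilibrium"] = find_equilibrium_3d(fx.params, order=order).as_dict()
    return out
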