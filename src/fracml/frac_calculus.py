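"""Discrete fractional sums, Caputo differences, and memory-convolution solvers.

The central object is the delta fractional sum on the integer time scale
``N_a = {a, a+1, ...}``,

.. math::

    \\Delta_a^{-\\vartheta} F(\\xi)
        = \\frac{1}{\\Gamma(\\vartheta)} \\sum_{\\Upsilon=0}^{\\xi-a}
          (\\xi - 1 - \\Upsilon)^{(\\vartheta-1)} F(\\Upsilon),

where ``t^{(\\nu)} = \\Gamma(t+1)/\\Gamma(t-\\nu+1)`` is the falling
factorial.  The Caputo fractional difference of order ``\\vartheta in (0,1)``
is the order ``1-\\vartheta`` fractional sum of the first forward
difference, which is what gives the discrete model its full-history
("memory") dependence.

The explicit solver realises the closed-form solution of the Caputo
difference initial-value problem,

.. math::

    x(n) = x(0) + \\frac{h^{\\vartheta}}{\\Gamma(\\vartheta)}
           \\sum_{\\lambda=0}^{n-1}
           \\frac{\\Gamma(n-\\lambda-1+\\vartheta)}{\\Gamma(n-\\lambda)}
           f(x(\\lambda)),

a fractional generalisation of the explicit Euler map (``\\vartheta = 1``,
``h = 1`` recovers ``x(n+1) = x(n) + f(x(n))`` exactly).  All Gamma ratios
are evaluated by the stable multiplicative recurrence
``c_0 = 1, c_j = c_{j-1} (j-1+\\vartheta)/j``; direct Gamma quotients
overflow beyond argument ~170 and are never used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "OrderSpec",
    "KernelWeights",
    "Trajectory",
    "SolverDivergenceError",
    "kernel_weights",
    "fractional_sum",
    "integer_difference",
    "caputo_difference",
    "solve_commensurate",
    "solve_incommensurate",
]


class SolverDivergenceError(RuntimeError):
    """State became non-finite during integration.

    Divergence aborts the run rather than clipping the state: silently
    clipped trajectories corrupt bifurcation sweeps.
    """

    def __init__(self, step: int, state=None):
        self.step = step
        self.state = state
        super().__init__(
            f"solver state became non-finite at step {step}; "
            "reduce the step size or check the vector field"
        )


@dataclass(frozen=True)
class OrderSpec:
    """Per-component fractional orders of an incommensurate system.

    ``rational_forms`` holds (numerator, denominator) pairs in lowest terms
    and ``lcm_denominator`` (H) is the least common multiple of the
    denominators, the quantity entering the incommensurate stability
    polynomial.  Orders equal across components mark the spec commensurate.
    """

    orders: tuple
    rational_forms: Optional[tuple] = None
    lcm_denominator: Optional[int] = None

    def __post_init__(self):
        orders = tuple(float(o) for o in self.orders)
        object.__setattr__(self, "orders", orders)
        if not orders:
            raise ValueError("OrderSpec needs at least one order")
        for o in orders:
            if not (0.0 < o <= 1.0):
                raise ValueError(f"fractional order {o} outside (0, 1]")
        if self.rational_forms is not None:
            forms = tuple((int(p), int(q)) for p, q in self.rational_forms)
            if len(forms) != len(orders):
                raise ValueError("one rational form per order required")
            for (p, q), o in zip(forms, orders):
                if q <= 0 or math.gcd(p, q) != 1:
                    raise ValueError(f"rational form {p}/{q} not in lowest terms")
                if abs(p / q - o) > 1e-12:
                    raise ValueError(f"rational form {p}/{q} does not match order {o}")
            object.__setattr__(self, "rational_forms", forms)
            H = 1
            for _, q in forms:
                H = H * q // math.gcd(H, q)
            if self.lcm_denominator is None:
                object.__setattr__(self, "lcm_denominator", H)
            elif self.lcm_denominator != H:
                raise ValueError("lcm_denominator inconsistent with rational forms")

    @classmethod
    def from_orders(cls, orders: Sequence[float], max_denominator: int = 1000) -> "OrderSpec":
        """Build a spec, rationalising each order with bounded denominators."""
        forms = []
        for o in orders:
            fr = Fraction(o).limit_denominator(max_denominator)
            if abs(float(fr) - o) > 1e-12:
                raise ValueError(
                    f"order {o} has no rational form with denominator <= {max_denominator}"
                )
            forms.append((fr.numerator, fr.denominator))
        return cls(orders=tuple(orders), rational_forms=tuple(forms))

    @property
    def commensurate(self) -> bool:
        return all(o == self.orders[0] for o in self.orders)

    @property
    def dimension(self) -> int:
        return len(self.orders)


@dataclass(frozen=True)
class KernelWeights:
    """Memory-kernel weights ``c_j = Gamma(j+order)/(Gamma(order) Gamma(j+1))``.

    ``c_0 = 1`` and the weights decrease strictly for order < 1; the solver
    scales the convolution by ``step**order``.
    """

    order: float
    weights: np.ndarray
    step: float = 1.0

    @property
    def memory_length(self) -> int:
        return len(self.weights)


def kernel_weights(order: float, n_terms: int, step: float = 1.0) -> KernelWeights:
    """Gamma-ratio convolution weights of the fractional Euler map.

    Computed by the multiplicative recurrence
    ``c_j = c_{j-1} (j - 1 + order)/j``, which is exact in exact arithmetic
    and numerically stable for arbitrarily many terms.
    """
    if not (0.0 < order <= 1.0):
        raise ValueError(f"order {order} outside (0, 1]")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    c = np.empty(n_terms)
    c[0] = 1.0
    for j in range(1, n_terms):
        c[j] = c[j - 1] * (j - 1 + order) / j
    return KernelWeights(order=float(order), weights=c, step=float(step))


def fractional_sum(values: Sequence[float], order: float, origin: float = 0.0) -> np.ndarray:
    """Delta fractional sum of the given order on ``N_origin``.

    Entry ``k`` of the result is the sum evaluated at
    ``xi = origin + order + k``; with the falling-factorial kernel this is a
    discrete convolution of the input with the Gamma-ratio weights.  Order 1
    collapses to the ordinary running sum.
    """
    f = np.asarray(values, dtype=float)
    if f.size == 0:
        raise ValueError("fractional_sum of an empty sequence")
    if order <= 0:
        raise ValueError("fractional sum order must be positive")
    n = f.size
    # weights Gamma(order + j) / (Gamma(order) Gamma(j + 1)), log-safe recurrence
    c = np.empty(n)
    c[0] = 1.0
    for j in range(1, n):
        c[j] = c[j - 1] * (j - 1 + order) / j
    out = np.empty(n)
    for k in range(n):
        out[k] = np.dot(c[: k + 1][::-1], f[: k + 1])
    return out


def integer_difference(values: Sequence[float], q: int) -> np.ndarray:
    """q-th forward difference via the signed binomial sum.

    ``(Delta^q F)(k) = sum_chi C(q, chi) (-1)^(q-chi) F(k + chi)``; for
    q = 1 this is the plain first forward difference.
    """
    f = np.asarray(values, dtype=float)
    if q <= 0:
        raise ValueError("difference order q must be a positive integer")
    if q >= f.size:
        raise ValueError(f"sequence of length {f.size} too short for Delta^{q}")
    signs = np.array([(-1) ** (q - chi) * math.comb(q, chi) for chi in range(q + 1)])
    n_out = f.size - q
    out = np.zeros(n_out)
    for chi, s in enumerate(signs):
        out += s * f[chi : chi + n_out]
    return out


def caputo_difference(values: Sequence[float], order: float) -> np.ndarray:
    """Caputo delta difference of order in (0, 1).

    Defined as the fractional sum of order ``1 - order`` applied to the
    first forward difference, on the shifted time scale; a constant
    sequence therefore maps to zero identically.
    """
    if not (0.0 < order < 1.0):
        raise ValueError(f"Caputo difference order {order} outside (0, 1)")
    f = np.asarray(values, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two points for a Caputo difference")
    return fractional_sum(integer_difference(f, 1), 1.0 - order)


@dataclass
class Trajectory:
    """Time-indexed state sequence from the memory-convolution solver."""

    times: np.ndarray
    states: np.ndarray  # shape (n_steps + 1, dim)
    order_spec: OrderSpec
    step: float = 1.0
    memory_length: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dimension(self) -> int:
        return self.states.shape[1]

    def component(self, i: int) -> np.ndarray:
        return self.states[:, i]

    def to_frame(self):
        """Columnar view ``time, u1, u2[, u3, ...]`` (pandas DataFrame)."""
        import pandas as pd

        cols = {"time": self.times}
        for i in range(self.dimension):
            cols[f"u{i + 1}"] = self.states[:, i]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        """Full-precision CSV with header ``time,u1,u2[,u3]``."""
        names = ["time"] + [f"u{i + 1}" for i in range(self.dimension)]
        data = np.column_stack([self.times, self.states])
        with open(path, "w") as fh:
            fh.write(",".join(names) + "\n")
            for row in data:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _check_finite(x: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(x)):
        raise SolverDivergenceError(step, x)


def solve_incommensurate(
    rhs: Callable[[np.ndarray], np.ndarray],
    orders,
    x0: Sequence[float],
    n_steps: int,
    step: float = 1.0,
    memory_length: Optional[int] = None,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate a Caputo-difference system with per-component orders.

    Each component carries its own Gamma-ratio kernel; components with
    equal orders share weights, so the commensurate solver is the exact
    special case.  ``memory_length`` truncates the convolution to the most
    recent L terms (short-memory principle); the default keeps the full
    quadratic-cost history.
    """
    if isinstance(orders, OrderSpec):
        spec = orders
    else:
        spec = OrderSpec(orders=tuple(orders))
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim != 1 or x0.size != spec.dimension:
        raise ValueError(
            f"state dimension {x0.size} does not match {spec.dimension} orders"
        )
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if memory_length is not None and memory_length <= 0:
        raise ValueError("memory_length must be positive")
    if step <= 0:
        raise ValueError("step must be positive")

    d = spec.dimension
    L = n_steps if memory_length is None else min(memory_length, n_steps)
    # one weight table per distinct order
    unique = {}
    for o in spec.orders:
        if o not in unique:
            unique[o] = kernel_weights(o, L).weights
    comp_w = [unique[o] for o in spec.orders]
    scale = np.array([step ** o for o in spec.orders])

    hist = np.empty((n_steps, d))  # f(x(lambda)) rows
    states = np.empty((n_steps + 1, d))
    states[0] = x0
    x = x0.copy()
    # overflow surfaces as inf and is converted into a divergence error
    with np.errstate(over="ignore", invalid="ignore"):
        for n in range(1, n_steps + 1):
            f = np.asarray(rhs(x), dtype=float)
            if f.shape != (d,):
                raise ValueError(f"rhs returned shape {f.shape}, expected ({d},)")
            _check_finite(f, n - 1)
            hist[n - 1] = f
            lo = max(0, n - L)
            window = hist[lo:n]  # (m, d)
            m = n - lo
            x = x0.copy()
            for i in range(d):
                # weights ordered oldest-memory last: c_{n-1-lambda}
                w = comp_w[i][:m][::-1]
                x[i] += scale[i] * np.dot(w, window[:, i])
            _check_finite(x, n)
            states[n] = x

    times = t0 + step * np.arange(n_steps + 1)
    return Trajectory(
        times=times,
        states=states,
        order_spec=spec,
        step=step,
        memory_length=memory_length,
    )


def solve_commensurate(
    rhs: Callable[[np.ndarray], np.ndarray],
    order: float,
    x0: Sequence[float],
    n_steps: int,
    step: float = 1.0,
    memory_length: Optional[int] = None,
    t0: float = 0.0,
) -> Trajectory:
    """Integrate a commensurate Caputo-difference system.

    With ``step = 1`` the iteration is bit-identical to the closed-form
    memory sum of the discrete model; ``order = 1`` is the explicit Euler
    map.  Scalar problems may pass a scalar ``x0`` wrapped to length one.
    """
    x0_arr = np.atleast_1d(np.asarray(x0, dtype=float))
    spec = OrderSpec(orders=(float(order),) * x0_arr.size)
    return solve_incommensurate(
        rhs, spec, x0_arr, n_steps, step=step, memory_length=memory_length, t0=t0
    )
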