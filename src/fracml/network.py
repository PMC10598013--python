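"""Erdos-Renyi coupled Morris-Lecar populations and the reduced cluster model.

A population of N two-variable neurons is coupled electrically (gap
junctions) on an undirected Erdos-Renyi graph.  Node ``i`` receives the
degree-normalised diffusive term

.. math::

    \\frac{W_\\epsilon}{\\sum_j c_{ij}} \\sum_j c_{ij} (u_{1j} - u_{1i})

on its voltage equation only; the gating variables stay uncoupled.  Each
node carries its own fractional order, set by a partition (r nodes at
order theta, s = N - r nodes at order phi), so heterogeneous memory depth
across the population is the object of study.

When the full network settles into cluster synchronisation, each cluster
can be replaced by one representative oscillator whose coupling strength
is weighted by the probability of meeting the other cluster in a random
neighbourhood — ``p_eps = s/N`` seen by the theta-cluster, ``p0 = r/N`` by
the phi-cluster, and optionally ``p1 = x/N`` for a third cluster.  The
reduced model uses the three-variable slow-fast neuron per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .frac_calculus import OrderSpec, SolverDivergenceError, Trajectory, kernel_weights
from .ml_models import MLParams2D, MLParams3D, gating_functions, ionic_current, rhs_3d

__all__ = [
    "NetworkSpec",
    "ReducedModelSpec",
    "NetworkTrajectory",
    "build_er_network",
    "assign_orders",
    "rhs_network",
    "simulate_network",
    "simulate_reduced",
]


@dataclass
class NetworkSpec:
    """Topology, coupling, and order assignment of one population."""

    N: int
    adjacency: np.ndarray            # symmetric 0/1, zero diagonal
    coupling: float                  # W_eps >= 0
    order_vector: np.ndarray         # per-node fractional order
    target_mean_degree: Optional[float] = None
    seed: Optional[int] = None
    rewired_nodes: tuple = ()

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.shape != (self.N, self.N):
            raise ValueError("adjacency shape does not match N")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if self.coupling < 0:
            raise ValueError("coupling strength must be >= 0")
        ov = np.asarray(self.order_vector, dtype=float)
        if ov.shape != (self.N,):
            raise ValueError("order_vector must have one entry per node")
        self.adjacency = A.astype(np.int8)
        self.order_vector = ov
        deg = self.degrees
        if np.any(deg < 1):
            raise ValueError("every node needs degree >= 1 (coupling normaliser)")

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1), dtype=float)

    def write_edge_list(self, path) -> None:
        """Plain text, one 0-based `i j` pair per line, i < j."""
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        with open(path, "w") as fh:
            for i, j in zip(ii, jj):
                fh.write(f"{i} {j}\n")


@dataclass
class ReducedModelSpec:
    """Two- or three-cluster reduction of a partitioned population.

    ``p_eps`` is the fraction of phi-cluster (activated) nodes met by a
    theta-cluster neuron, ``p0`` the converse, ``p1`` the optional third
    cluster fraction; applied current defaults to the slow-variable law of
    the 3D model when ``Im`` is None.
    """

    orders: Tuple[float, ...]        # (theta, phi) or (theta, phi, gamma)
    p_eps: float
    p0: float
    coupling: float
    params: MLParams3D
    p1: Optional[float] = None
    Im: Optional[float] = None

    def __post_init__(self):
        if len(self.orders) not in (2, 3):
            raise ValueError("reduced model has two or three clusters")
        probs = [self.p_eps, self.p0] + ([self.p1] if self.p1 is not None else [])
        if len(self.orders) == 3 and self.p1 is None:
            raise ValueError("three clusters need p1")
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("cluster probabilities must lie in [0, 1]")
        if self.p_eps + self.p0 > 1.0 + 1e-12:
            raise ValueError("p_eps + p0 cannot exceed 1")

    @classmethod
    def from_partition(
        cls,
        N: int,
        r: int,
        s: int,
        orders: Tuple[float, ...],
        coupling: float,
        params: MLParams3D,
        x: Optional[int] = None,
        Im: Optional[float] = None,
    ) -> "ReducedModelSpec":
        if r + s != N:
            raise ValueError(f"partition r + s = {r + s} != N = {N}")
        p1 = None
        if len(orders) == 3:
            x = N // 3 if x is None else x
            p1 = x / N
        return cls(
            orders=tuple(orders),
            p_eps=s / N,
            p0=r / N,
            p1=p1,
            coupling=coupling,
            params=params,
            Im=Im,
        )


@dataclass
class NetworkTrajectory:
    """Per-node voltage/gating traces of a simulated population."""

    times: np.ndarray
    states: np.ndarray               # (n_steps + 1, N, 2)
    spec: NetworkSpec
    step: float = 1.0
    memory_length: Optional[int] = None
    meta: dict = field(default_factory=dict)

    @property
    def u1(self) -> np.ndarray:
        """(T+1, N) voltage traces."""
        return self.states[:, :, 0]

    def to_frame(self):
        """Long-format ``time, node, u1, u2`` DataFrame."""
        import pandas as pd

        T, N, _ = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, N),
                "node": np.tile(np.arange(N), T),
                "u1": self.states[:, :, 0].ravel(),
                "u2": self.states[:, :, 1].ravel(),
            }
        )


def build_er_network(
    N: int,
    mean_degree: float,
    seed: int,
    coupling: float = 0.0,
    order_vector: Optional[Sequence[float]] = None,
) -> NetworkSpec:
    """Erdos-Renyi graph with edge probability mean_degree/(N-1).

    Deterministic under a fixed seed.  Isolated nodes (possible at small
    p) are rewired to one uniformly chosen partner so that the
    degree-normalised coupling stays defined; rewired node indices are
    recorded on the spec.
    """
    if N < 2:
        raise ValueError("need at least two nodes")
    p = mean_degree / (N - 1)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"edge probability {p} outside (0, 1]")
    rng = np.random.default_rng(seed)
    A = np.zeros((N, N), dtype=np.int8)
    iu = np.triu_indices(N, 1)
    edges = rng.random(len(iu[0])) < p
    A[iu] = edges
    A += A.T
    rewired = []
    for i in np.where(A.sum(axis=1) == 0)[0]:
        j = rng.integers(N - 1)
        j = j + (j >= i)  # uniform over the other N-1 nodes
        A[i, j] = A[j, i] = 1
        rewired.append(int(i))
    if order_vector is None:
        order_vector = np.ones(N)
    return NetworkSpec(
        N=N,
        adjacency=A,
        coupling=coupling,
        order_vector=np.asarray(order_vector, dtype=float),
        target_mean_degree=mean_degree,
        seed=seed,
        rewired_nodes=tuple(rewired),
    )


def assign_orders(N: int, r: int, s: int, theta: float, phi: float) -> np.ndarray:
    """Order vector: first r nodes at theta, last s nodes at phi."""
    if r + s != N:
        raise ValueError(f"partition r + s = {r + s} != N = {N}")
    if r < 0 or s < 0:
        raise ValueError("partition sizes must be non-negative")
    return np.concatenate([np.full(r, float(theta)), np.full(s, float(phi))])


def rhs_network(
    states: np.ndarray, spec: NetworkSpec, params: MLParams2D, Im: float
) -> np.ndarray:
    """Stacked vector field of the coupled population, shape (N, 2).

    Identical states across nodes zero the coupling term exactly
    (diffusive coupling); W_eps = 0 gives N independent neurons.
    """
    states = np.asarray(states, dtype=float)
    if states.shape != (spec.N, 2):
        raise ValueError(f"states must have shape ({spec.N}, 2)")
    u1 = states[:, 0]
    u2 = states[:, 1]
    g = gating_functions(u1, params)
    du1 = (Im - ionic_current(u1, u2, params)) / params.C
    du2 = params.phi * g.rate * (g.w_inf - u2)
    if spec.coupling != 0.0:
        A = spec.adjacency
        deg = spec.degrees
        du1 = du1 + spec.coupling * (A @ u1 - deg * u1) / deg / params.C
    return np.column_stack([du1, du2])


def simulate_network(
    spec: NetworkSpec,
    params: MLParams2D,
    Im: float,
    x0: np.ndarray,
    n_steps: int,
    step: float = 1.0,
    memory_length: Optional[int] = 500,
) -> NetworkTrajectory:
    """Integrate the coupled population with per-node fractional orders.

    Both state components of node ``i`` inherit that node's order.  The
    memory convolution is evaluated with one weight table per distinct
    order; the default short-memory window of 500 steps keeps the cost at
    O(N T L) and converges to the full-memory run as L grows (pass
    ``memory_length=None`` for full memory).
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (spec.N, 2):
        raise ValueError(f"x0 must have shape ({spec.N}, 2)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    N = spec.N
    L = n_steps if memory_length is None else min(memory_length, n_steps)
    unique = {}
    for o in spec.order_vector:
        if o not in unique:
            unique[o] = kernel_weights(float(o), L).weights
    # per-node weight matrix (N, L) and h^order scales
    W = np.stack([unique[o] for o in spec.order_vector])
    scale = step ** spec.order_vector

    hist = np.empty((n_steps, N, 2))
    states = np.empty((n_steps + 1, N, 2))
    states[0] = x0
    x = x0.copy()
    # overflow surfaces as inf and is converted into a divergence error
    with np.errstate(over="ignore", invalid="ignore"):
        for n in range(1, n_steps + 1):
            f = rhs_network(x, spec, params, Im)
            if not np.all(np.isfinite(f)):
                bad = int(np.where(~np.isfinite(f).all(axis=1))[0][0])
                raise SolverDivergenceError(n - 1, state=("node", bad))
            hist[n - 1] = f
            lo = max(0, n - L)
            m = n - lo
            w = W[:, :m][:, ::-1]                  # (N, m) newest-last reversed
            conv = np.einsum("nm,mnc->nc", w, hist[lo:n])
            x = x0 + scale[:, None] * conv
            if not np.all(np.isfinite(x)):
                bad = int(np.where(~np.isfinite(x).all(axis=1))[0][0])
                raise SolverDivergenceError(n, state=("node", bad))
            states[n] = x
    times = step * np.arange(n_steps + 1)
    return NetworkTrajectory(
        times=times, states=states, spec=spec, step=step, memory_length=memory_length
    )


def _rhs_reduced(x: np.ndarray, spec: ReducedModelSpec) -> np.ndarray:
    """Stacked cluster vector field; clusters are consecutive (u1,u2,u3)."""
    p = spec.params
    k = len(spec.orders)
    x = x.reshape(k, 3)
    out = np.empty_like(x)
    u1 = x[:, 0]
    for c in range(k):
        base = rhs_3d(x[c], p)
        if spec.Im is not None:
            base[0] += (spec.Im - float(p.applied_current(x[c, 2]))) / p.C
        out[c] = base
    # printed coupling pattern: theta <- p_eps (u1_phi - u1_theta),
    # phi <- p0 (u1_theta - u1_phi), gamma <- p1 (u1_gamma - u1_theta)
    out[0, 0] += spec.coupling * spec.p_eps * (u1[1] - u1[0]) / p.C
    out[1, 0] += spec.coupling * spec.p0 * (u1[0] - u1[1]) / p.C
    if k == 3:
        out[2, 0] += spec.coupling * spec.p1 * (u1[2] - u1[0]) / p.C
    return out.ravel()


def simulate_reduced(
    spec: ReducedModelSpec,
    x0: np.ndarray,
    n_steps: int,
    step: float = 1.0,
    memory_length: Optional[int] = None,
) -> Trajectory:
    """Integrate the reduced cluster model.

    State layout is cluster-major: (u1, u2, u3) per cluster; all three
    components of a cluster share that cluster's fractional order.  With
    equal probabilities and identical cluster states the coupling
    vanishes and the clusters evolve as independent slow-fast neurons.
    """
    from .frac_calculus import solve_incommensurate

    k = len(spec.orders)
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != 3 * k:
        raise ValueError(f"x0 must have {3 * k} entries for {k} clusters")
    orders = OrderSpec(orders=tuple(np.repeat(spec.orders, 3)))
    traj = solve_incommensurate(
        lambda x: _rhs_reduced(x, spec),
        orders,
        x0,
        n_steps,
        step=step,
        memory_length=memory_length,
    )
    traj.meta["clusters"] = k
    return traj
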