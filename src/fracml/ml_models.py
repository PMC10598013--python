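"""Morris-Lecar right-hand sides, gating functions, and parameter registry.

Two model families are implemented.  The dimensional two-variable model
(membrane potential u1 in mV-like units, K+ gating u2 in [0,1]) is

.. math::

    C \\dot u_1 = I_m - \\bar I(u_1, u_2), \\qquad
    \\dot u_2 = \\varphi\\, \\ell(u_1) (w_\\infty(u_1) - u_2),

with ionic current
``Ibar = WCa r_inf(u1)(u1 - FCa) + WK u2 (u1 - FK) + WL (u1 - FL)`` and
standard hyperbolic gating

``r_inf = (1 + tanh((u1-F1)/F2))/2``,
``w_inf = (1 + tanh((u1-F3)/F4))/2``,
``ell = cosh((u1-F3)/(2 F4))``.

The dimensionless slow-fast three-variable extension replaces the calcium
driving force by (u1 - 1), lets the applied current and the K+ gate
half-activation depend on a slow recovery variable u3
(``Im(u3) = 0.08 - 0.03 u3``, ``F3(u3) = 0.08 - u3``), and closes the loop
with ``\\dot u_3 = \\theta (u_1 + F_0)``, ``0 < \\theta << 1``.

For the 3D gating rate two typographic readings of the cosh factor
coexist in the source material; the amplitude-scaled one
``cosh(u1 - F3(u3)) / (2 F4)`` is the default because it is the only
reading that reproduces the reported spectral classification of all three
parameter groups (see docs/methods.md), and the textbook argument-scaled
form ``cosh((u1 - F3(u3))/(2 F4))`` stays selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "MLParams2D",
    "MLParams3D",
    "GroupFixture",
    "GatingValues",
    "gating_functions",
    "gating_functions_3d",
    "ionic_current",
    "rhs_2d",
    "rhs_3d",
    "parameter_registry",
    "list_groups",
]


@dataclass(frozen=True)
class MLParams2D:
    """Biophysical constants of the two-variable model (class I or II)."""

    C: float        # membrane capacitance
    WCa: float      # maximal Ca2+ conductance
    WK: float       # maximal K+ conductance
    WL: float       # leak conductance
    FCa: float      # Ca2+ reversal potential
    FK: float       # K+ reversal potential
    FL: float       # leak reversal potential
    F1: float       # Ca2+ gate half-activation
    F2: float       # Ca2+ gate slope
    F3: float       # K+ gate half-activation
    F4: float       # K+ gate slope
    phi: float      # K+ gating rate constant

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if min(self.WCa, self.WK, self.WL) <= 0:
            raise ValueError("conductances must be positive")
        if self.F2 == 0 or self.F4 == 0:
            raise ValueError("gating slopes F2, F4 must be nonzero")
        if self.phi <= 0:
            raise ValueError("gating rate phi must be positive")


@dataclass(frozen=True)
class MLParams3D:
    """Constants of the dimensionless slow-fast three-variable model.

    The applied current follows ``Im(u3) = Im_intercept + Im_slope * u3``
    and the K+ half-activation ``F3(u3) = F3_base - u3``.  ``rate_scaling``
    selects the cosh reading for the gating rate (see module docstring).
    """

    WCa: float
    WK: float
    WL: float
    FCa: float
    FK: float
    FL: float
    F1: float
    F2: float
    F4: float
    phi: float
    F0: float               # slow-variable offset: u1* = -F0
    theta: float            # slow/fast time-scale ratio, in (0, 1)
    C: float = 1.0
    Im_intercept: float = 0.08
    Im_slope: float = -0.03
    F3_base: float = 0.08
    rate_scaling: str = "amplitude"   # or "argument"

    def __post_init__(self):
        if not (0.0 < self.theta < 1.0):
            raise ValueError("time-scale ratio theta must lie in (0, 1)")
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if self.rate_scaling not in ("amplitude", "argument"):
            raise ValueError("rate_scaling must be 'amplitude' or 'argument'")

    def applied_current(self, u3: float) -> float:
        return self.Im_intercept + self.Im_slope * np.asarray(u3, dtype=float)

    def F3(self, u3: float):
        return self.F3_base - np.asarray(u3, dtype=float)


@dataclass(frozen=True)
class GroupFixture:
    """A printed parameter group plus the applied currents studied with it."""

    group_id: str
    model_dim: int
    params: Union[MLParams2D, MLParams3D]
    applied_currents: tuple


class GatingValues(NamedTuple):
    r_inf: float
    w_inf: float
    rate: float  # ell, the voltage-dependent K+ gating rate factor


def gating_functions(u1, params: MLParams2D) -> GatingValues:
    """Steady-state activations and the gating rate of the 2D model."""
    u1 = np.asarray(u1, dtype=float)
    r = 0.5 * (1.0 + np.tanh((u1 - params.F1) / params.F2))
    w = 0.5 * (1.0 + np.tanh((u1 - params.F3) / params.F4))
    ell = np.cosh((u1 - params.F3) / (2.0 * params.F4))
    return GatingValues(r, w, ell)


def gating_functions_3d(u1, u3, params: MLParams3D) -> GatingValues:
    """3D gating: the K+ gate centre slides with the slow variable."""
    u1 = np.asarray(u1, dtype=float)
    F3 = params.F3(u3)
    r = 0.5 * (1.0 + np.tanh((u1 - params.F1) / params.F2))
    w = 0.5 * (1.0 + np.tanh((u1 - F3) / params.F4))
    if params.rate_scaling == "amplitude":
        ell = np.cosh(u1 - F3) / (2.0 * params.F4)
    else:
        ell = np.cosh((u1 - F3) / (2.0 * params.F4))
    return GatingValues(r, w, ell)


def ionic_current(u1, u2, params) -> float:
    """Total ionic current Ibar(u1, u2).

    The calcium driving force is (u1 - FCa) for the dimensional 2D model
    and (u1 - 1) for the dimensionless 3D model; both carry FCa explicitly,
    and the 3D fixtures set FCa = 1 so the two readings coincide there.
    """
    u1 = np.asarray(u1, dtype=float)
    if isinstance(params, MLParams3D):
        r = 0.5 * (1.0 + np.tanh((u1 - params.F1) / params.F2))
        drive = u1 - 1.0
    else:
        r = gating_functions(u1, params).r_inf
        drive = u1 - params.FCa
    return (
        params.WCa * r * drive
        + params.WK * np.asarray(u2, dtype=float) * (u1 - params.FK)
        + params.WL * (u1 - params.FL)
    )


def rhs_2d(state, params: MLParams2D, Im: float) -> np.ndarray:
    """Vector field of the 2D model; first component already divided by C."""
    u1, u2 = state
    g = gating_functions(u1, params)
    du1 = (Im - ionic_current(u1, u2, params)) / params.C
    du2 = params.phi * g.rate * (g.w_inf - u2)
    return np.array([du1, du2])


def rhs_3d(state, params: MLParams3D) -> np.ndarray:
    """Vector field of the slow-fast 3D model."""
    u1, u2, u3 = state
    g = gating_functions_3d(u1, u3, params)
    du1 = (params.applied_current(u3) - ionic_current(u1, u2, params)) / params.C
    du2 = params.phi * g.rate * (g.w_inf - u2)
    du3 = params.theta * (u1 + params.F0)
    return np.array([du1, du2, du3])


def _load_registry() -> dict:
    with resources.files("fracml.data").joinpath("groups.json").open() as fh:
        return json.load(fh)


_REGISTRY_CACHE: dict = {}


def list_groups() -> list:
    """Valid (group_id, model_dim) pairs."""
    reg = _load_registry()
    out = []
    for dim_key in ("2d", "3d"):
        out.extend((g, int(dim_key[0])) for g in reg[dim_key])
    return out


def parameter_registry(group_id: str, model_dim: int) -> GroupFixture:
    """Return the printed constants of a parameter group.

    2D: group "i" is the C=20 class-I set (studied at Im in {40, 45}), and
    group "ii" is the class-II variant obtained by overriding
    WCa=4.4, F3=2, F4=30, phi=0.04 (studied at Im=100).  3D: groups
    "i"/"ii"/"iii" are the three dimensionless slow-fast sets.
    """
    key = (group_id, model_dim)
    if key in _REGISTRY_CACHE:
        return _REGISTRY_CACHE[key]
    reg = _load_registry()
    dim_key = f"{model_dim}d"
    if dim_key not in reg or group_id not in reg[dim_key]:
        raise KeyError(f"unknown parameter group {group_id!r} for the {model_dim}D model")
    entry = reg[dim_key][group_id]
    currents = tuple(entry.pop("applied_currents", ()))
    if model_dim == 2:
        params = MLParams2D(**entry)
    else:
        params = MLParams3D(**entry)
    fx = GroupFixture(
        group_id=group_id, model_dim=model_dim, params=params, applied_currents=currents
    )
    _REGISTRY_CACHE[key] = fx
    return fx


def with_rate_scaling(params: MLParams3D, rate_scaling: str) -> MLParams3D:
    """Copy of a 3D parameter set with the other cosh reading."""
    return replace(params, rate_scaling=rate_scaling)
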