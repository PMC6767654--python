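"""Subarachnoid-space (SAS) tracer boundary model.

The tracer (amount n0 = 0.5 mmol injected intrathecally) spreads upward in
the CSF surrounding the brain.  The Dirichlet concentration imposed on the
SAS interface is

    g(t, x) = c_CSF(t) * h(t, x),
    h(t, x) = 0.5 + arctan(-a (x3 - z0 - u_x3 t)) / pi,

a smooth step travelling upward at speed ``u_x3`` whose half-height front
starts at z0.  The mean SAS concentration c_CSF(t) follows from mass
conservation: parenchymal content + c_CSF * V_CSF + drained amount = n0,
so c_CSF is obtained by rearrangement and falls as tracer enters the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BoundaryParams:
    """SAS boundary-model constants (SI units).

    a : concentration-gradient steepness of the front, 1/m
    z0 : front position at t = 0 (absolute z-coordinate), m
    u_x3 : upward front speed in the SAS, m/s
    n0 : injected tracer amount, mol (0.5 mmol)
    V_CSF : CSF volume of SAS + ventricles, m^3 (140 mL)
    """

    a: float = 20.0
    z0: float = -0.2
    u_x3: float = 1.5e-5
    n0: float = 5e-4
    V_CSF: float = 1.4e-4

    def __post_init__(self):
        if self.a <= 0 or self.u_x3 < 0 or self.n0 <= 0 or self.V_CSF <= 0:
            raise ValueError("boundary parameters must be positive (u_x3 >= 0)")

    @property
    def initial_csf_concentration(self) -> float:
        """c_CSF(0) = n0 / V_CSF, mol/m^3 (3.57 for the defaults)."""
        return self.n0 / self.V_CSF


@dataclass
class TracerBudget:
    """State of the tracer mass balance at one instant.

    parenchymal_amount : integral of c over the parenchyma, mol
    drained_amount : cumulative drained amount (trapezoidal in time), mol
    c_csf : current mean SAS concentration, mol/m^3
    """

    parenchymal_amount: float = 0.0
    drained_amount: float = 0.0
    c_csf: float = 0.0


def spatial_profile_h(t, x3, params: BoundaryParams = BoundaryParams()):
    """Spatial step profile h(t, x3), strictly in (0, 1), decreasing in x3."""
    t = np.asarray(t, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    return 0.5 + np.arctan(-params.a * (x3 - params.z0 - params.u_x3 * t)) / np.pi


def update_csf_concentration(budget: TracerBudget,
                             params: BoundaryParams = BoundaryParams(),
                             tolerance: float = 0.02) -> float:
    """SAS concentration from the rearranged conservation identity.

    c_CSF = (n0 - parenchymal - drained) / V_CSF, floored at 0.  A numerator
    more negative than ``tolerance * n0`` signals a conservation breach
    upstream and raises.
    """
    remaining = params.n0 - budget.parenchymal_amount - budget.drained_amount
    if remaining < -tolerance * params.n0:
        raise ValueError(
            f"tracer budget breach: parenchymal + drained exceeds n0 by "
            f"{-remaining / params.n0:.2%}")
    c = max(remaining, 0.0) / params.V_CSF
    budget.c_csf = c
    return c


def boundary_value_g(t, x, c_csf: float, params: BoundaryParams = BoundaryParams()):
    """Dirichlet value g = c_CSF * h(t, x3) on the SAS interface.

    ``x`` is an (n, 3) array of points (or a single 3-vector).
    """
    if c_csf < 0:
        raise ValueError("c_csf must be non-negative")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return c_csf * spatial_profile_h(t, x[..., 2], params)
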