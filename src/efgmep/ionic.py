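"""Membrane (reaction) models and their analytic references.

Two reaction terms for the monodomain equation:

* a cubic polynomial ionic current I_ion = g v (1 - v/v_th)(1 - v/v_p), for
  which the 1D cable equation has a closed-form traveling-wave conduction
  velocity — the verification workhorse; potentials are handled as deviations
  from rest;
* a modified FitzHugh-Nagumo (FHN) model with a dimensionless excitation
  variable v in [0, 1] and a recovery current, time in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from efgmep.errors import EfgmError, InvalidArgumentError

__all__ = [
    "CubicIonicParams",
    "FHNParams",
    "NoPropagationError",
    "cubic_current",
    "analytic_velocity",
    "fhn_rhs",
]


class NoPropagationError(EfgmError):
    """The cubic model admits no traveling wave (S = v_p/(2 v_th) - 1 <= 0)."""


@dataclass
class CubicIonicParams:
    """Cubic ionic current parameters.

    Potentials are deviations from the resting potential: with absolute rest
    -85 mV, threshold -75 mV and plateau +15 mV, the deviations are
    v_th = 10 mV and v_p = 100 mV (the packaged defaults).

    g : membrane conductance, mS/mm^2
    C_m : membrane capacitance, uF/mm^2
    A_m : membrane surface-to-volume ratio, 1/mm
    v_rest : absolute resting potential, mV (bookkeeping only)
    """

    g: float = 0.004
    v_th: float = 10.0
    v_p: float = 100.0
    C_m: float = 0.01
    A_m: float = 200.0
    v_rest: float = -85.0

    def __post_init__(self):
        if not (0.0 < self.v_th < self.v_p):
            raise InvalidArgumentError("require 0 < v_th < v_p (deviations from rest)")
        if min(self.g, self.C_m, self.A_m) <= 0:
            raise InvalidArgumentError("g, C_m, A_m must be > 0")


@dataclass
class FHNParams:
    """Modified FitzHugh-Nagumo parameters (dimensionless shape parameters,
    diffusivities sigma_f/sigma_cf in mm^2/ms; time in ms)."""

    a: float = 0.13
    b: float = 0.013
    c1: float = 0.26
    c2: float = 0.1
    d: float = 1.0
    sigma_f: float = 4.0
    sigma_cf: float = 1.0


def cubic_current(v_m, params: CubicIonicParams):
    """Ionic current I_ion = g v (1 - v/v_th)(1 - v/v_p), uA/mm^2.

    Roots at v = 0 (rest), v_th and v_p; positive (repolarizing) below
    threshold, negative (depolarizing) between threshold and plateau.
    """
    v = np.asarray(v_m, dtype=float)
    out = params.g * v * (1.0 - v / params.v_th) * (1.0 - v / params.v_p)
    return float(out) if out.ndim == 0 else out


def analytic_velocity(params: CubicIonicParams, sigma: float) -> float:
    """Closed-form conduction velocity of the 1D cable, mm/ms.

    The monodomain cable with the cubic current is, after scaling, the
    bistable (Nagumo) equation; its unique traveling front has speed

        gamma = sqrt(g sigma / (A_m C_m^2)) * S / sqrt(S + 1),
        S = v_p / (2 v_th) - 1,

    which requires S > 0 (plateau more than twice the threshold deviation).
    The sqrt(sigma) scaling law holds exactly.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    s = params.v_p / (2.0 * params.v_th) - 1.0
    if s <= 0:
        raise NoPropagationError(
            f"S = v_p/(2 v_th) - 1 = {s:.3g} <= 0: no traveling wave"
        )
    return float(
        np.sqrt(params.g * sigma / (params.A_m * params.C_m**2)) * s / np.sqrt(s + 1.0)
    )


def fhn_rhs(v_m, i_ion, params: FHNParams):
    """FHN reaction terms: (dv_m/dt excitation part, dI_ion/dt).

    f(v, I) = c1 v (v - a)(1 - v) - c2 v I;  dI/dt = b (v - d I).
    Rest (0, 0) is an equilibrium; v = a is the excitation threshold.
    """
    v = np.asarray(v_m, dtype=float)
    w = np.asarray(i_ion, dtype=float)
    f = params.c1 * v * (v - params.a) * (1.0 - v) - params.c2 * v * w
    dw = params.b * (v - params.d * w)
    if f.ndim == 0:
        return float(f), float(dw)
    return f, dw
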