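"""Radius-dependent effective blood viscosity (Fåhræus–Lindqvist effect).

Apparent blood viscosity drops in small vessels because red cells migrate to
the axis and the cell-depleted marginal layer lubricates the flow.  We use the
empirical in-vitro law of Pries, Neuhaus & Gaehtgens (Am J Physiol 1992),
expressed relative to plasma viscosity:

    eta_45(d) = 220 exp(-1.3 d) + 3.2 - 2.44 exp(-0.06 d^0.645)
    C(d)      = (0.8 + exp(-0.075 d)) (-1 + 1/(1 + 1e-11 d^12))
                + 1/(1 + 1e-11 d^12)
    mu_rel(d, H) = 1 + (eta_45(d) - 1) * ((1 - H)^C - 1) / ((1 - 0.45)^C - 1)

with the tube diameter ``d`` in micrometers and discharge hematocrit ``H``.
The law is decreasing from the large-vessel plateau down to a minimum near
capillary diameters (~7 um) and rises again below that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ViscosityModel:
    """Parameters of the relative-viscosity law.

    hematocrit : discharge hematocrit (dimensionless, in (0, 1)).
    """

    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")


def effective_viscosity(radius_mm, model: ViscosityModel = ViscosityModel()):
    """Relative effective viscosity mu_rel for a vessel of given radius (mm).

    Accepts scalars or arrays; raises on non-positive radii.
    """
    r = np.asarray(radius_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    d = 2.0e3 * r  # diameter in micrometers
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    # 1e-11 d^12 overflows float64 past d ~ 1e6 um; clamp the switch term
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + s) + s
    h = ViscosityModel.__dataclass_fields__  # noqa: F841  (keep import-light)
    hd = model.hematocrit
    mu = 1.0 + (eta45 - 1.0) * ((1.0 - hd) ** c - 1.0) / (0.55**c - 1.0)
    return mu if mu.ndim else float(mu)


def poiseuille_resistance(radius_mm, length_mm, model: ViscosityModel = ViscosityModel()):
    """Hydraulic resistance ~ mu_rel L / r^4 (relative units).

    Diagnostic quantity: with the effective-permeability convention used in
    the porous-medium solver, only relative resistances matter.
    """
    r = np.asarray(radius_mm, dtype=float)
    length = np.asarray(length_mm, dtype=float)
    return 8.0 / np.pi * effective_viscosity(r, model) * length / r**4
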