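"""Four-subspace PBPK exchange, metabolization and RKF45 integration.

The homogenized hepatic space holds compound in four subspaces — red blood
cells (rbc), plasma (pls), interstitium (int) and liver cells (cell) — with
concentrations expressed per subspace volume (µmol/L).  Exchange across each
interface (a, b) is passive and gradient-driven:

    dc_a/dt -= (P_ab / f_a) (c_a - K_ab c_b)
    dc_b/dt += (P_ab / f_b) (c_a - K_ab c_b)

so the flux vanishes exactly at the equilibrium c_a = K_ab c_b and the tissue
mass  sum_i f_i c_i  is conserved.  P_ab is a volume-normalized exchange rate
in 1/min; K_ab is a dimensionless partition coefficient.  Metabolization is a
pure sink on the cellular subspace, either first order or Michaelis-Menten.

All kinetics here use minutes; the advection layers use seconds and convert
at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

SUBSPACES = ("rbc", "pls", "int", "cell")
_IDX = {name: i for i, name in enumerate(SUBSPACES)}


@dataclass
class VolumeFractions:
    """Volume fractions of the five HHS subspaces (scalars or voxel arrays).

    The sinusoidal subspace is the blood part, f_sin = f_rbc + f_pls; the
    rest subspace (resolved vessels, bile ducts) carries no compound.
    """

    rbc: float | np.ndarray = 0.09
    pls: float | np.ndarray = 0.13
    int_: float | np.ndarray = 0.16
    cell: float | np.ndarray = 0.55
    rest: float | np.ndarray = 0.07

    def __post_init__(self) -> None:
        total = self.rbc + self.pls + self.int_ + self.cell + self.rest
        if np.any(np.abs(np.asarray(total) - 1.0) > 1e-12):
            raise ValueError("volume fractions must sum to 1")
        for v in (self.rbc, self.pls, self.int_, self.cell, self.rest):
            if np.any(np.asarray(v) < 0):
                raise ValueError("volume fractions must be nonnegative")

    @property
    def sin(self):
        return self.rbc + self.pls

    @property
    def hematocrit(self):
        return self.rbc / self.sin

    def as_array(self) -> np.ndarray:
        """Stack (4, ...) in subspace order rbc, pls, int, cell."""
        arrs = np.broadcast_arrays(
            np.asarray(self.rbc, dtype=float),
            np.asarray(self.pls, dtype=float),
            np.asarray(self.int_, dtype=float),
            np.asarray(self.cell, dtype=float),
        )
        return np.stack(arrs)


@dataclass(frozen=True)
class Interface:
    """Passive exchange interface: equilibrium c_a = K · c_b, rate P (1/min)."""

    a: str
    b: str
    partition: float | np.ndarray  # K_ab
    permeability: float | np.ndarray  # P_ab, 1/min

    def __post_init__(self) -> None:
        if self.a not in _IDX or self.b not in _IDX or self.a == self.b:
            raise ValueError("interface must connect two distinct subspaces")
        if np.any(np.asarray(self.partition) <= 0):
            raise ValueError("partition coefficient must be positive")
        if np.any(np.asarray(self.permeability) < 0):
            raise ValueError("permeability must be nonnegative")


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical and exchange parameters of one compound.

    ``k_lip`` is the compound-specific lipid-affinity constant entering the
    steatotic cellular partition coefficient.
    """

    name: str
    mw: float  # g/mol
    logp: float
    fu: float  # fraction unbound in plasma
    interfaces: tuple[Interface, ...]
    k_lip: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fu <= 1.0:
            raise ValueError("fraction unbound must lie in [0, 1]")
        if self.k_lip < 0:
            raise ValueError("k_lip must be nonnegative")

    @property
    def k_rbc_pls(self) -> float:
        for itf in self.interfaces:
            if {itf.a, itf.b} == {"rbc", "pls"}:
                k = np.asarray(itf.partition)
                return float(k if itf.a == "rbc" else 1.0 / k)
        return 1.0

    @property
    def k_cell(self):
        """Partition coefficient of the cell-side interface (c_cell = K c_int)."""
        for itf in self.interfaces:
            if itf.a == "cell":
                return itf.partition
        raise ValueError(f"compound {self.name} has no cellular interface")

    def with_kcell(self, k_cell) -> "CompoundParams":
        """Replace the cellular partition coefficient (scalar or per-voxel)."""
        new = tuple(
            replace(i, partition=k_cell) if i.a == "cell" else i
            for i in self.interfaces
        )
        return replace(self, interfaces=new)

    def with_cell_permeability(self, p) -> "CompoundParams":
        new = tuple(
            replace(i, permeability=p) if "cell" in (i.a, i.b) else i
            for i in self.interfaces
        )
        return replace(self, interfaces=new)


@dataclass(frozen=True)
class MetabolismParams:
    """Cellular metabolization sink: none, first-order, or Michaelis-Menten."""

    mode: str = "none"  # none | linear | michaelis_menten
    k_met: float = 0.0  # 1/min
    v_max: float = 0.0  # µmol/L/min
    k_m: float = 1.0  # µmol/L

    def __post_init__(self) -> None:
        if self.mode not in ("none", "linear", "michaelis_menten"):
            raise ValueError(f"unknown metabolism mode {self.mode!r}")
        if self.mode == "linear" and self.k_met <= 0:
            raise ValueError("linear metabolism needs k_met > 0")
        if self.mode == "michaelis_menten" and (self.v_max <= 0 or self.k_m <= 0):
            raise ValueError("MM metabolism needs positive V_max and K_m")


def metabolization_rate(c_cell, params: MetabolismParams):
    """Sink rate on the cellular concentration (µmol/L/min, >= 0)."""
    c = np.asarray(c_cell, dtype=float)
    if np.any(c < 0):
        raise ValueError("cellular concentration must be nonnegative")
    if params.mode == "none":
        return np.zeros_like(c) if c.ndim else 0.0
    if params.mode == "linear":
        out = params.k_met * c
    else:
        out = params.v_max * c / (params.k_m + c)
    return out if c.ndim else float(out)


def exchange_rhs(
    c: np.ndarray, params: CompoundParams, f: VolumeFractions
) -> np.ndarray:
    """Passive-exchange right-hand side dc/dt (µmol/L/min), linear in c.

    ``c`` is stacked (4, ...) in subspace order.  Raises when an interface
    with nonzero permeability touches a subspace of zero volume fraction.
    """
    c = np.asarray(c, dtype=float)
    farr = f.as_array()
    out = np.zeros(c.shape, dtype=float)
    for itf in params.interfaces:
        ia, ib = _IDX[itf.a], _IDX[itf.b]
        P = np.asarray(itf.permeability, dtype=float)
        if np.all(P == 0):
            continue
        for i in (ia, ib):
            if np.any((np.asarray(farr[i]) == 0) & (P > 0)):
                raise ValueError(
                    f"interface {itf.a}-{itf.b} active where f_{SUBSPACES[i]} = 0"
                )
        grad = c[ia] - np.asarray(itf.partition) * c[ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            ja = np.where(P > 0, P / np.where(farr[ia] == 0, 1.0, farr[ia]), 0.0)
            jb = np.where(P > 0, P / np.where(farr[ib] == 0, 1.0, farr[ib]), 0.0)
        out[ia] -= ja * grad
        out[ib] += jb * grad
    return out


def pbpk_rhs(
    c: np.ndarray,
    params: CompoundParams,
    met: MetabolismParams,
    f: VolumeFractions,
    met_scale=1.0,
) -> np.ndarray:
    """Exchange plus cellular metabolization sink (µmol/L/min).

    ``met_scale`` multiplies the metabolization rate pointwise (0 in necrotic
    voxels, 1 elsewhere).
    """
    out = exchange_rhs(c, params, f)
    out[_IDX["cell"]] -= met_scale * metabolization_rate(
        np.maximum(c[_IDX["cell"]], 0.0), met
    )
    return out


# --------------------------------------------------------------------- RKF45
_A = [
    (),
    (1 / 4,),
    (3 / 32, 9 / 32),
    (1932 / 2197, -7200 / 2197, 7296 / 2197),
    (439 / 216, -8.0, 3680 / 513, -845 / 4104),
    (-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40),
]
_C = (0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2)
_B4 = (25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0)
_B5 = (16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55)


def rkf45_integrate(
    fun: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_span: tuple[float, float],
    tol: float = 1e-8,
    h0: float | None = None,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Adaptive Runge-Kutta-Fehlberg 4(5) integration of y' = fun(t, y).

    The classical Fehlberg embedded pair: the difference of the 4th- and
    5th-order solutions provides the local error estimate, the step size is
    adapted so the scaled local error stays below ``tol`` per step, and the
    5th-order solution is propagated (local extrapolation).  Works on arrays
    of any shape (each element integrated with a shared step size).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t0, t1 = float(t_span[0]), float(t_span[1])
    y = np.array(y0, dtype=float)
    span = t1 - t0
    if span == 0:
        return y
    if span < 0:
        raise ValueError("t_span must be increasing")
    h = min(0.1 * span, span) if h0 is None else min(h0, span)
    t = t0
    for _ in range(max_steps):
        if t >= t1:
            return y
        h = min(h, t1 - t)
        if h < 1e-14 * span:
            raise RuntimeError(
                f"RKF45 step size underflow at t={t:.6g} (state max "
                f"{np.max(np.abs(y)):.3g})"
            )
        k = []
        for s in range(6):
            ys = y if s == 0 else y + h * sum(a * ki for a, ki in zip(_A[s], k))
            k.append(fun(t + _C[s] * h, ys))
        y4 = y + h * sum(b * ki for b, ki in zip(_B4, k))
        y5 = y + h * sum(b * ki for b, ki in zip(_B5, k))
        scale = tol * (1.0 + np.max(np.abs(y)))
        err = float(np.max(np.abs(y5 - y4)))
        if err <= scale:
            t += h
            y = y5  # local extrapolation: propagate the 5th-order solution
            factor = 5.0 if err == 0 else min(5.0, 0.9 * (scale / err) ** 0.2)
            h *= factor
        else:
            h *= max(0.1, 0.9 * (scale / err) ** 0.25)
    raise RuntimeError("RKF45 exceeded the step budget")


def integrate_pointwise(
    c: np.ndarray,
    params: CompoundParams,
    met: MetabolismParams,
    f: VolumeFractions,
    dt_min: float,
    tol: float = 1e-8,
    met_scale=1.0,
) -> np.ndarray:
    """Advance the pointwise PBPK ODE by dt (minutes) at every grid node.

    The same embedded RKF45 pair is applied to the stacked state of all
    nodes; the shared adaptive step is controlled by the worst local error.
    """

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return pbpk_rhs(y, params, met, f, met_scale)

    return rkf45_integrate(rhs, c, (0.0, dt_min), tol=tol)


def wellstirred_reference(
    q_liv: float,
    v_liv: float,
    f: VolumeFractions,
    params: CompoundParams,
    met: MetabolismParams,
    inflow,
    duration_s: float,
    dt_out_s: float,
    tol: float = 1e-8,
) -> dict:
    """Well-stirred liver compartment model run head-to-head with the
    spatial simulator.

    Perfusion-limited inflow/outflow at total flow ``q_liv`` (mm^3/s) through
    the sinusoidal subspaces plus the identical exchange/metabolization
    kinetics.  Returns the outflow blood concentration series and ledger
    totals (nmol).
    """
    k_perf = 60.0 * q_liv / (v_liv * float(np.asarray(f.sin)))  # 1/min
    n_out = int(round(duration_s / dt_out_s))
    times = np.arange(n_out + 1) * dt_out_s
    state = np.zeros(5)  # c_rbc, c_pls, c_int, c_cell, metabolized density
    c_out = np.zeros(n_out + 1)
    inflow_mass = 0.0
    outflow_mass = 0.0
    farr = f.as_array()

    def rhs_factory(c_in_rbc: float, c_in_pls: float):
        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            c = y[:4]
            d = pbpk_rhs(c, params, met, f)
            dm = float(farr[3]) * metabolization_rate(max(c[3], 0.0), met)
            d = np.concatenate([d, [dm]])
            d[0] += k_perf * (c_in_rbc - c[0])
            d[1] += k_perf * (c_in_pls - c[1])
            return d

        return rhs

    h_rbc = float(np.asarray(f.hematocrit))
    for i in range(n_out):
        t = times[i]
        cin_rbc, cin_pls = inflow.phase_concentrations(t)
        rhs = rhs_factory(cin_rbc, cin_pls)
        # trapezoid on the perfusion fluxes over the output interval
        out0 = h_rbc * state[0] + (1 - h_rbc) * state[1]
        in_blood = h_rbc * cin_rbc + (1 - h_rbc) * cin_pls
        state = rkf45_integrate(
            rhs, state, (0.0, dt_out_s / 60.0), tol=tol,
            h0=min(0.1 * dt_out_s / 60.0, 1.0 / 60.0),
        )
        state[:4] = np.maximum(state[:4], 0.0)
        out1 = h_rbc * state[0] + (1 - h_rbc) * state[1]
        c_out[i + 1] = out1
        inflow_mass += q_liv * in_blood * dt_out_s
        outflow_mass += q_liv * 0.5 * (out0 + out1) * dt_out_s
    stored = float(v_liv * float(np.dot(farr.astype(float), state[:4])))
    return {
        "times": times,
        "c_out": c_out,
        "inflow_mass": inflow_mass,
        "outflow_mass": outflow_mass,
        "stored_mass": stored,
        "metabolized_mass": float(v_liv * state[4]),
        "state": state,
    }
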