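"""Deterministic synthetic study fixtures.

Everything the simulator needs can be generated here without external data:
an ellipsoidal two-lobe organ mask, CCO-grown supplying/draining trees, and a
synthetic compound set (an inert non-exchanging reference, a lipophilic
tracer, a linearly cleared drug and a Michaelis–Menten drug).  The compound
parameters are plausible synthetic defaults for a mouse-scale liver, not
literature values; they are the fixed study conditions for the test suite.

The standard fixture is a desk-scale analogue of a production setup: a
~800 mm^3 ellipsoid at 0.5 mm grid spacing with 64-leaf trees.
"""

from __future__ import annotations

import functools
import hashlib

from .geometry.mask import OrganMask, generate_synthetic_mask
from .geometry.tree import VascularTree, dyadic_tree, tree_to_json
from .kinetics import CompoundParams, Interface, MetabolismParams, VolumeFractions
from .simulator import PathologySpec, SimulationConfig, build_geometry
from .vascular import InflowProfile

#: default subspace volume fractions (mouse liver scale)
DEFAULT_FRACTIONS = VolumeFractions(rbc=0.09, pls=0.13, int_=0.16, cell=0.55, rest=0.07)

#: total hepatic perfusion, mm^3/s (~1.8 mL/min, mouse scale)
DEFAULT_Q_LIV = 30.0

#: default per-lobe steatosis lipid ranges (label -> (lo, hi)); the
#: left-lateral-like lobe 1 accumulates far more lipid than the rest
DEFAULT_STEATOSIS_RANGES = {1: (0.30, 0.70), 2: (0.05, 0.25)}

#: default necrotic volume fraction
DEFAULT_NECROSIS_GAMMA = 0.2


def default_compounds() -> dict[str, tuple[CompoundParams, MetabolismParams]]:
    """Synthetic default compound set (name -> (compound, metabolism)).

    - ``inert``: non-exchanging, non-metabolized — the mass-balance reference.
    - ``tracer``: lipophilic dye with passive exchange only (CFDA-SE-like role).
    - ``linear_drug``: passive exchange + first-order clearance.
    - ``mm_drug``: passive exchange + Michaelis-Menten clearance.
    """
    none = MetabolismParams()

    def chain(k_cell: float, p_cell: float) -> tuple[Interface, ...]:
        return (
            Interface("rbc", "pls", partition=0.7, permeability=20.0),
            Interface("pls", "int", partition=0.9, permeability=6.0),
            Interface("cell", "int", partition=k_cell, permeability=p_cell),
        )

    inert = CompoundParams(
        name="inert", mw=500.0, logp=0.0, fu=1.0,
        interfaces=(
            Interface("rbc", "pls", partition=1.0, permeability=0.0),
        ),
        k_lip=0.0,
    )
    tracer = CompoundParams(
        name="tracer", mw=557.0, logp=3.0, fu=0.1,
        interfaces=chain(k_cell=8.0, p_cell=2.0), k_lip=40.0,
    )
    linear_drug = CompoundParams(
        name="linear_drug", mw=843.0, logp=1.5, fu=0.6,
        interfaces=chain(k_cell=15.0, p_cell=2.0), k_lip=60.0,
    )
    mm_drug = CompoundParams(
        name="mm_drug", mw=326.0, logp=2.5, fu=0.03,
        interfaces=chain(k_cell=5.0, p_cell=3.0), k_lip=50.0,
    )
    return {
        "inert": (inert, none),
        "tracer": (tracer, none),
        "linear_drug": (linear_drug, MetabolismParams(mode="linear", k_met=0.05)),
        # K_m of the order of the cellular concentrations reached during the
        # bolus, so the kinetics operate in the mixed (not purely zero-order)
        # regime; intrinsic clearance V_max/K_m = 0.4 /min
        "mm_drug": (mm_drug, MetabolismParams(mode="michaelis_menten",
                                              v_max=40.0, k_m=100.0)),
    }


def standard_inflow(compound: CompoundParams,
                    fractions: VolumeFractions = DEFAULT_FRACTIONS,
                    concentration: float = 100.0,
                    duration: float = 10.0) -> InflowProfile:
    """Square bolus: 100 µmol/L whole blood for 10 s, phase-equilibrated."""
    import numpy as np

    return InflowProfile.plug(
        concentration, duration,
        k_rbc_pls=compound.k_rbc_pls,
        hematocrit=float(np.asarray(fractions.hematocrit)),
    )


@functools.lru_cache(maxsize=4)
def _standard_geometry(n_leaves: int = 64) -> tuple[OrganMask, VascularTree, VascularTree]:
    cfg = SimulationConfig(n_leaves=n_leaves, fractions=DEFAULT_FRACTIONS,
                           q_liv=DEFAULT_Q_LIV)
    return build_geometry(cfg)


def standard_fixture(n_leaves: int = 64) -> dict:
    """The acceptance-test substrate: mask, flow-assigned 64-leaf trees, and
    the synthetic compound set.  Deterministic; cached per process."""
    mask, svs, dvs = _standard_geometry(n_leaves)
    return {
        "mask": mask,
        "svs": svs,
        "dvs": dvs,
        "fractions": DEFAULT_FRACTIONS,
        "q_liv": DEFAULT_Q_LIV,
        "compounds": default_compounds(),
    }


def standard_config(
    compound_name: str = "tracer",
    pathology: PathologySpec | None = None,
    n_leaves: int = 64,
    duration: float = 60.0,
    dt: float = 0.5,
    **overrides,
) -> SimulationConfig:
    """Ready-to-run configuration on the standard fixture geometry."""
    fx = standard_fixture(n_leaves)
    compound, met = fx["compounds"][compound_name]
    cfg = SimulationConfig(
        mask=fx["mask"], svs=fx["svs"], dvs=fx["dvs"],
        q_liv=fx["q_liv"], fractions=fx["fractions"],
        compound=compound, metabolism=met,
        inflow=standard_inflow(compound),
        pathology=pathology or PathologySpec(),
        dt=dt, duration=duration, n_leaves=n_leaves,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def steatosis_spec(mode: str, seed: int = 7) -> PathologySpec:
    return PathologySpec(steatosis_mode=mode,
                         lobe_ranges=dict(DEFAULT_STEATOSIS_RANGES),
                         steatosis_seed=seed)


def necrosis_spec(gamma: float = DEFAULT_NECROSIS_GAMMA) -> PathologySpec:
    return PathologySpec(necrosis_gamma=gamma)


#: first-order clearance used to generate synthetic calibration truth data
CALIBRATION_K_TRUE = 0.3  # 1/min


@functools.lru_cache(maxsize=4)
def small_geometry(n_leaves: int = 8) -> tuple[OrganMask, VascularTree, VascularTree]:
    """A fast miniature geometry for parameter-recovery loops.

    At 8 leaves each terminal edge supplies a large tissue territory, so the
    terminal radius is set accordingly (0.25 mm) to keep intravascular
    velocities — and hence Courant sub-step counts — physiological.
    """
    cfg = SimulationConfig(
        half_axes=(6.0, 5.0, 4.0), spacing=1.0, n_leaves=n_leaves, r_leaf=0.25,
        q_liv=DEFAULT_Q_LIV, fractions=DEFAULT_FRACTIONS,
    )
    return build_geometry(cfg)


def small_config(compound_name: str = "linear_drug", duration: float = 120.0,
                 dt: float = 1.0, **overrides) -> SimulationConfig:
    """Calibration-scale run: a 2-minute window covering uptake and washout,
    so the outflow tail is informative about the clearance rate."""
    mask, svs, dvs = small_geometry()
    compound, met = default_compounds()[compound_name]
    cfg = SimulationConfig(
        mask=mask, svs=svs, dvs=dvs, half_axes=(6.0, 5.0, 4.0), spacing=1.0,
        r_leaf=0.25, q_liv=DEFAULT_Q_LIV, fractions=DEFAULT_FRACTIONS,
        compound=compound, metabolism=met, inflow=standard_inflow(compound),
        dt=dt, duration=duration, rkf45_tol=1e-7,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def dyadic_test_tree(depth: int, edge_length: float = 2.0, r_leaf: float = 0.1,
                     **kw) -> VascularTree:
    """Symmetric binary tree with analytic transit times (see geometry)."""
    return dyadic_tree(depth, edge_length=edge_length, r_leaf=r_leaf, **kw)


def fixture_digest(n_leaves: int = 64) -> str:
    """SHA-256 of the serialized standard fixture (determinism check)."""
    fx = standard_fixture(n_leaves)
    hasher = hashlib.sha256()
    hasher.update(fx["mask"].occupancy.tobytes())
    hasher.update(fx["mask"].lobe_label.astype("int16").tobytes())
    hasher.update(tree_to_json(fx["svs"]).encode())
    hasher.update(tree_to_json(fx["dvs"]).encode())
    return hasher.hexdigest()
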