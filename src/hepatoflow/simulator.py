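"""Operator-split first-pass perfusion simulator.

Per macro time step, in this order:

1. advection through the supplying vascular system (Courant sub-steps),
2. 3D advection in the homogenized hepatic space, with the supplying
   terminal-edge outflow as line sources and the draining-terminal
   neighborhood withdrawals as sinks,
3. pointwise PBPK exchange + metabolization (adaptive RKF45 per grid node),
4. advection through the draining vascular system, its terminal edges fed by
   the neighborhood-average concentrations (exactly the mass withdrawn).

Every phase posts to a mass ledger; the closure
inflow = outflow + stored + metabolized is audited at every output time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .darcy import build_line_sources, solve_pressure, velocity_from_pressure
from .geometry.cco import cco_extend
from .geometry.mask import OrganMask, generate_synthetic_mask
from .geometry.tree import (
    DRAINING,
    SUPPLYING,
    VascularTree,
    assign_flows,
    prune_and_contract,
)
from .hhs import (
    HHSAdvection,
    SubspaceField,
    neighborhood_average,
    neighborhood_voxels,
    rasterize_segment,
)
from .kinetics import (
    CompoundParams,
    MetabolismParams,
    VolumeFractions,
    metabolization_rate,
    pbpk_rhs,
    rkf45_integrate,
)
from .pathology import (
    apply_necrosis,
    make_steatosis_field,
    necrosis_mask,
    steatotic_kcell,
)
from .vascular import InflowProfile, TreeAdvectionSystem


@dataclass
class PathologySpec:
    """Optional pathophysiological state for a run."""

    steatosis_mode: str | None = None  # None | homogeneous | heterogeneous
    lobe_ranges: dict | None = None  # lobe label -> (lo, hi)
    coarsening: int = 4
    steatosis_seed: int = 7
    necrosis_gamma: float = 0.0


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one single-compound run."""

    # organ geometry (either a prebuilt mask or ellipsoid parameters)
    mask: OrganMask | None = None
    half_axes: tuple[float, float, float] = (8.0, 6.0, 4.0)
    spacing: float = 0.5
    lobe_split: tuple[int, float] = (1, 1.5)
    # vascular trees (either prebuilt or CCO-grown)
    svs: VascularTree | None = None
    dvs: VascularTree | None = None
    n_leaves: int = 64
    svs_seed: int = 11
    dvs_seed: int = 23
    r_leaf: float = 0.12
    murray_gamma: float = 3.0
    min_edge_length_factor: float = 1.0
    # physiology
    q_liv: float = 30.0  # mm^3/s, mouse-scale hepatic perfusion
    fractions: VolumeFractions = dc_field(default_factory=VolumeFractions)
    compound: CompoundParams | None = None
    metabolism: MetabolismParams = dc_field(default_factory=MetabolismParams)
    inflow: InflowProfile | None = None
    pathology: PathologySpec = dc_field(default_factory=PathologySpec)
    # numerics
    dt: float = 0.5  # s
    duration: float = 60.0  # s
    neighborhood_radius_factor: float = 2.0  # x grid spacing
    rkf45_tol: float = 1e-8
    ledger_abort_tol: float = 1e-6
    snapshot_times: tuple = ()
    k_eff: float = 1.0

    def content_hash(self) -> str:
        """Stable digest of the run conditions (geometry bytes, parameters,
        sampled inflow profile; no object identities)."""
        hasher = hashlib.sha256()

        def feed(x) -> None:
            if x is None:
                hasher.update(b"~")
            elif isinstance(x, np.ndarray):
                hasher.update(np.ascontiguousarray(x).tobytes())
            elif isinstance(x, (list, tuple)):
                for item in x:
                    feed(item)
            elif isinstance(x, dict):
                for key in sorted(map(str, x)):
                    hasher.update(str(key).encode())
            else:
                hasher.update(repr(x).encode())

        feed([self.half_axes, self.spacing, self.lobe_split, self.n_leaves,
              self.svs_seed, self.dvs_seed, self.r_leaf, self.murray_gamma,
              self.min_edge_length_factor, self.q_liv, self.dt, self.duration,
              self.neighborhood_radius_factor, self.rkf45_tol, self.k_eff,
              self.snapshot_times])
        if self.mask is not None:
            feed([self.mask.spacing, self.mask.occupancy, self.mask.lobe_label])
        for tree in (self.svs, self.dvs):
            if tree is not None:
                feed([tree.kind, tree.nodes, tree.edge_parent, tree.edge_child,
                      tree.radius])
        f = self.fractions
        feed([np.asarray(f.rbc), np.asarray(f.pls), np.asarray(f.int_),
              np.asarray(f.cell), np.asarray(f.rest)])
        if self.compound is not None:
            c = self.compound
            feed([c.name, c.mw, c.logp, c.fu, c.k_lip])
            for itf in c.interfaces:
                feed([itf.a, itf.b, np.asarray(itf.partition),
                      np.asarray(itf.permeability)])
        m = self.metabolism
        feed([m.mode, m.k_met, m.v_max, m.k_m])
        p = self.pathology
        feed([p.steatosis_mode, sorted((p.lobe_ranges or {}).items()),
              p.coarsening, p.steatosis_seed, p.necrosis_gamma])
        if self.inflow is not None:
            ts = np.linspace(0.0, self.duration, 257)
            feed([np.array([self.inflow.c_blood(t) for t in ts]),
                  self.inflow.k_rbc_pls, self.inflow.hematocrit])
        return hasher.hexdigest()[:16]


@dataclass
class SimulationResult:
    times: np.ndarray  # macro output grid (s)
    c_out: np.ndarray  # outflowing blood concentration at the DVS root (µmol/L)
    subspace_totals: np.ndarray  # (4, nt) stored amount per subspace (nmol)
    vascular_stored: np.ndarray  # (nt,) nmol in both trees
    cumulative_inflow: np.ndarray  # (nt,) nmol
    cumulative_outflow: np.ndarray
    cumulative_metabolized: np.ndarray
    closure_error: np.ndarray  # relative ledger residual per output time
    snapshots: dict  # time -> c_total full-grid array
    metadata: dict

    def final_closure_error(self) -> float:
        return float(self.closure_error[-1])


def total_concentration(field: SubspaceField) -> np.ndarray:
    """Imaging-comparable observable: c_total = sum_i f_i c_i per voxel
    (µmol per L of total tissue; the rest subspace carries no compound)."""
    farr = field.fractions.as_array()
    out = np.zeros(field.mask.shape)
    for i in range(4):
        out += np.broadcast_to(np.asarray(farr[i]), field.mask.shape) * field.c[i]
    out[~field.mask.occupancy] = 0.0
    return out


def _seed_tree(mask: OrganMask, kind: str, side: int) -> VascularTree:
    """One-edge seed tree entering the organ from the -x (+x) side."""
    fg = np.argwhere(mask.occupancy)
    h = mask.spacing
    centroid = (fg.mean(axis=0) + 0.5) * h
    x_extreme = fg[:, 0].min() if side < 0 else fg[:, 0].max()
    sel = fg[fg[:, 0] == x_extreme]
    mid = sel[np.argmin(np.sum((sel - sel.mean(axis=0)) ** 2, axis=1))]
    root = (mid + 0.5) * h
    dist = float(np.linalg.norm(centroid - root))
    # long enough that the first CCO bifurcation can split it (>= 2 voxels)
    frac = min(0.8, max(0.35, 2.5 * h / dist))
    tip = root + frac * (centroid - root)
    return VascularTree(
        kind=kind,
        nodes=np.vstack([root, tip]),
        edge_parent=[0],
        edge_child=[1],
        radius=[0.12],
    )


def build_geometry(cfg: SimulationConfig) -> tuple[OrganMask, VascularTree, VascularTree]:
    """Materialize mask and flow-assigned trees from a config."""
    mask = cfg.mask or generate_synthetic_mask(
        cfg.half_axes, cfg.spacing, lobe_split_plane=cfg.lobe_split
    )
    svs, dvs = cfg.svs, cfg.dvs
    min_len = cfg.min_edge_length_factor * mask.spacing
    if svs is None:
        svs = cco_extend(
            _seed_tree(mask, SUPPLYING, -1), mask, cfg.n_leaves,
            seed=cfg.svs_seed, r_leaf=cfg.r_leaf, gamma=cfg.murray_gamma,
            min_edge_length=min_len,
        )
    if dvs is None:
        dvs = cco_extend(
            _seed_tree(mask, DRAINING, +1), mask, cfg.n_leaves,
            seed=cfg.dvs_seed, r_leaf=cfg.r_leaf, gamma=cfg.murray_gamma,
            min_edge_length=min_len,
        )
    svs = prune_and_contract(svs, min_len, q_liv=cfg.q_liv)
    dvs = prune_and_contract(dvs, min_len, q_liv=cfg.q_liv)
    svs = assign_flows(svs, cfg.q_liv)
    dvs = assign_flows(dvs, cfg.q_liv)
    return mask, svs, dvs


def run(cfg: SimulationConfig) -> SimulationResult:
    """Execute the full operator-split simulation for one compound."""
    if cfg.compound is None or cfg.inflow is None:
        raise ValueError("config needs a compound and an inflow profile")
    if cfg.dt <= 0 or cfg.duration < cfg.dt:
        raise ValueError("need dt > 0 and duration >= dt")
    mask, svs, dvs = build_geometry(cfg)
    f = cfg.fractions
    compound, met = cfg.compound, cfg.metabolism
    h = mask.spacing
    occ_flat = mask.occupancy.ravel()

    # ---- Darcy velocity (static) -------------------------------------------
    sources = build_line_sources(svs, dvs, cfg.q_liv)
    pressure = solve_pressure(mask, sources, k_eff=cfg.k_eff)
    vel = velocity_from_pressure(pressure, cfg.k_eff, float(np.asarray(f.sin)))

    # ---- pathology ---------------------------------------------------------
    field = SubspaceField(mask=mask, fractions=f)
    met_scale: np.ndarray | float = 1.0
    pat = cfg.pathology
    lipid_mean = 0.0
    if pat.steatosis_mode is not None:
        lipid = make_steatosis_field(
            mask, pat.lobe_ranges, mode=pat.steatosis_mode,
            coarsening=pat.coarsening, seed=pat.steatosis_seed,
        )
        lipid_mean = lipid.mean
        k_cell = steatotic_kcell(
            float(np.asarray(compound.k_cell)), lipid.values, compound.k_lip
        )
        k_cell = np.where(mask.occupancy, k_cell, float(np.asarray(compound.k_cell)))
        compound = compound.with_kcell(k_cell.ravel())
    if pat.necrosis_gamma > 0:
        nec = necrosis_mask(mask, dvs, pat.necrosis_gamma)
        field, compound, met_grid = apply_necrosis(field, nec, compound)
        # metabolization only ever acts on foreground tissue
        met_scale = met_grid.ravel() * mask.occupancy.ravel()
        # flatten any per-voxel permeability arrays to the raveled grid
        compound = CompoundParams(
            name=compound.name, mw=compound.mw, logp=compound.logp, fu=compound.fu,
            interfaces=tuple(
                type(i)(
                    i.a, i.b,
                    np.asarray(i.partition).ravel() if np.ndim(i.partition) else i.partition,
                    np.asarray(i.permeability).ravel() if np.ndim(i.permeability) else i.permeability,
                )
                for i in compound.interfaces
            ),
            k_lip=compound.k_lip,
        )

    # kinetics act on the raveled grid; fractions flattened to match
    def ravel_f(x):
        return np.asarray(x, dtype=float).ravel() if np.ndim(x) else x

    f_kin = VolumeFractions(
        rbc=ravel_f(field.fractions.rbc),
        pls=ravel_f(field.fractions.pls),
        int_=ravel_f(field.fractions.int_),
        cell=ravel_f(field.fractions.cell),
        rest=ravel_f(field.fractions.rest),
    )
    farr_kin = f_kin.as_array()  # (4,) or (4, ngrid)

    # ---- advection systems & coupling geometry ----------------------------
    hema = float(np.asarray(f.hematocrit))
    svs_sys = TreeAdvectionSystem(svs, dx_target=h, hematocrit=hema)
    dvs_sys = TreeAdvectionSystem(dvs, dx_target=h, hematocrit=hema)
    hhs_adv = HHSAdvection(field, vel)
    src_geom = []
    for e in svs.terminal_edges:
        a, b = svs.nodes[svs.edge_parent[e]], svs.nodes[svs.edge_child[e]]
        src_geom.append(rasterize_segment(mask, a, b))
    radius = cfg.neighborhood_radius_factor * h
    sink_vox = []
    dvs_term = dvs.terminal_edges
    for e in dvs_term:
        a, b = dvs.nodes[dvs.edge_parent[e]], dvs.nodes[dvs.edge_child[e]]
        sink_vox.append(neighborhood_voxels(mask, a, b, radius))
    q_leaf_dvs = dvs.flow[dvs_term]
    phase_flow_dvs = np.array([hema, 1 - hema])[:, None] * q_leaf_dvs[None, :]

    # ---- time loop ---------------------------------------------------------
    n_steps = int(round(cfg.duration / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    c_out = np.zeros(n_steps + 1)
    subspace_totals = np.zeros((4, n_steps + 1))
    vasc_stored = np.zeros(n_steps + 1)
    cum_in = np.zeros(n_steps + 1)
    cum_out = np.zeros(n_steps + 1)
    cum_met = np.zeros(n_steps + 1)
    closure = np.zeros(n_steps + 1)
    snapshots: dict = {}
    snap_left = sorted(cfg.snapshot_times)
    h3 = h**3
    dt = cfg.dt
    cflat = field.c.reshape(4, -1)

    def grid_mass(c2d: np.ndarray) -> float:
        dens = np.sum(
            farr_kin.reshape(4, -1) * c2d if farr_kin.ndim > 1
            else farr_kin[:, None] * c2d,
            axis=0,
        )
        return float(dens[occ_flat].sum()) * h3

    subspace_totals[:, 0] = field.subspace_masses()
    exchange_active = any(
        np.any(np.asarray(itf.permeability) > 0) for itf in compound.interfaces
    )
    met_active = met.mode != "none" and bool(np.any(np.asarray(met_scale) != 0))
    for i in range(n_steps):
        t = times[i]
        # (1) supplying-tree advection
        svs_rec = svs_sys.step(dt, cfg.inflow, t0=t)
        cum_in[i + 1] = cum_in[i] + float(svs_rec["inflow_mass"].sum())
        # (2) HHS advection with coupling terms
        sink_avg = np.stack(
            [neighborhood_average(field, vox) for vox in sink_vox], axis=1
        )  # (2, n_term)
        sink_rates = [
            (sink_vox[s], phase_flow_dvs[:, s] * sink_avg[:, s])
            for s in range(len(sink_vox))
        ]
        src_rates = [
            (src_geom[s][0], src_geom[s][1], svs_rec["outflow_mass"][:, s] / dt)
            for s in range(len(src_geom))
        ]
        ledger = hhs_adv.step(dt, src_rates, sink_rates)
        # (3) pointwise PBPK exchange + metabolization
        step_met = 0.0
        if exchange_active or met_active:
            before = grid_mass(cflat) if met_active else 0.0

            def rhs(_t, y):
                return pbpk_rhs(y, compound, met, f_kin, met_scale)

            cnew = rkf45_integrate(
                rhs, cflat, (0.0, dt / 60.0), tol=cfg.rkf45_tol,
                h0=min(0.1 * dt / 60.0, 1.0 / 60.0),
            )
            cflat[:] = np.maximum(cnew, 0.0)
            # exchange conserves tissue mass, so the drop is the metabolized
            # amount; without an active sink it is identically zero
            if met_active:
                step_met = max(before - grid_mass(cflat), 0.0)
        cum_met[i + 1] = cum_met[i] + step_met
        # (4) draining-tree advection fed by exactly the withdrawn mass
        bc = ledger.withdrawn / (phase_flow_dvs * dt)
        dvs_rec = dvs_sys.step(dt, bc)
        out_mass = float(dvs_rec["outflow_mass"].sum())
        cum_out[i + 1] = cum_out[i] + out_mass
        c_out[i + 1] = out_mass / (cfg.q_liv * dt)
        # ---- ledger audit --------------------------------------------------
        subspace_totals[:, i + 1] = field.subspace_masses()
        vasc_stored[i + 1] = float(
            svs_sys.stored_mass().sum() + dvs_sys.stored_mass().sum()
        )
        stored = subspace_totals[:, i + 1].sum() + vasc_stored[i + 1]
        resid = cum_in[i + 1] - cum_out[i + 1] - cum_met[i + 1] - stored
        closure[i + 1] = abs(resid) / max(cum_in[i + 1], 1e-300)
        if cum_in[i + 1] > 0 and closure[i + 1] > cfg.ledger_abort_tol:
            raise RuntimeError(
                f"mass ledger violated at step {i + 1}: relative residual "
                f"{closure[i + 1]:.3e}"
            )
        while snap_left and snap_left[0] <= times[i + 1] + 1e-9:
            snapshots[snap_left.pop(0)] = total_concentration(field)

    metadata = {
        "config_hash": cfg.content_hash(),
        "compound": cfg.compound.name,
        "n_leaves_svs": int(svs.n_leaves),
        "n_leaves_dvs": int(dvs.n_leaves),
        "n_foreground_voxels": int(mask.n_foreground),
        "lipid_mean": lipid_mean,
        "seeds": {"svs": cfg.svs_seed, "dvs": cfg.dvs_seed,
                  "steatosis": cfg.pathology.steatosis_seed},
        "capping_events": int(ledger.capping_events) if n_steps else 0,
    }
    return SimulationResult(
        times=times, c_out=c_out, subspace_totals=subspace_totals,
        vascular_stored=vasc_stored, cumulative_inflow=cum_in,
        cumulative_outflow=cum_out, cumulative_metabolized=cum_met,
        closure_error=closure, snapshots=snapshots, metadata=metadata,
    )


def mass_balance_report(result: SimulationResult) -> dict:
    """Final-time mass accounting with relative closure error."""
    eps = 1e-300
    inflow = float(result.cumulative_inflow[-1])
    outflow = float(result.cumulative_outflow[-1])
    met = float(result.cumulative_metabolized[-1])
    stored_sub = result.subspace_totals[:, -1]
    stored = float(stored_sub.sum() + result.vascular_stored[-1])
    return {
        "inflow_nmol": inflow,
        "outflow_nmol": outflow,
        "metabolized_nmol": met,
        "stored_nmol": stored,
        "stored_by_subspace_nmol": {
            name: float(stored_sub[i])
            for i, name in enumerate(("rbc", "pls", "int", "cell"))
        },
        "stored_vascular_nmol": float(result.vascular_stored[-1]),
        "closure_error": abs(inflow - outflow - met - stored) / max(inflow, eps),
        "metabolized_fraction": met / max(inflow, eps),
    }


def summarize_outflow(
    times: np.ndarray,
    values: np.ndarray,
    inflow_times: np.ndarray | None = None,
    inflow_values: np.ndarray | None = None,
) -> dict:
    """Peak time/height, FWHM, AUC and a mean-transit-time estimate.

    MTT is the first temporal moment of the outflow curve minus the centroid
    of the inflow profile (zero when no inflow is given).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) == 0:
        raise ValueError("empty series")
    if not np.any(values > 0):
        return {"peak_time": None, "peak_height": 0.0, "auc": 0.0,
                "fwhm": None, "mtt": None, "flag": "all-zero series"}
    k = int(np.argmax(values))
    peak_t, peak_v = float(times[k]), float(values[k])
    auc = float(np.trapezoid(values, times))
    half = peak_v / 2.0
    above = values >= half
    idx = np.flatnonzero(above)

    def cross(i0: int, i1: int) -> float:
        v0, v1 = values[i0], values[i1]
        if v1 == v0:
            return float(times[i1])
        return float(times[i0] + (half - v0) * (times[i1] - times[i0]) / (v1 - v0))

    left = cross(idx[0] - 1, idx[0]) if idx[0] > 0 else float(times[0])
    right = cross(idx[-1] + 1, idx[-1]) if idx[-1] < len(times) - 1 else float(times[-1])
    fwhm = right - left
    centroid_out = float(np.trapezoid(values * times, times) / auc)
    mtt = centroid_out
    if inflow_times is not None and inflow_values is not None:
        iv = np.asarray(inflow_values, dtype=float)
        it = np.asarray(inflow_times, dtype=float)
        a = float(np.trapezoid(iv, it))
        if a > 0:
            mtt = centroid_out - float(np.trapezoid(iv * it, it) / a)
    return {"peak_time": peak_t, "peak_height": peak_v, "auc": auc,
            "fwhm": fwhm, "mtt": mtt}


def result_to_csv(result: SimulationResult, path: str) -> None:
    """Write the outflow and subspace time series as CSV."""
    header = ("t_s,c_out_umol_per_L,rbc_nmol,pls_nmol,int_nmol,cell_nmol,"
              "vascular_nmol,cum_in_nmol,cum_out_nmol,cum_met_nmol,closure")
    data = np.column_stack(
        [result.times, result.c_out, result.subspace_totals.T,
         result.vascular_stored, result.cumulative_inflow,
         result.cumulative_outflow, result.cumulative_metabolized,
         result.closure_error]
    )
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def report_to_json(result: SimulationResult, path: str) -> None:
    doc = {"mass_balance": mass_balance_report(result),
           "outflow_summary": summarize_outflow(result.times, result.c_out),
           "metadata": result.metadata}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
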