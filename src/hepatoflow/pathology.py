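"""Spatially heterogeneous pathophysiology: steatosis and pericentral necrosis.

Steatosis is modeled as a lipid volume ratio field rho(x) in [0, 1) that
raises the cellular partition coefficient — lipid-bound compound is retained
longer in the cells, which indirectly raises metabolization.  Necrosis (the
carbon-tetrachloride pattern: hepatocyte death around the central veins) is
modeled by converting the cellular subspace into interstitium in the fraction
gamma of the organ volume closest to the draining terminal edges, with
metabolization switched off there.  Neither pathology alters perfusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry.mask import OrganMask
from .geometry.tree import VascularTree
from .hhs import SubspaceField
from .kinetics import CompoundParams, VolumeFractions


@dataclass
class LipidField:
    """Per-voxel lipid volume ratio rho in [0, 1); zero is the healthy state."""

    mask: OrganMask
    values: np.ndarray  # full grid

    def __post_init__(self) -> None:
        v = self.values[self.mask.occupancy]
        if np.any(v < 0) or np.any(v >= 1):
            raise ValueError("lipid ratio must lie in [0, 1)")

    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask.occupancy]

    @property
    def mean(self) -> float:
        return float(self.foreground_values().mean())


@dataclass
class NecrosisMask:
    """Necrotic voxels: the gamma-quantile of foreground by distance to the
    nearest draining terminal-edge centerline."""

    mask: OrganMask
    necrotic: np.ndarray  # full-grid bool
    gamma: float


def make_steatosis_field(
    mask: OrganMask,
    lobe_ranges: dict[int, tuple[float, float]],
    mode: str = "heterogeneous",
    coarsening: int = 4,
    seed: int = 0,
) -> LipidField:
    """Build a lipid ratio field from per-lobe uniform ranges.

    heterogeneous: i.i.d. uniform draws on a grid ``coarsening`` times coarser
    than the computational resolution, interpolated multilinearly onto the
    voxel grid.  One coarse random field is drawn per lobe (from that lobe's
    range) and composited by lobe membership, so the per-lobe sample mean is
    an unbiased estimate of the lobe's range midpoint everywhere including
    the lobe boundary.  homogeneous: one constant equal to the
    volume-weighted mean of the per-lobe range midpoints.
    """
    if coarsening < 1:
        raise ValueError("coarsening must be >= 1")
    labels = np.unique(mask.lobe_label[mask.occupancy])
    for lab in labels:
        if int(lab) not in lobe_ranges:
            raise ValueError(f"no lipid range given for lobe label {int(lab)}")
        lo, hi = lobe_ranges[int(lab)]
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"lobe {int(lab)}: range must satisfy 0 <= lo <= hi < 1")

    counts = {int(l): int((mask.lobe_label == l).sum()) for l in labels}
    n_fg = mask.n_foreground
    mean_mid = sum(
        counts[l] / n_fg * 0.5 * (lobe_ranges[l][0] + lobe_ranges[l][1])
        for l in counts
    )
    if mode == "homogeneous":
        values = np.where(mask.occupancy, mean_mid, 0.0)
        return LipidField(mask=mask, values=values)
    if mode != "heterogeneous":
        raise ValueError(f"unknown steatosis mode {mode!r}")

    rng = np.random.default_rng(seed)
    shape = np.array(mask.shape)
    n_coarse = np.ceil((shape - 1) / coarsening).astype(int) + 1
    axes = [np.arange(n) * coarsening for n in n_coarse]
    fine_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    values = np.zeros(mask.shape)
    for lab in sorted(int(l) for l in labels):
        lo, hi = lobe_ranges[lab]
        draws = rng.uniform(lo, hi, size=int(np.prod(n_coarse)))
        # antithetic pairing: every second draw mirrors the previous one, so
        # the coarse-field mean is pinned at the range midpoint (variance
        # reduction; the marginal distribution stays uniform in [lo, hi])
        n_pairs = len(draws) // 2
        draws[1 : 2 * n_pairs : 2] = lo + hi - draws[0 : 2 * n_pairs : 2]
        draws = draws.reshape(tuple(n_coarse))
        interp = RegularGridInterpolator(axes, draws, method="linear")
        sel = mask.lobe_label == lab
        values[sel] = interp(fine_idx[sel])
    return LipidField(mask=mask, values=values)


def steatotic_kcell(k_cell_healthy, rho, k_lip, form=None):
    """Cellular partition coefficient under lipid accumulation.

    Default form: volume-weighted mixing of the aqueous and lipid affinity,
    K_cell(rho) = K_healthy (1 - rho) + k_lip rho — anchored at the healthy
    value for rho = 0 and strictly increasing in rho when k_lip > K_healthy.
    A different functional form can be plugged in via ``form(K_h, rho, k_lip)``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ValueError("lipid ratio must lie in [0, 1)")
    if k_lip < 0:
        raise ValueError("k_lip must be nonnegative")
    if form is not None:
        return form(k_cell_healthy, rho, k_lip)
    out = k_cell_healthy * (1.0 - rho) + k_lip * rho
    return out if rho.ndim else float(out)


def distance_to_terminal_edges(mask: OrganMask, tree: VascularTree) -> np.ndarray:
    """Exact distance (mm) from each foreground voxel center to the nearest
    terminal-edge centerline segment of ``tree``."""
    centers = mask.voxel_centers()
    best = np.full(len(centers), np.inf)
    for e in tree.terminal_edges:
        a = tree.nodes[tree.edge_parent[e]]
        b = tree.nodes[tree.edge_child[e]]
        d = b - a
        denom = float(d @ d)
        t = np.clip((centers - a) @ d / denom, 0.0, 1.0) if denom else 0.0
        proj = a[None] + np.atleast_1d(t)[:, None] * d[None]
        best = np.minimum(best, np.linalg.norm(centers - proj, axis=1))
    return best


def necrosis_mask(mask: OrganMask, dvs: VascularTree, gamma: float) -> NecrosisMask:
    """Select the gamma-quantile of foreground closest to DVS terminals."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("necrotic volume fraction must lie in [0, 1]")
    nec = np.zeros(mask.shape, dtype=bool)
    if gamma > 0:
        dist = distance_to_terminal_edges(mask, dvs)
        k = int(round(gamma * mask.n_foreground))
        order = np.argsort(dist, kind="stable")[:k]
        fg = np.argwhere(mask.occupancy)[order]
        nec[fg[:, 0], fg[:, 1], fg[:, 2]] = True
    return NecrosisMask(mask=mask, necrotic=nec, gamma=gamma)


def apply_necrosis(
    field: SubspaceField,
    nec: NecrosisMask,
    compound: CompoundParams,
) -> tuple[SubspaceField, CompoundParams, np.ndarray]:
    """Replace cellular by interstitial space in the necrotic volume.

    Returns (field with per-voxel volume fractions, compound with the
    cellular exchange deactivated in necrotic voxels, met_scale full-grid
    array that is 0 in necrotic voxels and 1 elsewhere).  The volume-fraction
    sum is preserved voxel-wise; perfusion is untouched.
    """
    f = field.fractions
    necro = nec.necrotic
    if not necro.any():
        return field, compound, np.ones(nec.mask.shape)
    f_int = np.broadcast_to(np.asarray(f.int_, dtype=float), nec.mask.shape).copy()
    f_cell = np.broadcast_to(np.asarray(f.cell, dtype=float), nec.mask.shape).copy()
    f_int[necro] += f_cell[necro]
    f_cell[necro] = 0.0
    new_f = VolumeFractions(
        rbc=f.rbc, pls=f.pls, int_=f_int, cell=f_cell, rest=f.rest
    )
    new_field = SubspaceField(mask=field.mask, fractions=new_f, c=field.c)
    met_scale = np.where(necro, 0.0, 1.0)
    # deactivate cellular exchange where the cellular space no longer exists
    for itf in compound.interfaces:
        if itf.a == "cell" or itf.b == "cell":
            p = np.asarray(itf.permeability, dtype=float) * np.where(necro, 0.0, 1.0)
            compound = compound.with_cell_permeability(p)
            break
    return new_field, compound, met_scale
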