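"""Steady Darcy perfusion of the homogenized hepatic space (HHS).

The tissue between the resolved vessels is a porous medium.  Blood enters
along the centerlines of the supplying terminal edges and leaves along the
draining ones; these line sources/sinks drive the pure-Neumann Poisson
problem

    -div(K_eff grad p) = q,      no-flux on the organ boundary,

discretized with trilinear (Q1) finite elements whose nodes are the centers
of foreground voxels.  The effective permeability K_eff is a relative unit
quantity, so p is only a relative pressure; the Darcy velocity
v = -(K_eff / phi_sin) grad p is the quantity used downstream.  The nullspace
(constants per connected component) is removed by mean-zero constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .geometry.mask import OrganMask
from .geometry.tree import VascularTree

_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
)


def _shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at local coords xi in [0,1]^3, shape (..., 8)."""
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    fx = np.stack([1 - x, x], -1)
    fy = np.stack([1 - y, y], -1)
    fz = np.stack([1 - z, z], -1)
    return np.stack(
        [fx[..., a] * fy[..., b] * fz[..., c] for a, b, c in _OFFSETS], -1
    )


def element_stiffness(h: float) -> np.ndarray:
    """8x8 Laplace stiffness of a trilinear element on a cube of side h."""
    g = (np.array([-1, 1]) / np.sqrt(3) + 1) / 2  # 2-pt Gauss on [0,1]
    K = np.zeros((8, 8))
    for gx in g:
        for gy in g:
            for gz in g:
                grads = np.zeros((8, 3))
                for n, (a, b, c) in enumerate(_OFFSETS):
                    fx, fy, fz = (1 - gx, gx)[a], (1 - gy, gy)[b], (1 - gz, gz)[c]
                    dfx, dfy, dfz = (-1, 1)[a], (-1, 1)[b], (-1, 1)[c]
                    grads[n] = [dfx * fy * fz, fx * dfy * fz, fx * fy * dfz]
                K += grads @ grads.T * (1.0 / 8.0)  # weight (1/2)^3 in local coords
    return K * h  # scale: grad ~ 1/h, volume ~ h^3


@dataclass
class SourceField:
    """Line sources/sinks: segments (mm endpoints) with uniform volumetric
    strength (mm^3/s per mm of length); supplying +, draining -."""

    segments: np.ndarray  # (n, 2, 3)
    strength: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float).reshape(-1, 2, 3)
        self.strength = np.asarray(self.strength, dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segments[:, 1] - self.segments[:, 0], axis=1)

    @property
    def net_flow(self) -> float:
        return float(np.sum(self.strength * self.lengths))


def build_line_sources(
    svs: VascularTree, dvs: VascularTree, q_liv: float
) -> SourceField:
    """Terminal-edge line sources (+Q_leaf/L) and sinks (-Q_leaf/L)."""
    segs, strength = [], []
    for tree, sign in ((svs, +1.0), (dvs, -1.0)):
        if tree.flow is None:
            raise ValueError("trees must have assigned flows")
        root_q = tree.flow[tree.root_edge]
        if abs(root_q - q_liv) > 1e-9 * max(q_liv, 1.0):
            raise ValueError("tree total flow does not match Q_liv")
        for e in tree.terminal_edges:
            a = tree.nodes[tree.edge_parent[e]]
            b = tree.nodes[tree.edge_child[e]]
            length = float(np.linalg.norm(b - a))
            segs.append([a, b])
            strength.append(sign * tree.flow[e] / length)
    return SourceField(np.asarray(segs), np.asarray(strength))


@dataclass
class PressureField:
    """Relative pressure at foreground voxel centers (mean zero per component)."""

    mask: OrganMask
    values: np.ndarray  # full grid, 0 outside active DOFs
    active: np.ndarray  # bool grid: voxels that belong to >=1 element


@dataclass
class VelocityField:
    """Piecewise-constant Darcy data on the voxel grid.

    ``face_flux_*`` are volumetric blood fluxes (mm^3/s) through the voxel
    faces orthogonal to each axis (zero on boundary/background faces); ``v``
    is the cell-centered interstitial velocity (mm/s), v = u / phi_sin.
    """

    mask: OrganMask
    face_flux_x: np.ndarray  # (nx+1, ny, nz)
    face_flux_y: np.ndarray
    face_flux_z: np.ndarray
    phi_sin: float
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.v is None:
            h = self.mask.spacing
            area = h * h
            vx = 0.5 * (self.face_flux_x[:-1] + self.face_flux_x[1:]) / area
            vy = 0.5 * (self.face_flux_y[:, :-1] + self.face_flux_y[:, 1:]) / area
            vz = 0.5 * (self.face_flux_z[:, :, :-1] + self.face_flux_z[:, :, 1:]) / area
            self.v = np.stack([vx, vy, vz], axis=-1) / self.phi_sin
            self.v[~self.mask.occupancy] = 0.0

    def divergence(self) -> np.ndarray:
        """Net volumetric outflow per voxel (mm^3/s)."""
        d = np.diff(self.face_flux_x, axis=0)
        d = d + np.diff(self.face_flux_y, axis=1)
        d = d + np.diff(self.face_flux_z, axis=2)
        return d


class _ElementMesh:
    """Q1 mesh on the foreground voxel centers, shared by solve and RHS."""

    def __init__(self, mask: OrganMask):
        occ = mask.occupancy
        nx, ny, nz = occ.shape
        el = (
            occ[:-1, :-1, :-1] & occ[1:, :-1, :-1] & occ[:-1, 1:, :-1]
            & occ[1:, 1:, :-1] & occ[:-1, :-1, 1:] & occ[1:, :-1, 1:]
            & occ[:-1, 1:, 1:] & occ[1:, 1:, 1:]
        )
        self.el_idx = np.argwhere(el)
        if len(self.el_idx) == 0:
            raise ValueError("mask too thin: no 2x2x2 foreground block exists")
        self.mask = mask
        active = np.zeros(occ.shape, dtype=bool)
        for off in _OFFSETS:
            active[
                tuple(slice(o, n + o - 1) for o, n in zip(off, occ.shape))
            ] |= el
        self.active = active
        self.dof_index = -np.ones(occ.shape, dtype=int)
        self.dof_index[active] = np.arange(active.sum())
        self.n_dof = int(active.sum())
        # per element: 8 dof ids
        self.el_dofs = np.stack(
            [
                self.dof_index[
                    self.el_idx[:, 0] + a, self.el_idx[:, 1] + b, self.el_idx[:, 2] + c
                ]
                for a, b, c in _OFFSETS
            ],
            axis=1,
        )
        h = mask.spacing
        self.el_lower = (self.el_idx + 0.5) * h  # physical corner (voxel center)
        self._tree = cKDTree(self.el_lower + 0.5 * h)

    def locate(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Element id and local coords for physical points (clamped to the
        nearest element when a point falls outside the element mesh)."""
        pts = np.atleast_2d(pts)
        _, el = self._tree.query(pts)
        xi = (pts - self.el_lower[el]) / self.mask.spacing
        return el, np.clip(xi, 0.0, 1.0)


def assemble_rhs(
    mesh: _ElementMesh, sources: SourceField, gauss_order: int = 3
) -> np.ndarray:
    """Exact-as-practical line integrals of the Q1 basis along each segment.

    Segments are subdivided at element faces; Gauss quadrature of the given
    order is applied per sub-segment.  Portions that leave the element mesh
    (terminal edges hugging the organ surface) are clamped to the nearest
    element so no source mass is lost (sum of the RHS equals the net source
    exactly, preserving the Neumann compatibility condition).
    """
    h = mesh.mask.spacing
    # Gauss nodes/weights on [0,1]
    xg, wg = np.polynomial.legendre.leggauss(gauss_order)
    xg = (xg + 1) / 2
    wg = wg / 2
    b = np.zeros(mesh.n_dof)
    for (p0, p1), q in zip(sources.segments, sources.strength):
        d = p1 - p0
        length = float(np.linalg.norm(d))
        if length == 0 or q == 0:
            continue
        # parameters where the segment crosses element-boundary planes
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] != 0:
                k0 = np.floor(p0[ax] / h - 0.5)
                k1 = np.floor(p1[ax] / h - 0.5)
                lo, hi = sorted((k0, k1))
                for k in np.arange(lo + 1, hi + 1):
                    t = ((k + 0.5) * h - p0[ax]) / d[ax]
                    if 0.0 < t < 1.0:
                        ts.append(float(t))
        ts = np.unique(ts)
        for ta, tb in zip(ts[:-1], ts[1:]):
            sub_len = (tb - ta) * length
            if sub_len == 0:
                continue
            tq = ta + (tb - ta) * xg
            pts = p0[None] + tq[:, None] * d[None]
            el, xi = mesh.locate(pts)
            N = _shape_functions(xi)  # (g, 8)
            np.add.at(b, mesh.el_dofs[el], q * sub_len * wg[:, None] * N)
    return b


def solve_pressure(
    mask: OrganMask, sources: SourceField, k_eff: float = 1.0
) -> PressureField:
    """Solve the pure-Neumann Darcy pressure problem on the foreground grid."""
    if k_eff <= 0:
        raise ValueError("k_eff must be positive")
    mesh = _ElementMesh(mask)
    Ke = element_stiffness(mask.spacing) * k_eff
    rows = np.repeat(mesh.el_dofs, 8, axis=1).ravel()
    cols = np.tile(mesh.el_dofs, (1, 8)).ravel()
    vals = np.tile(Ke.ravel(), len(mesh.el_idx))
    K = sparse.csr_matrix((vals, (rows, cols)), shape=(mesh.n_dof, mesh.n_dof))
    b = assemble_rhs(mesh, sources)

    n_comp, labels = connected_components(K != 0, directed=False)
    total = float(np.sum(np.abs(sources.strength) * sources.lengths))
    for comp in range(n_comp):
        net = float(b[labels == comp].sum())
        if abs(net) > 1e-9 * max(total, 1.0):
            raise ValueError(
                f"incompatible sources: net flow {net:.3e} in component {comp}"
            )
    # bordered system: mean-zero constraint per connected component
    C = sparse.csr_matrix(
        (np.ones(mesh.n_dof), (np.arange(mesh.n_dof), labels)),
        shape=(mesh.n_dof, n_comp),
    )
    A = sparse.bmat([[K, C], [C.T, None]], format="csc")
    rhs = np.concatenate([b, np.zeros(n_comp)])
    sol = spsolve(A, rhs)
    p = np.zeros(mask.shape)
    p[mesh.active] = sol[: mesh.n_dof]
    return PressureField(mask=mask, values=p, active=mesh.active)


def velocity_from_pressure(
    p: PressureField, k_eff: float = 1.0, phi_sin: float = 0.2
) -> VelocityField:
    """Face-centered difference quotients of p; zero flux at organ boundary.

    Face volumetric flux = -K_eff * (p_+ - p_-)/h * h^2 on faces between two
    active foreground voxels, zero elsewhere, which enforces the no-flux
    organ-boundary condition at the discrete level.
    """
    if phi_sin <= 0:
        raise ValueError("phi_sin must be positive")
    h = p.mask.spacing
    act = p.active
    pv = p.values
    nx, ny, nz = p.mask.shape
    fx = np.zeros((nx + 1, ny, nz))
    fy = np.zeros((nx, ny + 1, nz))
    fz = np.zeros((nx, ny, nz + 1))
    both = act[:-1] & act[1:]
    fx[1:-1][both] = (-k_eff * (pv[1:] - pv[:-1]) / h * h * h)[both]
    both = act[:, :-1] & act[:, 1:]
    fy[:, 1:-1][both] = (-k_eff * (pv[:, 1:] - pv[:, :-1]) / h * h * h)[both]
    both = act[:, :, :-1] & act[:, :, 1:]
    fz[:, :, 1:-1][both] = (-k_eff * (pv[:, :, 1:] - pv[:, :, :-1]) / h * h * h)[both]
    return VelocityField(
        mask=p.mask, face_flux_x=fx, face_flux_y=fy, face_flux_z=fz, phi_sin=phi_sin
    )
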