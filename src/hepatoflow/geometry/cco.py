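"""Constrained constructive optimization (CCO) growth of vascular trees.

Synthetic vascular refinement: new terminal sites are sampled inside the
organ mask and connected one at a time through a new bifurcation whose
position minimizes the total intravascular volume  sum_e pi r_e^2 L_e,
subject to equal terminal flows and the Murray radius rule.  This is the
classic minimal-volume growth objective for organ-shape-constrained trees;
the bifurcation position is optimized continuously (Nelder–Mead) starting
from the perpendicular foot point of the target on the host segment.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .mask import OrganMask
from .tree import VascularTree


def point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance from point p to segment [a, b] (all shape (3,))."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _foot_point(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, tlo: float = 0.1, thi: float = 0.9
) -> np.ndarray:
    ab = b - a
    t = float(np.clip((p - a) @ ab / (ab @ ab), tlo, thi))
    return a + t * ab


def _attach(
    tree: VascularTree,
    edge: int,
    x: np.ndarray,
    target: np.ndarray,
    r_leaf: float,
    gamma: float,
) -> VascularTree:
    """Split ``edge`` at position x and hang a new terminal edge to ``target``."""
    n = len(tree.nodes)
    nodes = np.vstack([tree.nodes, x[None], target[None]])
    ep = np.concatenate([tree.edge_parent, [n, n]])
    ec = np.concatenate([tree.edge_child, [tree.edge_child[edge], n + 1]])
    ec_mod = ec.copy()
    # original edge now ends at the bifurcation node
    ec_mod[edge] = n
    r = np.concatenate([tree.radius, [tree.radius[edge], r_leaf]])
    cand = VascularTree(
        kind=tree.kind, nodes=nodes, edge_parent=ep, edge_child=ec_mod, radius=r
    )
    return cand.with_murray_radii(r_leaf, gamma)


def _segments_admissible(
    tree: VascularTree, mask: OrganMask, min_len: float
) -> bool:
    lengths = tree.lengths
    if np.any(lengths < min_len):
        return False
    mids = 0.5 * (tree.nodes[tree.edge_parent] + tree.nodes[tree.edge_child])
    pts = np.vstack([tree.nodes, mids])
    return bool(np.all(mask.contains(pts)))


def optimal_bifurcation(
    tree: VascularTree,
    edge: int,
    target: np.ndarray,
    mask: OrganMask,
    r_leaf: float = 0.1,
    gamma: float = 3.0,
    optimize: bool = True,
    min_edge_length: float | None = None,
) -> tuple[np.ndarray, float, VascularTree] | None:
    """Best in-mask bifurcation position on ``edge`` for a new leaf at ``target``.

    Returns (position, volume, candidate tree) or None when no admissible
    position exists.  Admissible means: all nodes and segment midpoints in the
    mask foreground and no edge shorter than ``min_edge_length`` (default one
    grid spacing, matching the sub-resolution pruning threshold so that grown
    trees survive pruning unchanged).  With ``optimize=False`` the
    perpendicular foot point is used directly (the unoptimized
    nearest-attachment baseline).
    """
    target = np.asarray(target, dtype=float)
    a = tree.nodes[tree.edge_parent[edge]]
    b = tree.nodes[tree.edge_child[edge]]
    min_len = mask.spacing if min_edge_length is None else min_edge_length
    seg_len = float(np.linalg.norm(b - a))
    if seg_len < 2.0 * min_len:
        return None  # edge too short to host a bifurcation
    tlo = min_len / seg_len
    x0 = _foot_point(target, a, b, tlo=max(0.1, tlo), thi=min(0.9, 1.0 - tlo))

    def cost(x: np.ndarray) -> float:
        cand = _attach(tree, edge, x, target, r_leaf, gamma)
        if not _segments_admissible(cand, mask, min_len):
            return np.inf
        return cand.volume

    c0 = cost(x0)
    if not np.isfinite(c0):
        return None
    if not optimize:
        return x0, c0, _attach(tree, edge, x0, target, r_leaf, gamma)
    res = minimize(
        cost,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 0.05 * mask.spacing,
            "fatol": 1e-10,
            "maxiter": 200,
            "initial_simplex": x0[None] + np.vstack(
                [np.zeros(3), 0.5 * mask.spacing * np.eye(3)]
            ),
        },
    )
    best_x, best_c = (res.x, res.fun) if res.fun <= c0 else (x0, c0)
    if not np.isfinite(best_c):
        return None
    return best_x, float(best_c), _attach(tree, edge, best_x, target, r_leaf, gamma)


def cco_extend(
    tree: VascularTree,
    mask: OrganMask,
    n_leaves_target: int,
    seed: int = 0,
    r_leaf: float = 0.1,
    gamma: float = 3.0,
    optimize: bool = True,
    n_candidate_edges: int = 5,
    max_attempts: int = 400,
    min_edge_length: float | None = None,
) -> VascularTree:
    """Grow the tree by adding terminal sites until it has ``n_leaves_target``.

    Target sites are drawn uniformly from mask foreground voxel centers with
    minimum-distance rejection against existing nodes (the rejection radius
    relaxes geometrically when sampling stalls).  Deterministic for a fixed
    seed.  Raises if an insertion finds no admissible bifurcation.
    """
    if n_leaves_target < tree.n_leaves:
        raise ValueError("n_leaves_target below current leaf count")
    if n_leaves_target == tree.n_leaves:
        return tree
    rng = np.random.default_rng(seed)
    centers = mask.voxel_centers()
    d_min0 = 0.8 * (mask.volume / max(n_leaves_target, 1)) ** (1.0 / 3.0)

    while tree.n_leaves < n_leaves_target:
        insertion = tree.n_leaves + 1
        d_min = d_min0
        placed = False
        for attempt in range(max_attempts):
            if attempt and attempt % 40 == 0:
                d_min *= 0.7
            target = centers[rng.integers(len(centers))]
            d_nodes = np.linalg.norm(tree.nodes - target, axis=1)
            if d_nodes.min() < d_min:
                continue
            # candidate host edges: nearest few segments
            d_seg = np.array(
                [
                    point_segment_distance(
                        target,
                        tree.nodes[tree.edge_parent[e]],
                        tree.nodes[tree.edge_child[e]],
                    )
                    for e in range(tree.n_edges)
                ]
            )
            hosts = np.argsort(d_seg, kind="stable")[:n_candidate_edges]
            best = None
            for e in hosts:
                out = optimal_bifurcation(
                    tree, int(e), target, mask, r_leaf, gamma, optimize,
                    min_edge_length=min_edge_length,
                )
                if out is not None and (best is None or out[1] < best[1]):
                    best = out
                if not optimize and best is not None:
                    break  # baseline: nearest admissible segment, no search
            if best is not None:
                tree = best[2]
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"CCO insertion {insertion}: no admissible in-mask candidate site"
            )
    return tree
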