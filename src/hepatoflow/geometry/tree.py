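"""Directed bifurcative vascular trees.

A tree is stored as flat arrays: node positions (mm) plus edges defined by
(parent node, child node, radius).  Supplying trees (portal-vein-like) carry
blood from the root towards the leaves; draining trees (hepatic-vein-like)
collect it in the opposite direction.  Either way edges are stored pointing
away from the root; the ``kind`` attribute fixes the flow direction.

Flows are assigned under the equal-leaf-outflow assumption: every terminal
edge carries Q_liv / N_leaves, interior edges the sum over their leaf
descendants, which makes junction conservation exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

SUPPLYING = "supplying"
DRAINING = "draining"


@dataclass
class VascularTree:
    kind: str
    nodes: np.ndarray  # (n_nodes, 3) float, mm
    edge_parent: np.ndarray  # (n_edges,) int — node index at the root side
    edge_child: np.ndarray  # (n_edges,) int — node index away from the root
    radius: np.ndarray  # (n_edges,) float, mm
    flow: np.ndarray | None = None  # (n_edges,) float, mm^3/s of blood

    def __post_init__(self) -> None:
        if self.kind not in (SUPPLYING, DRAINING):
            raise ValueError(f"unknown tree kind {self.kind!r}")
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.edge_parent = np.asarray(self.edge_parent, dtype=int)
        self.edge_child = np.asarray(self.edge_child, dtype=int)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.flow is not None:
            self.flow = np.asarray(self.flow, dtype=float)

    # ---------------------------------------------------------------- basics
    @property
    def n_edges(self) -> int:
        return len(self.edge_parent)

    @property
    def lengths(self) -> np.ndarray:
        d = self.nodes[self.edge_child] - self.nodes[self.edge_parent]
        return np.linalg.norm(d, axis=1)

    @property
    def areas(self) -> np.ndarray:
        return np.pi * self.radius**2

    @property
    def velocity(self) -> np.ndarray:
        """Mean blood velocity per edge, mm/s (requires assigned flows)."""
        if self.flow is None:
            raise ValueError("flows not assigned")
        return self.flow / self.areas

    @property
    def volume(self) -> float:
        """Total intravascular volume sum_e pi r_e^2 L_e (mm^3)."""
        return float(np.sum(self.areas * self.lengths))

    def children_of_node(self) -> list[list[int]]:
        """Outgoing edge ids per node."""
        out: list[list[int]] = [[] for _ in range(len(self.nodes))]
        for e, p in enumerate(self.edge_parent):
            out[p].append(e)
        return out

    @property
    def root_node(self) -> int:
        children = set(self.edge_child.tolist())
        roots = [n for n in range(len(self.nodes)) if n not in children]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return roots[0]

    @property
    def root_edge(self) -> int:
        out = np.flatnonzero(self.edge_parent == self.root_node)
        if len(out) != 1:
            raise ValueError("root node must have exactly one outgoing edge")
        return int(out[0])

    @property
    def terminal_edges(self) -> np.ndarray:
        """Edge ids whose child node has no outgoing edges."""
        has_out = np.zeros(len(self.nodes), dtype=bool)
        has_out[self.edge_parent] = True
        return np.flatnonzero(~has_out[self.edge_child])

    @property
    def n_leaves(self) -> int:
        return len(self.terminal_edges)

    def parent_edge(self) -> np.ndarray:
        """Incoming edge id per edge (-1 for the root edge)."""
        in_edge = -np.ones(len(self.nodes), dtype=int)
        in_edge[self.edge_child] = np.arange(self.n_edges)
        return in_edge[self.edge_parent]

    def topological_edge_order(self) -> np.ndarray:
        """Edge ids ordered root-first (parents before children)."""
        kids = self.children_of_node()
        order, stack = [], [self.root_node]
        while stack:
            n = stack.pop()
            for e in kids[n]:
                order.append(e)
                stack.append(self.edge_child[e])
        if len(order) != self.n_edges:
            raise ValueError("tree is not connected or contains a cycle")
        return np.asarray(order, dtype=int)

    def leaf_counts(self) -> np.ndarray:
        """Number of terminal descendants per edge (1 for terminal edges)."""
        counts = np.zeros(self.n_edges, dtype=int)
        counts[self.terminal_edges] = 1
        parent = self.parent_edge()
        for e in self.topological_edge_order()[::-1]:
            if parent[e] >= 0:
                counts[parent[e]] += counts[e]
        return counts

    def validate(self, mask=None, tol_voxels: float = 1.0) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if np.any(self.radius <= 0):
            raise ValueError("all edge radii must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("all edge lengths must be positive")
        self.topological_edge_order()  # connectivity + acyclicity + single root
        if self.flow is not None:
            kids = self.children_of_node()
            for e in range(self.n_edges):
                ch = kids[self.edge_child[e]]
                if ch:
                    res = abs(self.flow[e] - sum(self.flow[c] for c in ch))
                    if res > 1e-12 * max(self.flow[e], 1e-300):
                        raise ValueError(f"flow not conserved at edge {e}")
        if mask is not None:
            d = mask.distance_to_foreground(self.nodes)
            if np.any(np.asarray(d) > tol_voxels * mask.spacing * np.sqrt(3)):
                raise ValueError("tree node outside mask foreground")

    # ------------------------------------------------------------------- ops
    def with_murray_radii(self, r_leaf: float, gamma: float = 3.0) -> "VascularTree":
        """Recompute radii: terminal edges get ``r_leaf``, interior edges the
        Murray-law value r_p = (sum_c r_c^gamma)^(1/gamma)."""
        if r_leaf <= 0:
            raise ValueError("r_leaf must be positive")
        r = np.zeros(self.n_edges)
        r[self.terminal_edges] = r_leaf
        parent = self.parent_edge()
        acc = np.zeros(self.n_edges)
        for e in self.topological_edge_order()[::-1]:
            if r[e] == 0.0:
                r[e] = acc[e] ** (1.0 / gamma)
            if parent[e] >= 0:
                acc[parent[e]] += r[e] ** gamma
        return replace(self, radius=r, flow=self.flow)


def assign_flows(tree: VascularTree, q_liv: float) -> VascularTree:
    """Equal outflow per terminal edge: Q_e = Q_liv * (#leaf descendants) / N."""
    if q_liv < 0:
        raise ValueError("Q_liv must be nonnegative")
    if np.any(tree.radius <= 0):
        raise ValueError("zero-radius edge")
    counts = tree.leaf_counts()
    flow = q_liv * counts / tree.n_leaves
    return replace(tree, flow=flow)


def prune_and_contract(
    tree: VascularTree, min_length: float, q_liv: float | None = None
) -> VascularTree:
    """Remove sub-resolution edges.

    Terminal edges shorter than ``min_length`` are pruned; interior short
    edges are contracted (their endpoints merged), which may create
    multifurcations.  Flows are reassigned afterwards when the input tree had
    flows (total preserved unless ``q_liv`` overrides it).
    """
    if min_length < 0:
        raise ValueError("min_length must be nonnegative")
    if q_liv is None and tree.flow is not None:
        q_liv = float(tree.flow[tree.root_edge])

    nodes = tree.nodes.copy()
    edges = [
        (int(p), int(c), float(r))
        for p, c, r in zip(tree.edge_parent, tree.edge_child, tree.radius)
    ]

    def build() -> VascularTree:
        p = np.array([e[0] for e in edges])
        c = np.array([e[1] for e in edges])
        r = np.array([e[2] for e in edges])
        used = np.unique(np.concatenate([p, c]))
        remap = {int(n): i for i, n in enumerate(used)}
        return VascularTree(
            kind=tree.kind,
            nodes=nodes[used],
            edge_parent=np.array([remap[int(x)] for x in p]),
            edge_child=np.array([remap[int(x)] for x in c]),
            radius=r,
        )

    changed = True
    while changed:
        changed = False
        t = build()
        lengths = t.lengths
        term = set(t.terminal_edges.tolist())
        root = t.root_edge
        for e in np.argsort(lengths):
            if lengths[e] >= min_length:
                break
            if e == root:
                if len(edges) == 1:
                    raise ValueError("pruning would remove the root edge")
                continue  # never prune/contract the root edge itself
            p, c, r = edges[e]
            if e in term:
                edges.pop(e)
            else:
                # contract: merge child node c into parent node p
                edges.pop(e)
                edges = [
                    (p if ep == c else ep, ec, er) for (ep, ec, er) in edges
                ]
            changed = True
            break

    out = build()
    if q_liv is not None:
        out = assign_flows(out, q_liv)
    return out


# --------------------------------------------------------------------- I/O
def tree_to_json(tree: VascularTree, path: str | None = None) -> str:
    doc = {
        "kind": tree.kind,
        "nodes": tree.nodes.tolist(),
        "edges": [
            {"parent": int(p), "child": int(c), "radius": float(r)}
            for p, c, r in zip(tree.edge_parent, tree.edge_child, tree.radius)
        ],
    }
    if tree.flow is not None:
        for d, q in zip(doc["edges"], tree.flow):
            d["flow"] = float(q)
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tree_from_json(source: str) -> VascularTree:
    """Load a tree from a JSON document (path or literal JSON text)."""
    if source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    edges = doc["edges"]
    flow = None
    if edges and "flow" in edges[0]:
        flow = np.array([e["flow"] for e in edges])
    return VascularTree(
        kind=doc["kind"],
        nodes=np.asarray(doc["nodes"], dtype=float),
        edge_parent=np.array([e["parent"] for e in edges]),
        edge_child=np.array([e["child"] for e in edges]),
        radius=np.array([e["radius"] for e in edges]),
        flow=flow,
    )


def tree_to_vtk(tree: VascularTree, path: str) -> None:
    """Export centerlines as legacy-ASCII VTK polydata (visualization only)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "hepatoflow vascular tree",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(tree.nodes)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in tree.nodes]
    lines.append(f"LINES {tree.n_edges} {3 * tree.n_edges}")
    lines += [
        f"2 {int(p)} {int(c)}" for p, c in zip(tree.edge_parent, tree.edge_child)
    ]
    lines += [
        f"CELL_DATA {tree.n_edges}",
        "SCALARS radius float 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{r:.6g}" for r in tree.radius]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def dyadic_tree(
    depth: int,
    edge_length: float = 2.0,
    r_leaf: float = 0.1,
    gamma: float = 3.0,
    kind: str = SUPPLYING,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    direction: int = +1,
) -> VascularTree:
    """Perfectly symmetric binary tree with 2**depth leaves.

    Grows along +x (or -x for ``direction=-1``); siblings split in y.  All
    edges have the same length, so root-to-leaf path length is
    (depth + 1) * edge_length, making transit times analytic.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    origin = np.asarray(origin, dtype=float)
    nodes = [origin]
    ep, ec = [], []
    frontier = [0]
    span = edge_length * 2.0 ** max(depth - 1, 0)
    for level in range(depth + 1):
        new_frontier = []
        for node in frontier:
            base = nodes[node]
            if level == 0:
                offsets = [np.array([direction * edge_length, 0.0, 0.0])]
            else:
                dy = span / 2.0**level
                offsets = [
                    np.array([direction * edge_length, +dy, 0.0]),
                    np.array([direction * edge_length, -dy, 0.0]),
                ]
            for off in offsets:
                nodes.append(base + off)
                ep.append(node)
                ec.append(len(nodes) - 1)
                new_frontier.append(len(nodes) - 1)
        frontier = new_frontier
    tree = VascularTree(
        kind=kind,
        nodes=np.asarray(nodes),
        edge_parent=np.asarray(ep),
        edge_child=np.asarray(ec),
        radius=np.ones(len(ep)),
    )
    return tree.with_murray_radii(r_leaf, gamma)
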