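import numpy as np
import pytest

from hepatoflow.geometry.mask import OrganMask
from hepatoflow.geometry.tree import DRAINING, SUPPLYING, VascularTree, assign_flows


@pytest.fixture(scope="session")
def box_mask() -> OrganMask:
    """A solid 16^3 box (with one-voxel background rim), spacing 0.5 mm."""
    occ = np.zeros((18, 18, 18), dtype=bool)
    occ[1:-1, 1:-1, 1:-1] = True
    return OrganMask(spacing=0.5, occupancy=occ)


def random_tree(rng: np.random.Generator, kind: str = SUPPLYING,
                max_depth: int = 4, q_liv: float = 5.0) -> VascularTree:
    """Random bifurcative tree with positive radii/lengths, flow-assigned."""
    nodes = [np.zeros(3), np.array([1.0 + rng.random(), 0.0, 0.0])]
    ep, ec = [0], [1]
    leaves = [1]
    n_splits = rng.integers(1, 2 ** max_depth)
    for _ in range(n_splits):
        parent = int(rng.choice(leaves))
        leaves.remove(parent)
        for _ in range(2):
            step = rng.uniform(0.3, 2.0, size=3) * rng.choice([-1, 1], size=3)
            nodes.append(nodes[parent] + step + np.array([1.0, 0, 0]))
            ep.append(parent)
            ec.append(len(nodes) - 1)
            leaves.append(len(nodes) - 1)
    tree = VascularTree(
        kind=kind, nodes=np.asarray(nodes), edge_parent=ep, edge_child=ec,
        radius=rng.uniform(0.05, 0.4, size=len(ep)),
    )
    return assign_flows(tree, q_liv)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
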