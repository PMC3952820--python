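"""Organ masks, viscosity law, flow assignment, pruning, tree I/O."""

import json

import numpy as np
import pytest

from hepatoflow.geometry import (
    OrganMask,
    ViscosityModel,
    assign_flows,
    dyadic_tree,
    effective_viscosity,
    generate_synthetic_mask,
    prune_and_contract,
    tree_from_json,
    tree_to_json,
    tree_to_vtk,
)
from hepatoflow.geometry.tree import VascularTree


class TestSyntheticMask:
    def test_volume_matches_analytic_ellipsoid(self):
        mask = generate_synthetic_mask((8, 6, 4), 0.5)
        analytic = 4.0 / 3.0 * np.pi * 8 * 6 * 4
        assert abs(mask.volume - analytic) / analytic < 0.05

    def test_volume_is_count_times_h3(self):
        mask = generate_synthetic_mask((8, 6, 4), 0.5)
        assert mask.volume == mask.n_foreground * 0.5**3

    def test_two_lobes_split_by_plane(self):
        mask = generate_synthetic_mask((8, 6, 4), 0.5, lobe_split_plane=(1, 1.5))
        labels = np.unique(mask.lobe_label[mask.occupancy])
        assert set(labels) == {1, 2}
        assert np.all((mask.lobe_label > 0) == mask.occupancy)

    def test_deterministic(self):
        a = generate_synthetic_mask((8, 6, 4), 0.5, seed=3)
        b = generate_synthetic_mask((8, 6, 4), 0.5, seed=3)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.lobe_label, b.lobe_label)

    def test_degenerate_spacing_errors(self):
        with pytest.raises(ValueError):
            generate_synthetic_mask((2, 2, 2), 5.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_synthetic_mask((0, 1, 1), 0.5)
        with pytest.raises(ValueError):
            OrganMask(spacing=0.5, occupancy=np.zeros((3, 3, 3), dtype=bool))


class TestViscosity:
    def test_large_vessel_asymptote(self):
        # oracle: the law evaluated deep in its large-diameter plateau
        asymptote = effective_viscosity(100.0)
        assert abs(effective_viscosity(2.0) - asymptote) / asymptote < 0.01

    def test_decreases_towards_capillary_radii(self):
        assert effective_viscosity(0.010) < effective_viscosity(0.500)

    def test_positive_over_wide_radius_range(self):
        radii = np.geomspace(1e-3, 10.0, 50)
        assert np.all(effective_viscosity(radii) > 0)

    def test_nonpositive_radius_errors(self):
        with pytest.raises(ValueError):
            effective_viscosity(0.0)

    def test_hematocrit_validation(self):
        with pytest.raises(ValueError):
            ViscosityModel(hematocrit=1.2)


class TestFlowAssignment:
    def test_equal_leaf_flows_dyadic(self):
        tree = assign_flows(dyadic_tree(3), 8.0)
        assert np.allclose(tree.flow[tree.terminal_edges], 1.0)

    def test_root_flow_equals_total(self, rng):
        from conftest import random_tree

        tree = random_tree(rng, q_liv=7.3)
        assert tree.flow[tree.root_edge] == pytest.approx(7.3, rel=1e-14)

    def test_doubling_flow_doubles_velocity(self):
        t1 = assign_flows(dyadic_tree(2), 4.0)
        t2 = assign_flows(dyadic_tree(2), 8.0)
        assert np.allclose(2 * t1.velocity, t2.velocity, rtol=1e-14)

    def test_junction_conservation_exact(self, rng):
        from conftest import random_tree

        for _ in range(20):
            tree = random_tree(rng)
            tree.validate()  # includes junction-sum check at 1e-12 relative

    def test_zero_radius_errors(self):
        tree = dyadic_tree(1)
        tree.radius[0] = 0.0
        with pytest.raises(ValueError):
            assign_flows(tree, 1.0)


class TestPruneAndContract:
    def test_zero_min_length_is_identity(self):
        tree = assign_flows(dyadic_tree(2), 4.0)
        out = prune_and_contract(tree, 0.0)
        assert out.n_edges == tree.n_edges
        assert np.allclose(out.flow, tree.flow)

    def test_short_terminal_pruned_and_flow_resplit(self):
        # 3 leaves: one short (0.1 mm) terminal edge; pruning it re-splits
        # the equal leaf flow among the remaining 2 leaves
        nodes = np.array([
            [0, 0, 0], [1, 0, 0], [2, 1, 0], [2, -1, 0], [2.08, 1.06, 0],
        ], dtype=float)
        tree = VascularTree(
            kind="supplying", nodes=nodes,
            edge_parent=[0, 1, 1, 2], edge_child=[1, 2, 3, 4],
            radius=[0.3, 0.2, 0.2, 0.1],
        )
        tree = assign_flows(tree, 6.0)
        assert np.allclose(tree.flow[tree.terminal_edges], 3.0)
        out = prune_and_contract(tree, 0.2)
        assert out.n_leaves == 2
        assert np.allclose(out.flow[out.terminal_edges], 3.0)
        assert np.all(out.lengths >= 0.2)

    def test_interior_contraction_creates_multifurcation(self):
        # short interior edge between two bifurcations -> 3 children
        nodes = np.array([
            [0, 0, 0], [1, 0, 0], [1.05, 0, 0],
            [2, 1, 0], [2, -1, 0], [2, 0, 1],
        ], dtype=float)
        tree = VascularTree(
            kind="supplying", nodes=nodes,
            edge_parent=[0, 1, 1, 2, 2], edge_child=[1, 2, 3, 4, 5],
            radius=[0.3, 0.25, 0.2, 0.2, 0.2],
        )
        tree = assign_flows(tree, 9.0)
        out = prune_and_contract(tree, 0.2)
        out.validate()
        kids = out.children_of_node()
        assert max(len(k) for k in kids) == 3
        assert out.flow[out.root_edge] == pytest.approx(9.0)

    def test_pruning_root_errors(self):
        tree = VascularTree(
            kind="supplying", nodes=[[0, 0, 0], [0.05, 0, 0]],
            edge_parent=[0], edge_child=[1], radius=[0.1],
        )
        with pytest.raises(ValueError):
            prune_and_contract(tree, 1.0)


class TestMaskIO:
    def test_nifti_roundtrip(self, tmp_path):
        from hepatoflow.geometry import load_mask_nifti, save_mask_nifti

        mask = generate_synthetic_mask((4, 3, 2), 0.5, lobe_split_plane=(1, 0.5))
        path = str(tmp_path / "mask.nii.gz")
        save_mask_nifti(mask, path)
        back = load_mask_nifti(path)
        assert back.spacing == pytest.approx(mask.spacing)
        assert np.array_equal(back.occupancy, mask.occupancy)
        assert np.array_equal(back.lobe_label, mask.lobe_label)

    def test_scalar_field_export(self, tmp_path):
        import nibabel as nib

        from hepatoflow.geometry import save_scalar_nifti

        field = np.random.default_rng(0).random((5, 4, 3))
        path = str(tmp_path / "field.nii.gz")
        save_scalar_nifti(field, 0.5, path)
        img = nib.load(path)
        assert np.allclose(np.asarray(img.dataobj), field, atol=1e-6)


class TestTreeIO:
    def test_json_roundtrip(self, rng):
        from conftest import random_tree

        tree = random_tree(rng)
        doc = tree_to_json(tree)
        back = tree_from_json(doc)
        assert np.allclose(back.nodes, tree.nodes)
        assert np.array_equal(back.edge_parent, tree.edge_parent)
        assert np.allclose(back.radius, tree.radius)
        assert np.allclose(back.flow, tree.flow)
        json.loads(doc)  # valid JSON

    def test_vtk_export(self, tmp_path):
        tree = dyadic_tree(2)
        path = tmp_path / "tree.vtk"
        tree_to_vtk(tree, str(path))
        text = path.read_text()
        assert "POLYDATA" in text and f"LINES {tree.n_edges}" in text


class TestMurrayRadii:
    def test_parent_radius_follows_power_law(self):
        tree = dyadic_tree(2, r_leaf=0.1, gamma=3.0)
        kids = tree.children_of_node()
        for e in range(tree.n_edges):
            ch = kids[tree.edge_child[e]]
            if ch:
                expected = sum(tree.radius[c] ** 3 for c in ch) ** (1 / 3)
                assert tree.radius[e] == pytest.approx(expected, rel=1e-12)
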