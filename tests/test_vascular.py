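"""1D intravascular advection: transit times, junction rules, mass ledger."""

import numpy as np
import pytest

from conftest import random_tree
from hepatoflow.geometry.tree import (
    DRAINING,
    SUPPLYING,
    VascularTree,
    assign_flows,
    dyadic_tree,
)
from hepatoflow.vascular import (
    InflowProfile,
    TreeAdvectionSystem,
    dvs_leaf_inflow,
    terminal_outflow_to_hhs,
)


def single_tube(length=10.0, radius=0.5, v=2.0, kind=SUPPLYING) -> VascularTree:
    q = v * np.pi * radius**2
    tree = VascularTree(
        kind=kind, nodes=[[0, 0, 0], [length, 0, 0]],
        edge_parent=[0], edge_child=[1], radius=[radius],
    )
    return assign_flows(tree, q)


class TestInflowProfile:
    def test_phase_split_respects_partition(self):
        prof = InflowProfile.plug(10.0, 5.0, k_rbc_pls=2.0, hematocrit=0.4)
        c_rbc, c_pls = prof.phase_concentrations(1.0)
        assert c_rbc == pytest.approx(2.0 * c_pls)
        assert 0.4 * c_rbc + 0.6 * c_pls == pytest.approx(10.0)

    def test_finite_support(self):
        prof = InflowProfile.plug(10.0, 5.0)
        assert prof.c_blood(6.0) == 0.0 and prof.c_blood(4.0) == 10.0

    def test_dose_to_concentration(self):
        # 1 µmol/kg on 0.025 kg at Q=30 mm^3/s over 10 s: 25 nmol over
        # 300 mm^3 of blood -> 0.0833 nmol/mm^3 = 83.3 µmol/L
        prof = InflowProfile.from_dose(1.0, 0.025, 30.0, 10.0)
        assert prof.c_blood(0.0) == pytest.approx(25.0 / 300.0)


class TestAdvection:
    def test_constant_state_is_steady(self):
        sys = TreeAdvectionSystem(single_tube(), dx_target=1.0)
        sys.c[:] = 5.0
        prof = InflowProfile.plug(5.0, 1e9, k_rbc_pls=1.0, hematocrit=0.45)
        for _ in range(10):
            sys.step(0.7, prof)
        assert np.allclose(sys.c, 5.0, atol=1e-12)

    def test_plug_front_exits_at_transit_time(self):
        # L/v = 5 s; median arrival of the plug mass within one cell transit
        tube = single_tube(length=10.0, v=2.0)
        sys = TreeAdvectionSystem(tube, dx_target=0.5)
        prof = InflowProfile.plug(1.0, 0.5, k_rbc_pls=1.0, hematocrit=0.45)
        dt = 0.05
        t, masses, times = 0.0, [], []
        for _ in range(300):
            rec = sys.step(dt, prof, t0=t)
            t += dt
            masses.append(rec["outflow_mass"].sum())
            times.append(t)
        masses = np.array(masses)
        cum = np.cumsum(masses)
        total = cum[-1]
        arrival = times[int(np.searchsorted(cum, 0.5 * total))]
        cell_transit = (10.0 / 20) / 2.0  # dx / v
        # plug center injected at 0.25 s, so expected median exit 5.25 s
        assert abs(arrival - 5.25) <= cell_transit + dt

    def test_draining_junction_flow_weighted_mixing(self):
        # child flows 3:1 with concentrations 4 and 0 -> merged value 3
        nodes = np.array([[0, 0, 0], [2, 0, 0], [4, 1, 0], [4, -1, 0]], float)
        tree = VascularTree(
            kind=DRAINING, nodes=nodes, edge_parent=[0, 1, 1],
            edge_child=[1, 2, 3], radius=[0.4, 0.3, 0.2],
        )
        # force 3:1 leaf flows by bypassing the equal-split rule
        tree.flow = np.array([4.0, 3.0, 1.0])
        sys = TreeAdvectionSystem(tree, dx_target=1.0)
        bc = np.array([[4.0, 0.0], [4.0, 0.0]])
        for _ in range(200):
            rec = sys.step(0.05, bc)
        assert np.allclose(rec["outflow_concentration"], 3.0, rtol=1e-10)

    def test_mass_ledger_closes_on_random_trees(self, rng):
        for kind in (SUPPLYING, DRAINING):
            for _ in range(30):
                tree = random_tree(rng, kind=kind)
                sys = TreeAdvectionSystem(tree, dx_target=0.8)
                n_term = len(sys.terminal_edges)
                stored0 = sys.stored_mass().sum()
                total_in = total_out = 0.0
                for k in range(5):
                    if kind == SUPPLYING:
                        inflow = InflowProfile.plug(
                            float(rng.uniform(0.5, 5)), 0.2, hematocrit=0.45
                        )
                    else:
                        inflow = rng.uniform(0, 3, size=(2, n_term))
                    rec = sys.step(0.1, inflow, t0=0.0)
                    total_in += rec["inflow_mass"].sum()
                    total_out += rec["outflow_mass"].sum()
                stored = sys.stored_mass().sum()
                resid = total_in - total_out - (stored - stored0)
                assert abs(resid) <= 1e-10 * max(total_in, 1.0)

    def test_nonnegativity_preserved(self, rng):
        tree = random_tree(rng)
        sys = TreeAdvectionSystem(tree, dx_target=0.5)
        sys.c[:] = rng.uniform(0, 2, size=sys.c.shape)
        prof = InflowProfile.plug(3.0, 0.3, hematocrit=0.45)
        for _ in range(20):
            sys.step(0.2, prof)
        assert np.all(sys.c >= 0)

    def test_numerical_diffusion_shrinks_with_refinement(self):
        # temporal spread of the exit pulse decreases as the sub-grid refines
        widths = []
        for dx in (2.0, 1.0, 0.5):
            sys = TreeAdvectionSystem(single_tube(length=10.0, v=2.0), dx_target=dx)
            prof = InflowProfile.plug(1.0, 0.5, hematocrit=0.45)
            dt, t = 0.05, 0.0
            ts, ms = [], []
            for _ in range(400):
                rec = sys.step(dt, prof, t0=t)
                t += dt
                ts.append(t)
                ms.append(rec["outflow_mass"].sum())
            ms, ts = np.array(ms), np.array(ts)
            mean = np.sum(ts * ms) / ms.sum()
            widths.append(np.sqrt(np.sum((ts - mean) ** 2 * ms) / ms.sum()))
        assert widths[0] > widths[1] > widths[2]

    def test_rbc_pls_stay_proportional(self):
        sys = TreeAdvectionSystem(single_tube(), dx_target=0.5)
        prof = InflowProfile.plug(1.0, 2.0, k_rbc_pls=2.0, hematocrit=0.45)
        # proportional inflow: c_rbc = 2 c_pls at all times
        for k in range(100):
            sys.step(0.1, prof, t0=0.1 * k)
        assert np.allclose(sys.c[0], 2.0 * sys.c[1], rtol=1e-12, atol=1e-15)

    def test_zero_flow_edge_rejected(self):
        tree = single_tube()
        tree.flow = np.array([0.0])
        with pytest.raises(ValueError):
            TreeAdvectionSystem(tree)

    def test_negative_dt_rejected(self):
        sys = TreeAdvectionSystem(single_tube())
        with pytest.raises(ValueError):
            sys.step(-1.0, InflowProfile.plug(1.0, 1.0))


class TestTerminalCoupling:
    def test_uniform_line_density(self):
        # terminal edge passing 2 nmol/s over 4 mm -> 0.5 nmol/(s mm)
        tube = single_tube(length=4.0, v=2.0)
        sys = TreeAdvectionSystem(tube, dx_target=0.5)
        sys.c[:] = 1.0  # with Q = v pi r^2 = 1.5708 mm^3/s per phase split
        prof = InflowProfile.plug(1.0, 1e9, k_rbc_pls=1.0, hematocrit=0.45)
        dt = 0.5
        rec = sys.step(dt, prof)
        dens = terminal_outflow_to_hhs(sys, rec, dt)
        q = tube.flow[0]
        assert dens.sum() == pytest.approx(q * 1.0 / 4.0, rel=1e-12)
        # zero concentration -> zero source
        sys.c[:] = 0.0
        rec = sys.step(dt, InflowProfile.plug(0.0, 1.0), t0=1e10)
        assert np.allclose(terminal_outflow_to_hhs(sys, rec, dt), 0.0)

    def test_steady_state_source_sum_equals_inflow_rate(self):
        tree = assign_flows(dyadic_tree(2, edge_length=1.0), 4.0)
        sys = TreeAdvectionSystem(tree, dx_target=0.5)
        prof = InflowProfile.plug(2.0, 1e9, k_rbc_pls=1.0, hematocrit=0.45)
        for k in range(300):
            rec = sys.step(0.1, prof, t0=0.1 * k)
        dens = terminal_outflow_to_hhs(sys, rec, 0.1)
        lengths = tree.lengths[sys.terminal_edges]
        total_rate = float((dens * lengths[None]).sum())
        assert total_rate == pytest.approx(4.0 * 2.0, rel=1e-8)

    def test_draining_only_error(self):
        sys = TreeAdvectionSystem(single_tube(kind=DRAINING), dx_target=1.0)
        rec = sys.step(0.1, np.zeros((2, 1)))
        with pytest.raises(ValueError):
            terminal_outflow_to_hhs(sys, rec, 0.1)


class TestDvsLeafInflow:
    def test_constant_leaf_feed_converges_to_same_outflow(self):
        tree = assign_flows(dyadic_tree(3, edge_length=1.0, kind=DRAINING), 8.0)
        sys = TreeAdvectionSystem(tree, dx_target=0.5)
        bc = dvs_leaf_inflow(sys, np.full(8, 3.0))
        # run past the longest root-to-leaf transit time
        transit = float(np.sum(tree.lengths / tree.velocity))
        t, n = 0.0, 0
        while t < 3 * transit:
            rec = sys.step(0.1, bc)
            t += 0.1
        assert np.allclose(rec["outflow_concentration"], 3.0, rtol=1e-9)

    def test_zero_everywhere_zero_outflow(self):
        tree = assign_flows(dyadic_tree(2, kind=DRAINING), 4.0)
        sys = TreeAdvectionSystem(tree, dx_target=1.0)
        rec = sys.step(1.0, dvs_leaf_inflow(sys, np.zeros(4)))
        assert rec["outflow_mass"].sum() == 0.0

    def test_single_hot_leaf_flow_weighted(self):
        tree = assign_flows(dyadic_tree(2, edge_length=1.0, kind=DRAINING), 4.0)
        sys = TreeAdvectionSystem(tree, dx_target=0.5)
        vals = np.zeros(4)
        vals[0] = 8.0
        bc = dvs_leaf_inflow(sys, vals)
        for _ in range(500):
            rec = sys.step(0.1, bc)
        # leaf carries Q/4 of the total -> root outflow 8 * 1/4 = 2
        assert np.allclose(rec["outflow_concentration"], 2.0, rtol=1e-9)

    def test_count_mismatch_errors(self):
        tree = assign_flows(dyadic_tree(2, kind=DRAINING), 4.0)
        sys = TreeAdvectionSystem(tree, dx_target=1.0)
        with pytest.raises(ValueError):
            dvs_leaf_inflow(sys, np.zeros(3))
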