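"""PBPK exchange/metabolization kinetics and the RKF45 integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatoflow.fixtures import default_compounds
from hepatoflow.kinetics import (
    CompoundParams,
    Interface,
    MetabolismParams,
    VolumeFractions,
    exchange_rhs,
    metabolization_rate,
    pbpk_rhs,
    rkf45_integrate,
    wellstirred_reference,
)
from hepatoflow.vascular import InflowProfile

F = VolumeFractions()
FARR = F.as_array()


def chain_compound(k_rp=0.7, k_pi=0.9, k_ci=8.0, p=(20.0, 6.0, 2.0)):
    return CompoundParams(
        name="x", mw=300.0, logp=1.0, fu=0.5,
        interfaces=(
            Interface("rbc", "pls", k_rp, p[0]),
            Interface("pls", "int", k_pi, p[1]),
            Interface("cell", "int", k_ci, p[2]),
        ),
    )


def equilibrium_state(comp: CompoundParams, c_int=2.0) -> np.ndarray:
    c_pls = comp.interfaces[1].partition * c_int
    c_rbc = comp.interfaces[0].partition * c_pls
    c_cell = comp.interfaces[2].partition * c_int
    return np.array([c_rbc, c_pls, c_int, c_cell])


class TestExchange:
    def test_zero_rhs_at_interface_equilibria(self):
        comp = chain_compound()
        c = equilibrium_state(comp)
        assert np.all(np.abs(exchange_rhs(c, comp, F)) < 1e-12)

    def test_zero_permeability_zero_rhs(self):
        comp = chain_compound(p=(0.0, 0.0, 0.0))
        c = np.array([5.0, 1.0, 3.0, 0.1])
        assert np.all(exchange_rhs(c, comp, F) == 0.0)

    def test_linearity(self, rng):
        comp = chain_compound()
        a, b = rng.uniform(0, 5, size=(2, 4))
        lhs = exchange_rhs(2.0 * a + 3.0 * b, comp, F)
        rhs = 2.0 * exchange_rhs(a, comp, F) + 3.0 * exchange_rhs(b, comp, F)
        assert np.allclose(lhs, rhs, rtol=0, atol=1e-12 * max(1, np.abs(lhs).max()))

    def test_mass_conserved_exactly(self, rng):
        comp = chain_compound()
        c = rng.uniform(0, 10, size=4)
        d = exchange_rhs(c, comp, F)
        assert abs(float(FARR @ d)) < 1e-12

    def test_two_subspace_relaxation_rate_matches_eigenvalue(self):
        # closed (a,b) system decays to equilibrium at
        # lambda = P (1/f_a + K/f_b)
        K, P = 3.0, 1.5
        comp = CompoundParams(
            name="two", mw=1.0, logp=0.0, fu=1.0,
            interfaces=(Interface("pls", "int", K, P),),
        )
        lam = P * (1.0 / float(F.pls) + K / float(F.int_))
        c0 = np.array([0.0, 4.0, 1.0, 0.0])
        t_end = 2.0 / lam  # two e-foldings of the deviation

        def rhs(_t, y):
            return exchange_rhs(y, comp, F)

        c1 = rkf45_integrate(rhs, c0, (0.0, t_end), tol=1e-10)
        dev0 = c0[1] - K * c0[2]
        dev1 = c1[1] - K * c1[2]
        lam_est = -np.log(dev1 / dev0) / t_end
        assert lam_est == pytest.approx(lam, rel=1e-6)

    def test_zero_fraction_on_active_interface_errors(self):
        comp = chain_compound()
        f = VolumeFractions(rbc=0.0, pls=0.22, int_=0.16, cell=0.55, rest=0.07)
        with pytest.raises(ValueError):
            exchange_rhs(np.ones(4), comp, f)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equilibrium_globally_attracting(self, seed):
        """All eigenvalues of the closed exchange operator have nonpositive
        real part for random valid parameter sets."""
        rng = np.random.default_rng(seed)
        comp = chain_compound(
            k_rp=rng.uniform(0.1, 5), k_pi=rng.uniform(0.1, 5),
            k_ci=rng.uniform(0.1, 30), p=tuple(rng.uniform(0, 30, size=3)),
        )
        A = np.column_stack(
            [exchange_rhs(np.eye(4)[i], comp, F) for i in range(4)]
        )
        assert np.all(np.linalg.eigvals(A).real <= 1e-10)


class TestMetabolization:
    def test_linear_rate(self):
        met = MetabolismParams(mode="linear", k_met=0.1)
        assert metabolization_rate(2.0, met) == pytest.approx(0.2)

    def test_mm_half_saturation(self):
        met = MetabolismParams(mode="michaelis_menten", v_max=8.0, k_m=3.0)
        assert metabolization_rate(3.0, met) == pytest.approx(4.0)

    def test_mm_linear_limit(self):
        met = MetabolismParams(mode="michaelis_menten", v_max=8.0, k_m=3.0)
        c = 3.0 / 1000.0
        linear = 8.0 / 3.0 * c
        assert abs(metabolization_rate(c, met) - linear) / linear < 1e-3

    def test_negative_concentration_errors(self):
        with pytest.raises(ValueError):
            metabolization_rate(-1.0, MetabolismParams(mode="linear", k_met=0.1))

    def test_sink_mass_budget(self, rng):
        """d/dt sum_i f_i c_i = -f_cell * r_met for the combined rhs."""
        comp = chain_compound()
        met = MetabolismParams(mode="michaelis_menten", v_max=5.0, k_m=2.0)
        c = rng.uniform(0, 10, size=4)
        d = pbpk_rhs(c, comp, met, F)
        expected = -float(FARR[3]) * metabolization_rate(c[3], met)
        assert float(FARR @ d) == pytest.approx(expected, rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MetabolismParams(mode="linear", k_met=0.0)
        with pytest.raises(ValueError):
            MetabolismParams(mode="bogus")


class TestRKF45:
    def test_linear_decay_matches_exponential(self):
        c = rkf45_integrate(lambda t, y: -y, np.array([1.0]), (0.0, 1.0), tol=1e-8)
        assert c[0] == pytest.approx(np.exp(-1.0), abs=1e-8)

    def test_zero_rhs_identity(self):
        y0 = np.array([1.0, 2.0])
        y = rkf45_integrate(lambda t, y: 0.0 * y, y0, (0.0, 5.0), tol=1e-6)
        assert np.array_equal(y, y0)

    def test_error_decreases_with_tolerance(self):
        errs = []
        for tol in (1e-4, 1e-6, 1e-8):
            c = rkf45_integrate(lambda t, y: -y, np.array([1.0]), (0.0, 2.0), tol=tol)
            errs.append(abs(c[0] - np.exp(-2.0)))
        assert errs[0] > errs[1] > errs[2]

    def test_step_underflow_raises(self):
        def stiff_blowup(t, y):
            return y / max(1.0 - t, 1e-30) ** 2

        with pytest.raises(RuntimeError):
            rkf45_integrate(stiff_blowup, np.array([1.0]), (0.0, 2.0), tol=1e-10)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            rkf45_integrate(lambda t, y: -y, np.array([1.0]), (0.0, 1.0), tol=0.0)


class TestWellStirred:
    def test_zero_inflow_zero_output(self):
        comp, met = default_compounds()["tracer"]
        inflow = InflowProfile(lambda t: 0.0, comp.k_rbc_pls, float(np.asarray(F.hematocrit)))
        out = wellstirred_reference(30.0, 800.0, F, comp, met, inflow, 20.0, 0.5)
        assert np.allclose(out["c_out"], 0.0)
        assert out["metabolized_mass"] == 0.0

    def test_inert_constant_inflow_converges_to_inflow(self):
        comp, met = default_compounds()["inert"]
        inflow = InflowProfile.plug(
            10.0, 1e9, k_rbc_pls=1.0, hematocrit=float(np.asarray(F.hematocrit))
        )
        out = wellstirred_reference(30.0, 400.0, F, comp, met, inflow, 120.0, 1.0)
        assert out["c_out"][-1] == pytest.approx(10.0, rel=1e-3)

    def test_mass_ledger_closes(self):
        comp, met = default_compounds()["linear_drug"]
        inflow = InflowProfile.plug(
            50.0, 10.0, k_rbc_pls=comp.k_rbc_pls,
            hematocrit=float(np.asarray(F.hematocrit)),
        )
        out = wellstirred_reference(30.0, 800.0, F, comp, met, inflow, 60.0, 0.25)
        resid = out["inflow_mass"] - out["outflow_mass"] - out["stored_mass"] \
            - out["metabolized_mass"]
        assert abs(resid) / out["inflow_mass"] < 5e-3  # trapezoid output flux
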