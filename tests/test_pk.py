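"""Pharmacokinetic layer: rate laws, topology rules, mass balance, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm

import il21pkpd as il
from il21pkpd.pk import (
    PKConfigError,
    PKParams,
    PKState,
    PKTopology,
    degradation_rate,
    pk_rhs,
    transition_rate,
)


class TestRateLaws:
    @pytest.mark.parametrize("x,w,a,expected", [
        (3.0, 2.0, 0.0, 6.0),          # linear limit when alpha = 0
        (1.0, 1.0, 1.0, 0.5),          # direct evaluation of w*x/(1+a*x)
    ])
    def test_transition_examples(self, x, w, a, expected):
        assert transition_rate(x, w, a) == pytest.approx(expected)

    def test_transition_saturates_at_w_over_alpha(self):
        assert transition_rate(1e9, 2.0, 0.5) == pytest.approx(4.0, rel=1e-6)

    @pytest.mark.parametrize("x,d,b,expected", [
        (5.0, 3.0, 0.0, 15.0),
        (2.0, 1.0, 0.5, 1.0),
    ])
    def test_degradation_examples(self, x, d, b, expected):
        assert degradation_rate(x, d, b) == pytest.approx(expected)

    def test_degradation_saturates_at_d_over_beta(self):
        assert degradation_rate(1e9, 3.0, 1.5) == pytest.approx(2.0, rel=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_rate(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            degradation_rate(1.0, -1.0, 0.0)

    @given(x=st.floats(0, 1e6), w=st.floats(0, 100), a=st.floats(0, 10))
    def test_flux_nonnegative_and_below_linear(self, x, w, a):
        j = transition_rate(x, w, a)
        assert 0.0 <= j <= w * x + 1e-9


class TestTopology:
    def test_iv_has_four_compartments_bidirectional_with_plasma(self):
        topo = il.iv_topology()
        assert topo.n_compartments == 4
        assert topo.dosed_compartment == "plasma"
        for sec in ("sec1", "sec2", "sec3"):
            assert ("plasma", sec) in topo.transitions
            assert (sec, "plasma") in topo.transitions

    def test_depot_has_eight_compartments(self):
        topo = il.depot_topology("SC")
        assert topo.n_compartments == 8
        assert topo.dosed_compartment == "depot"

    def test_wrong_compartment_count_rejected(self):
        with pytest.raises(PKConfigError):
            PKTopology("IV", ("plasma", "sec1", "sec2"),
                       (("plasma", "sec1"), ("plasma", "sec2")), ())

    def test_unreachable_compartment_rejected(self):
        with pytest.raises(PKConfigError, match="unreachable"):
            PKTopology("IV", ("plasma", "sec1", "sec2", "sec3"),
                       (("plasma", "sec1"), ("plasma", "sec2")), ())

    def test_missing_rate_is_configuration_error(self):
        topo = il.iv_topology()
        par = il.default_pk_params("IV")
        del par.w[("plasma", "sec1")]
        with pytest.raises(PKConfigError, match="missing transition rate"):
            par.validate(topo)

    def test_yaml_round_trip(self, tmp_path):
        topo = il.depot_topology("IP")
        par = il.default_pk_params("IP")
        path = tmp_path / "pk.yaml"
        il.dump_pk_yaml(path, topo, par)
        topo2, par2 = il.load_pk_yaml(path)
        assert topo2 == topo
        assert par2.w == par.w and par2.d == par.d
        assert par2.s == par.s and par2.v_plasma == par.v_plasma


class TestRHS:
    def test_empty_system_has_zero_derivatives(self):
        topo = il.iv_topology()
        par = il.default_pk_params("IV")
        d = pk_rhs(PKState(np.zeros(4)), topo, par)
        assert np.all(d.amounts == 0) and d.degraded == 0

    def test_single_transition_is_antisymmetric(self):
        topo = PKTopology("IV", ("plasma", "sec1", "sec2", "sec3"),
                          (("plasma", "sec1"), ("plasma", "sec2"),
                           ("plasma", "sec3")), ())
        par = PKParams(w={("plasma", "sec1"): 2.0, ("plasma", "sec2"): 0.0,
                          ("plasma", "sec3"): 0.0},
                       alpha={}, d={}, beta={}, s=10.0)
        d = pk_rhs(PKState(np.array([4.0, 0, 0, 0])), topo, par)
        assert d.amounts[0] == pytest.approx(-8.0)
        assert d.amounts[1] == pytest.approx(8.0)
        assert d.amounts.sum() == pytest.approx(0.0)

    def test_total_derivative_equals_minus_degradation(self, rng):
        topo = il.iv_topology()
        par = il.default_pk_params("IV")
        x = rng.uniform(0, 10, 4)
        d = pk_rhs(PKState(x), topo, par)
        total_deg = sum(degradation_rate(x[topo.index(c)], par.d[c],
                                         par.beta.get(c, 0.0))
                        for c in topo.degradations)
        assert d.amounts.sum() == pytest.approx(-total_deg, rel=1e-12)
        assert d.degraded == pytest.approx(total_deg, rel=1e-12)


class TestConcentrations:
    @pytest.mark.parametrize("x0,v,expected", [(50.0, 2.0, 25.0), (0.0, 2.0, 0.0),
                                               (1.0, 2.0, 0.5)])
    def test_plasma_concentration(self, x0, v, expected):
        par = PKParams(s=10.0, v_plasma=v)
        assert il.plasma_concentration(x0, par) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            il.plasma_concentration(1.0, PKParams(s=10.0, v_plasma=0.0))

    @pytest.mark.parametrize("c,s,expected", [(25.0, 1.0, 25.0), (25.0, 100.0, 0.25),
                                              (0.0, 50.0, 0.0)])
    def test_tissue_concentration(self, c, s, expected):
        assert il.tissue_concentration(c, s) == pytest.approx(expected)

    def test_tissue_below_plasma_and_warns_below_one(self):
        assert il.tissue_concentration(10.0, 4.0) <= 10.0
        with pytest.warns(UserWarning):
            il.tissue_concentration(10.0, 0.5)


class TestSystemInvariants:
    def test_mass_balance_under_arbitrary_regimens(self, sc_model):
        for reg in [il.standard_b16_regimen(),
                    il.Regimen("SC", 13.7, 1.3, 0.37, 11),
                    il.Regimen("SC", 200.0, 0.0, 2.0, 5)]:
            traj = il.simulate_therapy(reg, sc_model.topology,
                                       sc_model.pk_params, sc_model.pd_params,
                                       t_end=12.0, dt=0.002)
            assert traj.mass_balance_error() < 1e-6

    def test_mass_balance_iv(self, iv_setup):
        topo, par = iv_setup
        traj = il.simulate_single_dose(topo, par, 50.0, 3.0)
        assert traj.mass_balance_error() < 1e-6

    def test_linear_limit_matches_matrix_exponential(self, iv_setup):
        """With alpha=beta=0 the PK system is linear; dense RK4 output must
        match the closed-form matrix-exponential solution to 1e-6."""
        topo, par = iv_setup
        par = par.copy()
        par.alpha = {k: 0.0 for k in par.w}
        par.beta = {c: 0.0 for c in par.d}
        n = topo.n_compartments
        A = np.zeros((n, n))
        for (a, b) in topo.transitions:
            i, j = topo.index(a), topo.index(b)
            A[i, i] -= par.w[(a, b)]
            A[j, i] += par.w[(a, b)]
        for c in topo.degradations:
            i = topo.index(c)
            A[i, i] -= par.d[c]
        traj = il.simulate_single_dose(topo, par, 50.0, 1.0, dt=0.002)
        x0 = np.zeros(n)
        x0[topo.plasma_index] = 50.0
        for t_probe in (0.1, 0.4, 1.0):
            idx = np.argmin(np.abs(traj.times - t_probe))
            exact = expm(A * traj.times[idx]) @ x0
            rel = np.abs(traj.pk_amounts[idx] - exact) / max(np.abs(exact).max(), 1e-12)
            assert rel.max() < 1e-6

    def test_amounts_never_meaningfully_negative(self, std_trajectory):
        assert std_trajectory.pk_amounts.min() > -1e-9

    def test_auc_nondecreasing_in_dose(self, sc_model):
        aucs = []
        for dose in (5.0, 20.0, 50.0, 150.0):
            traj = il.simulate_single_dose(sc_model.topology, sc_model.pk_params,
                                           dose, 3.0, dt=0.005)
            aucs.append(np.trapezoid(traj.plasma_conc, traj.times))
        assert np.all(np.diff(aucs) > 0)
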