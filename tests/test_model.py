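"""Model-equation unit and property tests.

Derived expectations are checked against independent term-by-term
arithmetic or numerical integration oracles written out in the tests
themselves, never against the functions under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from glucagon_challenge import (
    FixedKinetics,
    Protocol,
    SubjectParameters,
    apply_baseline_constraints,
    eliminate_baseline_params,
    glucose_rhs,
    hgp_rate,
    hormone_trajectory,
    make_baseline,
    receptor_rhs,
    receptor_steady_state,
    system_rhs,
)
from glucagon_challenge.model import DegenerateModelError

# cohort-average subject constants
AVG = dict(b_G=0.0804, V_1=5.63, K1_prime=0.00501, k_in=21.5, V_h=4.65)


class TestHgpRate:
    def test_vanishes_to_basal_rate_without_bound_receptor(self):
        p = SubjectParameters(**AVG)
        assert hgp_rate(0.0, p) == pytest.approx(p.b_G)

    @pytest.mark.parametrize("k1p", [1e-4, 0.00501, 0.3])
    def test_half_maximal_at_apparent_dissociation_constant(self, k1p):
        p = SubjectParameters(**{**AVG, "K1_prime": k1p})
        assert hgp_rate(k1p, p) == pytest.approx(p.b_G + p.V_1 / 2)

    def test_average_subject_basal_value(self):
        # independent arithmetic: 0.0804 + 5.63 * x / (0.00501^2 + x), x = 0.0037^2
        x = 0.0037 * 0.0037
        expected = 0.0804 + 5.63 * x / (0.00501 * 0.00501 + x)
        p = SubjectParameters(**AVG)
        assert hgp_rate(0.0037, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.0674, abs=5e-5)

    def test_monotone_and_bounded(self):
        p = SubjectParameters(**AVG)
        re = np.linspace(0, 1, 400)
        vals = hgp_rate(re, p)
        assert np.all(np.diff(vals) >= 0)
        assert np.all(vals <= p.b_G + p.V_1 + 1e-12)

    def test_rejects_negative_bound_fraction(self):
        with pytest.raises(ValueError):
            hgp_rate(-0.1, SubjectParameters())


class TestReceptorSteadyState:
    def test_no_ligand_all_receptor_free(self, fixed):
        r, re = receptor_steady_state(0.0, SubjectParameters(), fixed)
        assert (r, re) == (1.0, 0.0)

    def test_average_subject_values_against_ode_oracle(self, fixed):
        """Closed form equals the long-time limit of the receptor ODE
        integrated from several initial conditions at constant glucagon."""
        p = SubjectParameters(**AVG)
        r_bar, re_bar = receptor_steady_state(14.3, p, fixed)
        assert r_bar == pytest.approx(0.555, abs=5e-4)
        assert re_bar == pytest.approx(0.0037, abs=5e-5)
        for r0, re0 in [(1.0, 0.0), (0.2, 0.1), (0.0, 0.0)]:
            sol = solve_ivp(
                lambda t, y: receptor_rhs(y[0], y[1], 14.3, p, fixed),
                (0.0, 400.0), [r0, re0], method="LSODA",
                rtol=1e-10, atol=1e-12)
            assert sol.y[0][-1] == pytest.approx(r_bar, abs=1e-8)
            assert sol.y[1][-1] == pytest.approx(re_bar, abs=1e-8)

    def test_is_exact_fixed_point(self, fixed):
        p = SubjectParameters(**AVG)
        r, re = receptor_steady_state(14.3, p, fixed)
        dr, dre = receptor_rhs(r, re, 14.3, p, fixed)
        assert abs(dr) < 1e-14 and abs(dre) < 1e-14

    def test_degenerate_kinetics_rejected(self):
        dead = FixedKinetics(k_on=0, k_off=0, k_rec=0)
        with pytest.raises(DegenerateModelError):
            receptor_steady_state(10.0, SubjectParameters(k_in=0), dead)

    @given(
        E=st.floats(0.0, 200.0),
        k_in=st.floats(0.01, 100.0),
        V_h=st.floats(0.1, 50.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_fractions_of_conserved_total(self, E, k_in, V_h):
        fixed = FixedKinetics()
        p = SubjectParameters(k_in=k_in, V_h=V_h)
        r, re = receptor_steady_state(E, p, fixed)
        assert 0.0 <= r <= 1.0 and 0.0 <= re <= 1.0
        assert r + re <= 1.0 + 1e-12


class TestReceptorRhs:
    def test_empty_ligand_equilibrium(self, fixed):
        assert receptor_rhs(1.0, 0.0, 0.0, SubjectParameters(), fixed) == (0.0, 0.0)

    def test_term_by_term_hand_evaluation(self, fixed):
        p = SubjectParameters(**AVG)
        r, re, E = 0.5, 0.01, 36.8
        a = 0.0036 * 4.65 * 36.8          # binding rate k_on * V_h * E
        dr_hand = -a * r + 14.4 * re + 0.18 * (1 - r - re)
        dre_hand = a * r - 14.4 * re - 21.5 * re
        dr, dre = receptor_rhs(r, re, E, p, fixed)
        assert dr == pytest.approx(dr_hand, rel=1e-12)
        assert dre == pytest.approx(dre_hand, rel=1e-12)

    def test_conserves_total_receptor(self, fixed):
        # d(r + r_e + r_i)/dt = 0 by construction: dr + dre = -(internalized flux) + recycling
        p = SubjectParameters(**AVG)
        r, re = 0.3, 0.02
        dr, dre = receptor_rhs(r, re, 20.0, p, fixed)
        dri = p.k_in * re + fixed.k_in_free * r - fixed.k_rec * (1 - r - re)
        assert dr + dre + dri == pytest.approx(0.0, abs=1e-15)


class TestHormoneTrajectory:
    def test_continuous_at_switch_and_baseline_before(self):
        t = np.array([0.0, 1.5, 2.999, 3.0])
        vals = hormone_trajectory(t, 14.3, 4134.7, 19.6, 5.73, t_switch=3.0)
        assert np.allclose(vals, 14.3)

    @pytest.mark.parametrize(
        "baseline,Q,V,k,plateau",
        [(14.3, 4134.7, 19.6, 5.73, 4134.7 / (19.6 * 5.73)),   # ~36.8 pmol/L
         (10.0, 480.0, 1.52, 30.5, 480.0 / (1.52 * 30.5))],    # ~10.35 mU/L
    )
    def test_plateau_matches_infusion_balance(self, baseline, Q, V, k, plateau):
        assert hormone_trajectory(1e3, baseline, Q, V, k) == pytest.approx(plateau)
        # design anchor: glucagon rises 2-3-fold over its basal 14.3 pmol/L
        if Q > 1000:
            assert 2.0 < plateau / 14.3 < 3.0

    def test_agrees_with_numeric_integration(self):
        k, Q, V, c0 = 5.73, 4134.7, 19.6, 14.3
        sol = solve_ivp(lambda t, y: [Q / V - k * y[0]], (3.0, 6.0), [c0],
                        method="LSODA", rtol=1e-11, atol=1e-13, dense_output=True)
        t = np.linspace(3.0, 6.0, 50)
        analytic = hormone_trajectory(t, c0, Q, V, k)
        assert np.max(np.abs(analytic - sol.sol(t)[0]) / analytic) < 1e-8

    def test_monotone_between_baseline_and_plateau(self):
        t = np.linspace(3.0, 6.0, 200)
        vals = hormone_trajectory(t, 14.3, 4134.7, 19.6, 5.73)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 14.3) & (vals <= 4134.7 / (19.6 * 5.73) + 1e-9))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hormone_trajectory(4.0, 14.3, 4134.7, 19.6, 0.0)
        with pytest.raises(ValueError):
            hormone_trajectory(4.0, 14.3, 4134.7, -1.0, 5.73)


class TestGlucoseRhs:
    def test_zero_at_baseline_steady_state(self, avg_subject, protocol, fixed):
        params, bl = avg_subject
        val = glucose_rhs(bl.G_bar, bl.I_bar, bl.re_bar, params, protocol,
                          t=1.0, fixed=fixed)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_empty_model_is_flat(self, protocol, fixed):
        p = SubjectParameters(b_G=0, V_1=0, V_ii=0, V_id=0)
        for G in [0.5, 1.0, 3.0]:
            assert glucose_rhs(G, 10.0, 0.01, p, protocol, t=1.0,
                               fixed=fixed) == 0.0

    def test_term_by_term_hand_evaluation(self, protocol, fixed):
        p = SubjectParameters()  # average values, including V_ii=0.896, K_id=11
        G, I, re, t = 1.0, 10.0, 0.01, 4.0
        hill = 5.63 * re ** 2 / (0.00501 ** 2 + re ** 2)
        hand = 0.24 / 4.44 + 0.0804 + hill - 0.896 - 1.52 * I * G / (11.0 + G)
        assert glucose_rhs(G, I, re, p, protocol, t=t,
                           fixed=fixed) == pytest.approx(hand, rel=1e-12)

    def test_nonpositive_glucose_rejected_when_Kii_zero(self, protocol, fixed):
        with pytest.raises(ValueError):
            glucose_rhs(0.0, 10.0, 0.01, SubjectParameters(), protocol,
                        t=4.0, fixed=fixed)


class TestSystemRhs:
    def test_baseline_is_fixed_point_in_phase_one(self, avg_subject, protocol, fixed):
        params, bl = avg_subject
        y0 = np.array([bl.G_bar, bl.I_bar, bl.E_bar, bl.r_bar, bl.re_bar])
        dy = system_rhs(y0, 1.0, params, protocol, fixed, baseline=bl)
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_hormone_components_match_closed_forms(self, avg_subject, protocol, fixed):
        params, bl = avg_subject
        y0 = np.array([bl.G_bar, bl.I_bar, bl.E_bar, bl.r_bar, bl.re_bar])
        sol = solve_ivp(
            lambda t, y: system_rhs(y, t, params, protocol, fixed),
            (3.0, 6.0), y0, method="LSODA", rtol=1e-10, atol=1e-12,
            dense_output=True)
        t = np.linspace(3.0, 6.0, 40)
        I_exact = hormone_trajectory(t, bl.I_bar, protocol.Q_I, protocol.V_I,
                                     params.k_degI)
        E_exact = hormone_trajectory(t, bl.E_bar, protocol.Q_E, protocol.V_E,
                                     params.k_degE)
        assert np.max(np.abs(sol.sol(t)[1] - I_exact) / I_exact) < 1e-8
        assert np.max(np.abs(sol.sol(t)[2] - E_exact) / E_exact) < 1e-8

    def test_long_horizon_receptor_converges_to_steady_state(
            self, avg_subject, protocol, fixed):
        params, bl = avg_subject
        e_inf = protocol.Q_E / (protocol.V_E * params.k_degE)
        y0 = np.array([bl.G_bar, bl.I_bar, bl.E_bar, bl.r_bar, bl.re_bar])
        big = Protocol(t_end=120.0)
        sol = solve_ivp(lambda t, y: system_rhs(y, t, params, big, fixed),
                        (3.0, 120.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        r_inf, re_inf = receptor_steady_state(e_inf, params, fixed)
        assert sol.y[3][-1] == pytest.approx(r_inf, abs=1e-7)
        assert sol.y[4][-1] == pytest.approx(re_inf, abs=1e-7)


class TestBaselineElimination:
    def test_no_receptor_drive_puts_everything_in_basal_rate(self, fixed):
        p = SubjectParameters(V_1=1e-300)  # K1_prime must stay > 0
        p.V_1 = 0.0
        bl = make_baseline(0.9, 10.0, 14.3, p, fixed, Fhgp_bar=2.0)
        b_G, _ = eliminate_baseline_params(bl, p, fixed)
        assert b_G == pytest.approx(2.0)

    def test_no_insulin_dependence_puts_all_clearance_in_Vii(self, fixed):
        p = SubjectParameters(V_id=0.0)
        bl = make_baseline(0.9, 10.0, 14.3, p, fixed, Fhgp_bar=2.0)
        _, V_ii = eliminate_baseline_params(bl, p, fixed)
        assert V_ii == pytest.approx(2.0)

    def test_round_trip_recovers_generating_b_G(self, fixed):
        p = SubjectParameters()  # b_G = 0.0804 generates Fhgp_bar
        bl = make_baseline(0.9, 10.0, 14.3, p, fixed)
        b_G, V_ii = eliminate_baseline_params(bl, p, fixed)
        assert b_G == pytest.approx(p.b_G, rel=1e-10)

    def test_negative_elimination_warns_not_raises(self, fixed):
        p = SubjectParameters(V_1=100.0)  # Hill term exceeds basal HGP
        bl = make_baseline(0.9, 10.0, 14.3, p, fixed, Fhgp_bar=0.5)
        with pytest.warns(RuntimeWarning):
            eliminate_baseline_params(bl, p, fixed)

    def test_baseline_consistency_after_elimination(self, fixed):
        """After elimination the full system derivative vanishes at the
        baseline state with zero infusions."""
        protocol = Protocol()
        p = SubjectParameters(V_1=4.0, K1_prime=0.004, k_in=15.0, V_h=3.0)
        bl = make_baseline(1.0, 12.0, 14.3, p, fixed)
        p = apply_baseline_constraints(p, bl, fixed)
        y0 = np.array([bl.G_bar, bl.I_bar, bl.E_bar, bl.r_bar, bl.re_bar])
        dy = system_rhs(y0, 0.5, p, protocol, fixed, baseline=bl)
        assert np.allclose(dy, 0.0, atol=1e-12)
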