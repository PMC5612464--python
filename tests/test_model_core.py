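"""Transition-matrix structure, single-step accounting and steady states."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from melmark import model_core as mc
from melmark.curves import CurveSet, constant_curve
from melmark.model_core import (BASELINE, D1, D23, D4, DEATH, U1, U23, U4,
                                FluxTally, InfeasibleParameterError,
                                ParameterSet, build_transition_matrix,
                                annual_outputs, run_trajectory, steady_state,
                                steady_state_outputs, step)

from conftest import random_admissible_parameters


class TestParameterSet:
    def test_partition_complement(self, template):
        assert template.f1 == pytest.approx(1.0 - template.f23 - template.f4)

    @pytest.mark.parametrize("bad", [
        {"q": 1.2}, {"r": -0.01}, {"p": 0.5}, {"f23": 0.3, "f4": 0.25},
    ])
    def test_invalid_parameters_rejected(self, template, bad):
        with pytest.raises(ValueError):
            template.with_updates(**bad)

    def test_infeasible_stage1_row_rejected(self, template):
        # r + r/3 + D0 + d must not exceed 1
        with pytest.raises(InfeasibleParameterError):
            template.with_updates(r=0.72, D0=0.05, d=0.006)


class TestTransitionMatrix:
    def test_row_stochastic_and_sparsity(self, template):
        M = build_transition_matrix(template)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)
        assert M[DEATH, BASELINE] == 1.0
        # structurally forbidden transitions stay exactly zero
        assert M[D4, BASELINE] == 0.0
        assert M[D1, BASELINE] == 0.0
        assert M[U23, U1] == 0.0
        assert M[BASELINE, D1] == 0.0

    def test_stage4_row_complement_of_death_rates(self, template):
        # q = 0.37 and d = 0.006 leave a 0.624 probability of remaining
        M = build_transition_matrix(template.with_updates(q=0.37, d=0.006))
        assert M[D4, DEATH] == pytest.approx(0.376)
        assert M[D4, D4] == pytest.approx(0.624)

    def test_zero_rates_give_identity_baseline_row(self, template):
        M = build_transition_matrix(template.with_updates(d=0.0), i_val=0.0)
        assert M[BASELINE, BASELINE] == 1.0

    def test_progression_rates_scale_with_p(self, template):
        # r = 0.00375 with p = 15: undiagnosed routes r and r/3, diagnosed
        # routes slower by the factor p
        M = build_transition_matrix(template.with_updates(r=0.00375, p=15.0))
        assert M[U1, U23] == pytest.approx(0.00375)
        assert M[U1, U4] == pytest.approx(0.00125)
        assert M[D1, D23] == pytest.approx(0.00025)
        assert M[D1, D4] == pytest.approx(0.00375 / 45.0)

    def test_overdiagnosis_never_enters_matrix(self, template):
        M0 = build_transition_matrix(template, o_val=0.0)
        M1 = build_transition_matrix(template, o_val=0.1)
        np.testing.assert_array_equal(M0, M1)

    def test_infeasible_row_names_the_state(self, template):
        with pytest.raises(InfeasibleParameterError, match="u1"):
            build_transition_matrix(template, d_val=0.999)


class TestStep:
    def test_identity_matrix_is_a_fixed_point(self, template):
        state = np.array([0.9, 0.02, 0.01, 0.005, 0.05, 0.008, 0.004, 0.003])
        nxt, tally = step(state, np.eye(8), d_val=0.0)
        np.testing.assert_array_equal(nxt, state)
        assert all(v == 0.0 for v in tally)

    def test_mass_conserved_for_random_parameters(self, template):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = random_admissible_parameters(rng)
            M = build_transition_matrix(params)
            state = rng.dirichlet(np.ones(8))
            nxt, _ = step(state, M, d_val=params.d)
            assert nxt.sum() == pytest.approx(state.sum(), abs=1e-12)
            assert np.all(nxt >= 0)

    def test_single_step_matches_hand_oracle(self, template):
        """Entry-by-entry pencil-and-paper propagation of one year."""
        p = template  # I0=0.00031, D0=0.05, r=0.00375, p=15, q=0.37, d=0.006
        s = np.array([0.90, 0.04, 0.005, 0.002, 0.04, 0.008, 0.004, 0.001])
        M = build_transition_matrix(p)
        nxt, tally = step(s, M, d_val=p.d, o_val=0.02)

        i, dv, r, pr, q, d = p.I0, p.D0, p.r, p.p, p.q, p.d
        stay_b = 1.0 - i - d
        stay_u1 = 1.0 - dv - r - r / 3 - d
        stay_u23 = 1.0 - p.t4 - p.t6 - d
        stay_u4 = 1.0 - p.t5 - d
        stay_d1 = 1.0 - r / pr - r / (3 * pr) - d
        stay_d23 = 1.0 - p.t7 - d
        expected = np.array([
            s[0] * stay_b + s[7],
            s[0] * i * p.f1 + s[1] * stay_u1,
            s[0] * i * p.f23 + s[1] * r + s[2] * stay_u23,
            s[0] * i * p.f4 + s[1] * r / 3 + s[2] * p.t6 + s[3] * stay_u4,
            s[1] * dv + s[4] * stay_d1,
            s[2] * p.t4 + s[4] * r / pr + s[5] * stay_d23,
            s[3] * p.t5 + s[4] * r / (3 * pr) + s[5] * p.t7
            + s[6] * (1.0 - q - d),
            (s[:7].sum()) * d + s[6] * q,
        ])
        np.testing.assert_allclose(nxt, expected, atol=1e-15)
        assert tally.stage1_diagnoses == pytest.approx(s[1] * dv * 1e5)
        assert tally.stage23_diagnoses == pytest.approx(s[2] * p.t4 * 1e5)
        assert tally.stage4_diagnoses == pytest.approx(s[3] * p.t5 * 1e5)
        assert tally.overdiagnoses == pytest.approx(0.02 * s[1] * dv * 1e5)
        assert tally.melanoma_deaths == pytest.approx(s[6] * q * 1e5)
        assert tally.other_deaths == pytest.approx((1 - s[7]) * d * 1e5)


class TestSteadyState:
    def test_no_incidence_collapses_to_baseline(self, template):
        pi = steady_state(template.with_updates(d=0.0), i_val=0.0)
        np.testing.assert_allclose(pi, np.eye(8)[BASELINE], atol=1e-12)

    def test_power_iteration_agrees_with_linear_solve(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            params = random_admissible_parameters(rng)
            pi_pow = steady_state(params, method="power")
            pi_sol = steady_state(params, method="solve")
            np.testing.assert_allclose(pi_pow, pi_sol, atol=1e-10)

    def test_stationarity(self, template):
        pi = steady_state(template, method="solve")
        M = build_transition_matrix(template)
        np.testing.assert_allclose(pi @ M, pi, atol=1e-12)

    def test_outputs_internally_consistent(self, template):
        out = steady_state_outputs(template)
        # stationarity identity: diagnoses = melanoma deaths + background
        # deaths out of the diagnosed pool
        pi = out["state"]
        diagnosed = pi[[D1, D23, D4]].sum() * 1e5
        assert out["incidence"] == pytest.approx(
            out["mortality"] + template.d * diagnosed, rel=1e-9)


class TestTrajectory:
    def test_constant_curves_hold_the_steady_state(self, template):
        pi = steady_state(template, method="solve")
        curves = CurveSet(constant_curve(template.I0),
                          constant_curve(template.D0), constant_curve(0.0))
        traj = run_trajectory(template, curves, range(1982, 2014), pi)
        assert len(traj) == 32
        first, last = traj.tallies[0], traj.tallies[-1]
        for f, l in zip(first, last):
            assert f == pytest.approx(l, rel=1e-9)
        np.testing.assert_allclose(traj.final_state, pi, atol=1e-12)

    def test_mass_conserved_over_a_century(self, template):
        pi = steady_state(template, method="solve")
        curves = CurveSet(constant_curve(template.I0),
                          constant_curve(template.D0), constant_curve(0.0))
        traj = run_trajectory(template, curves, range(1982, 2082), pi,
                              extend=True)
        assert abs(traj.final_state.sum() - 1.0) < 1e-12

    def test_annual_outputs_additivity(self, reference_model):
        from melmark.calibration import model_series
        traj = run_trajectory(reference_model.params, reference_model.curves,
                              range(1982, 2014), reference_model.initial_state)
        out = annual_outputs(traj)
        # all-cause mortality = background deaths + melanoma deaths
        d = reference_model.params.d
        dead = traj.states[:, DEATH]
        expected = d * (1 - dead) * 1e5 + out["melanoma_mortality"].values
        np.testing.assert_allclose(out["all_cause_mortality"].values,
                                   expected, rtol=1e-12)

    def test_curve_undefined_year_raises(self, template):
        pi = steady_state(template, method="solve")
        curves = CurveSet(constant_curve(template.I0),
                          constant_curve(template.D0), constant_curve(0.0))
        with pytest.raises(Exception):
            run_trajectory(template, curves, range(1982, 2020), pi,
                           extend=False)


@given(d_shift=st.floats(0.0, 0.05))
def test_raising_detection_never_hurts(d_shift):
    """More secondary prevention can only add diagnoses and avert deaths."""
    from melmark.calibration import default_parameters
    params = default_parameters(0.05, 15.0)
    pi = steady_state(params, method="solve")

    def totals(dv):
        curves = CurveSet(constant_curve(params.I0), constant_curve(dv),
                          constant_curve(0.0))
        traj = run_trajectory(params, curves, range(1982, 2014), pi)
        return (sum(t.diagnostic_incidence for t in traj.tallies),
                sum(t.melanoma_deaths for t in traj.tallies))

    diag0, mort0 = totals(params.D0)
    diag1, mort1 = totals(params.D0 + d_shift)
    assert diag1 >= diag0 - 1e-9
    assert mort1 <= mort0 + 1e-9


def test_overdiagnosis_is_dynamics_neutral(reference_model):
    """Any O(t) leaves states and mortality bit-identical; only the
    incidence tally moves."""
    m = reference_model
    base = run_trajectory(m.params, m.curves, range(1982, 2014),
                          m.initial_state)
    overlay = CurveSet(m.curves.I_curve, m.curves.D_curve,
                       constant_curve(0.08))
    over = run_trajectory(m.params, overlay, range(1982, 2014),
                          m.initial_state)
    np.testing.assert_array_equal(base.states, over.states)
    for tb, to in zip(base.tallies, over.tallies):
        assert tb.melanoma_deaths == to.melanoma_deaths
        assert tb.stage1_diagnoses == to.stage1_diagnoses
        assert to.overdiagnoses > tb.overdiagnoses == 0.0
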