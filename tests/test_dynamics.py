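"""Core model: rate laws, simulation, oracle agreement, structural properties."""

import numpy as np
import pytest
from scipy.optimize import brentq

import doxopkpd as dx
from doxopkpd.params import PDParams, PKParams

from ._oracles import logistic_closed_form, rk4_bolus_reference

ARMS = (0.0, 10.0, 20.0, 40.0, 50.0, 200.0, 450.0, 900.0)


class TestEffluxRate:
    def test_zero_at_zero(self, pk):
        assert dx.efflux_rate(0.0, pk) == 0.0

    def test_half_effect_identity(self, pk):
        # at XB = kth the numerator/denominator structure forces Vmax/(2·kth)
        assert dx.efflux_rate(pk.kth, pk) == pytest.approx(pk.vmax / (2 * pk.kth), rel=1e-12)
        assert dx.efflux_rate(pk.kth, pk) == pytest.approx(17.780172, rel=1e-6)

    def test_decays_at_high_bound_drug(self, pk):
        # exponents 1.31 vs 2.31 make the rate fall off as 1/XB
        high = dx.efflux_rate(1e6, pk)
        higher = dx.efflux_rate(1e7, pk)
        assert higher < high < dx.efflux_rate(pk.kth, pk)
        assert higher == pytest.approx(high / 10.0, rel=0.01)

    def test_negative_input_rejected(self, pk):
        with pytest.raises(ValueError):
            dx.efflux_rate(-1.0, pk)


class TestDeathRate:
    def test_zero_and_half_saturation(self, pd_params):
        assert dx.death_rate(0.0, pd_params) == 0.0
        assert dx.death_rate(pd_params.xb_hs, pd_params) == pytest.approx(
            pd_params.kd_max / 2.0, rel=1e-12
        )
        assert dx.death_rate(47.5, pd_params) == pytest.approx(0.02175, rel=1e-12)

    def test_monotone_and_bounded(self, pd_params):
        xb = np.linspace(0, 5000, 200)
        kd = dx.death_rate(xb, pd_params)
        assert np.all(np.diff(kd) > 0)
        assert np.all(kd < pd_params.kd_max)
        assert dx.death_rate(1e9, pd_params) == pytest.approx(pd_params.kd_max, rel=1e-6)

    def test_negative_input_rejected(self, pd_params):
        with pytest.raises(ValueError):
            dx.death_rate(-0.1, pd_params)


class TestRhs:
    def test_drug_free_reduces_to_logistic(self, pk, pd_params):
        n = 1e4
        d = dx.rhs(0.0, [0, 0, 0, n], pk, pd_params)
        expect_dn = pd_params.k_p * n * (1 - n / pd_params.theta)
        assert d[:3] == pytest.approx([0, 0, 0], abs=0)
        assert d[3] == pytest.approx(expect_dn, rel=1e-12)

    def test_carrying_capacity_fixed_point(self, pk, pd_params):
        d = dx.rhs(0.0, [0, 0, 0, pd_params.theta], pk, pd_params)
        assert d[3] == pytest.approx(0.0, abs=1e-9)

    def test_uptake_term_hand_value(self, pk, pd_params):
        # dXF/dt at (XE=100, XF=XB=0): k_fe·(VE/VI)·XE, evaluated independently
        d = dx.rhs(0.0, [100.0, 0.0, 0.0, 1e4], pk, pd_params)
        expected = 5.63e-4 * (100.0 / 0.07) * 100.0
        assert d[1] == pytest.approx(expected, rel=1e-12)
        assert d[1] == pytest.approx(80.428571, rel=1e-6)


class TestSimulate:
    def test_drug_free_matches_logistic_closed_form(self, pk, pd_params):
        grid = np.linspace(0, 456, 115)
        traj = dx.simulate(pk, pd_params, dx.TreatmentSchedule(), 1e4, (0, 456), grid)
        closed = logistic_closed_form(grid, 1e4, pd_params.k_p, pd_params.theta)
        assert np.max(np.abs(traj.n - closed) / closed) < 1e-6

    def test_zero_dose_event_is_inert(self, pk, pd_params):
        grid = np.linspace(0, 200, 101)
        empty = dx.simulate(pk, pd_params, dx.TreatmentSchedule(), 1e4, (0, 200), grid)
        zero = dx.simulate(
            pk, pd_params, dx.TreatmentSchedule.single_bolus(0.0, 3.0, 10.0), 1e4, (0, 200), grid
        )
        # integration restarts at the (inert) event boundaries allow tiny
        # solver-path differences at the working tolerance
        np.testing.assert_allclose(zero.n, empty.n, rtol=1e-6)
        assert np.all(zero.xb == 0)

    @pytest.mark.parametrize("dose", [10.0, 200.0, 900.0])
    def test_matches_fixed_step_rk4_reference(self, pk, pd_params, dose):
        grid = np.arange(0.0, 456.1, 24.0)
        traj = dx.simulate(
            pk, pd_params, dx.TreatmentSchedule.single_bolus(dose, 3.0, 0.0), 1e4, (0, 456), grid
        )
        ref = rk4_bolus_reference(pk, pd_params, dose, 1e4, grid, exposure_h=3.0, h=1e-3)
        for k, state in enumerate([traj.xe, traj.xf, traj.xb, traj.n]):
            scale = np.max(np.abs(ref[:, k])) or 1.0
            assert np.max(np.abs(state - ref[:, k])) / scale < 1e-4

    def test_states_stay_nonnegative(self, pk, pd_params):
        for dose in ARMS:
            sched = (
                dx.TreatmentSchedule()
                if dose == 0
                else dx.TreatmentSchedule.single_bolus(dose, 3.0, 0.0)
            )
            traj = dx.simulate(pk, pd_params, sched, 1e4, (0, 456), np.linspace(0, 456, 400))
            for state in (traj.xe, traj.xf, traj.xb, traj.n):
                assert np.all(state >= 0)

    def test_final_count_nonincreasing_in_dose(self, pk, pd_params):
        finals = []
        for dose in ARMS:
            sched = (
                dx.TreatmentSchedule()
                if dose == 0
                else dx.TreatmentSchedule.single_bolus(dose, 3.0, 0.0)
            )
            traj = dx.simulate(pk, pd_params, sched, 1e4, (0, 456), np.array([0.0, 456.0]))
            finals.append(traj.n[-1])
        assert np.all(np.diff(finals) <= 0)

    def test_post_washout_bound_drug_decays_at_gamma(self, pk, pd_params):
        grid = np.arange(0.0, 456.1, 1.0)
        traj = dx.simulate(
            pk, pd_params, dx.TreatmentSchedule.single_bolus(900.0, 3.0, 0.0), 1e4, (0, 456), grid
        )
        tail = grid >= 300  # XF has long emptied by then
        slope = np.polyfit(grid[tail], np.log(traj.xb[tail]), 1)[0]
        # slight slow-down from drug recycling through the medium is expected
        assert -slope == pytest.approx(pk.gamma, rel=0.1)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            dx.TreatmentSchedule(
                (dx.DoseEvent(0.0, 100.0, 3.0), dx.DoseEvent(2.0, 100.0, 3.0))
            )

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError):
            dx.TreatmentSchedule(
                (dx.DoseEvent(10.0, 100.0, 3.0), dx.DoseEvent(0.0, 100.0, 3.0))
            )

    def test_bad_grid_rejected(self, pk, pd_params):
        with pytest.raises(ValueError):
            dx.simulate(pk, pd_params, dx.TreatmentSchedule(), 1e4, (0, 10), np.array([0.0, 20.0]))


class TestQuadratureFastPath:
    """The Bernoulli-form quadrature used in fitting matches the coupled ODE."""

    @pytest.mark.parametrize("dose", [10.0, 50.0, 900.0])
    def test_agrees_with_coupled_ode(self, pk, pd_params, dose):
        from scipy.integrate import solve_ivp

        times = np.arange(0.0, 457.0, 24.0)
        fast = dx.predict_arm_counts(pk, pd_params, dose, times, n0=1e4)
        sched = dx.TreatmentSchedule.single_bolus(dose, 3.0, -3.0)
        grid = np.unique(np.concatenate([np.arange(-3, 456.001, 0.5), times]))
        pk_traj = dx.simulate(pk, pd_params, sched, 1e4, (-3, 456), grid)
        i0 = int(np.where(grid == 0.0)[0][0])
        y0 = [pk_traj.xe[i0], pk_traj.xf[i0], pk_traj.xb[i0], 1e4]
        sol = solve_ivp(
            dx.rhs, (0, 456), y0, args=(pk, pd_params), t_eval=times, rtol=1e-10, atol=1e-12
        )
        assert np.max(np.abs(fast - sol.y[3]) / sol.y[3]) < 1e-4


class TestEfficacyThreshold:
    def test_formula_against_bisection(self, pd_params):
        xb_star = dx.efficacy_threshold(pd_params)
        assert xb_star == pytest.approx(39.6835, rel=1e-4)
        by_bisection = brentq(
            lambda xb: dx.death_rate(xb, pd_params) - pd_params.k_p, 1e-9, 1e6
        )
        assert xb_star == pytest.approx(by_bisection, rel=1e-9)

    def test_limit_cases(self):
        tiny_kp = PDParams(k_p=1e-12, n0={0.0: 1.0})
        assert dx.efficacy_threshold(tiny_kp) == pytest.approx(0.0, abs=1e-6)
        unreachable = PDParams(k_p=0.05, kd_max=0.04, n0={0.0: 1.0})
        assert np.isinf(dx.efficacy_threshold(unreachable))


class TestParameterValidation:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            PKParams(vmax=-1.0)
        with pytest.raises(ValueError):
            PKParams(gamma=-0.001)
        with pytest.raises(ValueError):
            PDParams(k_p=0.0)
        with pytest.raises(ValueError):
            dx.DoseEvent(0.0, -5.0, 3.0)

    def test_gamma_zero_allowed(self):
        assert PKParams(gamma=0.0).gamma == 0.0

    def test_params_roundtrip(self, tmp_path, pk, pd_params):
        path = tmp_path / "params.yaml"
        dx.save_params(pk, pd_params, path)
        pk2, pd2 = dx.load_params(path)
        assert pk2 == pk
        assert pd2.k_p == pd_params.k_p
        assert pd2.n0_for(900.0) == pd_params.n0_for(900.0)
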