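"""CO2-loop forward model: hinge, steady states, forcing, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventpkpd import (
    ForcingProtocol,
    GasState,
    HCVRParameters,
    PhysiologyConstants,
    RunRecord,
    brain_step_halftime,
    calibrate_vco2,
    closed_loop_steady_state,
    hinge,
    simulate_run,
    vco2_for_resting_state,
    ventilation_from_brain_pco2,
)
from ventpkpd.physiology import RK4_STEP_MIN, simulate_driven


class TestHinge:
    def test_value_at_kink(self):
        assert hinge(0.0, 0.1) == pytest.approx(0.1 * np.log(2.0), rel=1e-12)

    def test_linear_asymptote(self):
        assert hinge(10.0, 0.1) == pytest.approx(10.0, abs=5e-7)

    def test_flat_asymptote(self):
        assert hinge(-10.0, 0.1) < 1e-40

    def test_overflow_safe(self):
        assert np.isfinite(hinge(1e6, 0.1))
        assert hinge(1e6, 0.1) == pytest.approx(1e6)

    @given(x=st.floats(-100, 100), delta=st.floats(1e-3, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_max_relaxation(self, x, delta):
        # smooth hinge sits within delta*ln2 above max(0, x), never below
        # (up to rounding in the large-x regime where H(x) -> x)
        h = float(hinge(x, delta))
        lo = max(0.0, x)
        assert lo - 1e-9 * max(1.0, abs(x)) <= h
        assert h <= lo + delta * np.log(2.0) + 1e-12

    @given(delta=st.floats(1e-3, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone(self, delta):
        # strictly increasing wherever the value has not underflowed
        xs = np.linspace(-20, 20, 400)
        h = np.asarray(hinge(xs, delta))
        nonzero = h[:-1] > 1e-300
        assert np.all(np.diff(h)[nonzero] > 0)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            hinge(1.0, 0.0)


class TestVentilationLaw:
    def test_below_threshold_is_baseline(self, median_hcvr, calibrated_constants):
        ve = ventilation_from_brain_pco2(median_hcvr, median_hcvr.vrt - 10.0,
                                         calibrated_constants)
        assert ve == pytest.approx(8.3, abs=1e-6)

    def test_median_value_at_55(self, median_hcvr, calibrated_constants):
        # 8.3 + 2.5*H(11) = 35.8 at the median parameter set
        ve = ventilation_from_brain_pco2(median_hcvr, 55.0, calibrated_constants)
        assert ve == pytest.approx(35.8, abs=1e-6)

    def test_zero_slope_flat(self, calibrated_constants):
        hc = HCVRParameters(8.3, 41.0, 44.0, 0.0)
        pbs = np.linspace(20, 80, 25)
        ve = ventilation_from_brain_pco2(hc, pbs, calibrated_constants)
        assert np.allclose(ve, 8.3)


class TestSteadyState:
    def test_calibration_value(self):
        cons = PhysiologyConstants()
        vco2 = calibrate_vco2(8.3, 41.0, cons)
        # (8.3 - 1.8)*41/(10*11.5) = 266.5/115
        assert vco2 == pytest.approx(266.5 / 115.0, rel=1e-12)

    def test_calibration_roundtrip(self, median_hcvr, calibrated_constants):
        ss = closed_loop_steady_state(median_hcvr, calibrated_constants, 0.0)
        assert ss.feasible
        assert ss.ve == pytest.approx(8.3, abs=1e-10)
        assert ss.gas.arterial_pco2 == pytest.approx(41.0, abs=1e-10)

    def test_calibration_limit_at_dead_space(self):
        cons = PhysiologyConstants()
        assert calibrate_vco2(cons.vd + 1e-9, 41.0, cons) < 1e-9

    def test_calibration_rejects_apneic_baseline(self):
        cons = PhysiologyConstants()
        with pytest.raises(ValueError):
            calibrate_vco2(1.0, 41.0, cons)

    def test_metabolic_hyperbola(self, median_hcvr, calibrated_constants):
        cons = calibrated_constants
        for pi in (0.0, 5.0, 20.0):
            ss = closed_loop_steady_state(median_hcvr, cons, pi)
            lhs = (ss.ve - cons.vd) * (ss.gas.arterial_pco2 - pi)
            rhs = cons.lambda1 * cons.lambda2 * cons.vco2
            assert abs(lhs - rhs) / rhs < 1e-8

    def test_ode_rhs_vanishes_at_fixed_point(self, median_hcvr, calibrated_constants):
        cons = calibrated_constants
        ss = closed_loop_steady_state(median_hcvr, cons, 0.0)
        pa, pv = ss.gas.arterial_pco2, ss.gas.venous_pco2
        dpa = ((ss.ve - cons.vd) * (0.0 - pa)
               + cons.lambda1 * cons.q * (pv - pa)) / cons.valv
        dpv = (cons.q * (pa - pv) + cons.lambda2 * cons.vco2) / cons.vts
        assert abs(dpa) < 1e-9 and abs(dpv) < 1e-9

    def test_venous_exceeds_arterial(self, median_hcvr, calibrated_constants):
        ss = closed_loop_steady_state(median_hcvr, calibrated_constants, 0.0)
        assert ss.gas.venous_pco2 > ss.gas.arterial_pco2

    def test_monotone_in_inspired(self, median_hcvr, calibrated_constants):
        pis = np.linspace(0, 30, 7)
        sols = [closed_loop_steady_state(median_hcvr, calibrated_constants, pi)
                for pi in pis]
        pas = [s.gas.arterial_pco2 for s in sols]
        ves = [s.ve for s in sols]
        assert np.all(np.diff(pas) > 0)
        # ventilation strictly rises once the loop operates above threshold
        above = [s for s in sols if s.gas.arterial_pco2 > median_hcvr.vrt]
        assert np.all(np.diff([s.ve for s in above]) > 0)
        assert ves[-1] > ves[0]

    def test_apneic_no_solution(self, calibrated_constants):
        hc = HCVRParameters(1.0, 41.0, 44.0, 0.0)  # flat VE below dead space
        ss = closed_loop_steady_state(hc, calibrated_constants, 0.0)
        assert not ss.feasible

    def test_hinge_aware_calibration_consistency(self):
        # threshold below resting PETCO2: resting ventilation includes the
        # active hinge term, and the loop still rests exactly at the pair
        cons = PhysiologyConstants()
        hc = HCVRParameters(8.3, 45.0, 42.0, 2.5)
        cons = cons.with_vco2(vco2_for_resting_state(hc, cons))
        ss = closed_loop_steady_state(hc, cons, 0.0)
        assert ss.gas.arterial_pco2 == pytest.approx(45.0, abs=1e-9)
        assert ss.ve > hc.baseline_ve


class TestForcingProtocol:
    def test_default_drops_final_step(self):
        p = ForcingProtocol()
        assert p.effective_increments() == (4.5, 9.0, 13.5)
        assert p.total_duration == pytest.approx(27.0)

    def test_short_steps_keep_all_four(self):
        p = ForcingProtocol(step_duration=6.0, max_total=20.0)
        assert len(p.effective_increments()) == 4

    def test_validation(self):
        with pytest.raises(ValueError):
            ForcingProtocol(step_increments=(9.0, 4.5))
        with pytest.raises(ValueError):
            ForcingProtocol(step_duration=-1.0)


class TestSimulateRun:
    def test_equilibrium_invariant_without_forcing(self, median_hcvr,
                                                   calibrated_constants):
        proto = ForcingProtocol(resting_duration=5.0, step_increments=(0.0,),
                                step_duration=5.0)
        rec = simulate_run(median_hcvr, calibrated_constants, proto)
        assert np.all(np.abs(rec.ve_s - 8.3) < 1e-3)

    def test_plateaus_reach_target(self, median_run):
        # end-tidal forcing lands within 0.5 mmHg of each step target
        for i, inc in enumerate((4.5, 9.0, 13.5)):
            end = (6 + 7 * (i + 1)) * 60 - 1
            assert abs(median_run.petco2_s[end] - (41.0 + inc)) < 0.5

    def test_long_steps_settle_on_static_law(self, median_hcvr,
                                             calibrated_constants):
        # with steps long enough to reach steady state, the final-2-min mean
        # ventilation of each step lies on baseline + S*(PETCO2 - VRT)
        proto = ForcingProtocol(resting_duration=6.0,
                                step_increments=(4.5, 9.0, 13.5),
                                step_duration=18.0, max_total=60.0)
        rec = simulate_run(median_hcvr, calibrated_constants, proto)
        for i in range(3):
            sl = slice(6 + 18 * i + 16, 6 + 18 * (i + 1))
            pet = rec.petco2_min[sl].mean()
            ve = rec.ve_min[sl].mean()
            line = 8.3 + 2.5 * max(pet - 44.0, 0.0)
            assert abs(ve - line) / line < 0.02

    def test_inspired_never_negative(self, median_run):
        assert np.all(median_run.pico2_s >= 0.0)

    def test_output_grid_refinement(self, median_hcvr, calibrated_constants):
        # halving the output sampling density changes the 1-min block
        # averages only through transient minutes, and by well under 0.5%
        r1 = simulate_run(median_hcvr, calibrated_constants, dt_out=1.0)
        r2 = simulate_run(median_hcvr, calibrated_constants, dt_out=2.0)
        assert np.allclose(r1.ve_min, r2.ve_min, rtol=5e-3)
        assert np.allclose(r1.petco2_min, r2.petco2_min, rtol=5e-3)

    def test_matches_adaptive_reference_solver(self, median_hcvr,
                                               calibrated_constants, median_run):
        # independent oracle: re-integrate the three mass-balance ODEs with
        # scipy's adaptive solver, driven by the recorded inspired PCO2
        from scipy.integrate import solve_ivp

        cons = calibrated_constants
        pic = median_run.pico2_substep

        def rhs(t, y):
            pa, pv, pb = y
            k = min(int(t / RK4_STEP_MIN), len(pic) - 1)
            ve = 8.3 + 2.5 * float(hinge(pb - 44.0, cons.delta))
            dpa = ((ve - cons.vd) * (pic[k] - pa)
                   + cons.lambda1 * cons.q * (pv - pa)) / cons.valv
            dpv = (cons.q * (pa - pv) + cons.lambda2 * cons.vco2) / cons.vts
            dpb = (pa - pb) / cons.tau
            return [dpa, dpv, dpb]

        t_end = 27.0
        pv0 = 41.0 + cons.lambda2 * cons.vco2 / cons.q
        sol = solve_ivp(rhs, (0.0, t_end), [41.0, pv0, 41.0], method="LSODA",
                        rtol=1e-8, atol=1e-10, max_step=RK4_STEP_MIN,
                        t_eval=np.arange(0, t_end, 1.0))
        pa_ref = sol.y[0]
        pa_rk4 = median_run.petco2_s[::60][: len(pa_ref)]
        assert np.allclose(pa_rk4, pa_ref, atol=2e-4)

    def test_csv_roundtrip(self, median_run, tmp_path):
        path = tmp_path / "run.csv"
        median_run.to_csv(path)
        back = RunRecord.from_csv(path)
        assert back.subject_id == median_run.subject_id
        assert np.allclose(back.ve_min, median_run.ve_min)
        assert np.allclose(back.petco2_min, median_run.petco2_min)
        assert np.allclose(back.pico2_min, median_run.pico2_min)
        assert back.pico2_substep is None


class TestBrainLag:
    def test_half_time_is_tau_ln2(self):
        cons = PhysiologyConstants()
        t_half = brain_step_halftime(cons)
        assert t_half == pytest.approx(cons.tau * np.log(2.0), rel=1e-4)

    def test_driven_step_half_time(self, median_hcvr, calibrated_constants):
        # closed-loop-free check on the integrated kernel: drive inspired
        # PCO2 so arterial jumps, brain PCO2 crosses 50% near tau*ln2
        cons = calibrated_constants
        t_half = cons.tau * np.log(2.0)
        assert abs(brain_step_halftime(cons) - t_half) / t_half < 0.01


class TestValidation:
    def test_constants_enforce_lambda2(self):
        cons = PhysiologyConstants(lambda0=0.2)
        assert cons.lambda2 == pytest.approx(20.0)

    def test_constants_reject_nonpositive(self):
        with pytest.raises(ValueError):
            PhysiologyConstants(tau=-1.0)

    def test_gas_state_rejects_negative(self):
        with pytest.raises(ValueError):
            GasState(-1.0, 45.0, 41.0, 0.0, 41.0)
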