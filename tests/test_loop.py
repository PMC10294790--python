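"""Closed-loop dosing: controller recursion, dose shaping, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thyrodose import (
    ControllerState,
    ControllerTF,
    ReferenceSchedule,
    TherapyLimits,
    controller_step,
    nominal_patient,
    run_closed_loop,
    shape_dose,
)


class TestControllerStep:
    def test_zero_state_zero_error_gives_zero(self, controller):
        state = ControllerState()
        assert controller_step(state, controller, 5.0, 5.0) == 0.0

    def test_hand_unrolled_two_steps(self, controller):
        """Errors (1, 0) from rest give outputs (b1, b0 - a0 b1)."""
        state = ControllerState()
        u1 = controller_step(state, controller, 1.0, 0.0)
        u2 = controller_step(state, controller, 0.0, 0.0)
        assert u1 == pytest.approx(controller.b1)
        assert u2 == pytest.approx(controller.b0 - controller.a0 * controller.b1)

    def test_linearity_in_state_and_input(self, controller):
        s1 = ControllerState(e_prev=0.4, u_prev=-0.2)
        s2 = ControllerState(e_prev=0.8, u_prev=-0.4)
        u1 = controller_step(s1, controller, 2.0, 0.5)
        u2 = controller_step(s2, controller, 4.0, 1.0)
        assert u2 == pytest.approx(2.0 * u1)

    def test_unnormalized_controller_rejected(self):
        bad = ControllerTF(b1=1.0, b0=0.0, a1=2.0, a0=0.0)
        with pytest.raises(ValueError, match="normalized"):
            controller_step(ControllerState(), bad, 1.0, 0.0)


class TestShapeDose:
    def test_rate_clip_then_ceiling(self):
        limits = TherapyLimits()
        dose = shape_dose(350.0, 187.5, limits, y=5.0, in_band=False)
        assert dose == 200.0

    def test_in_band_holds_previous_dose(self):
        dose = shape_dose(500.0, 87.5, TherapyLimits(), y=12.0, in_band=True)
        assert dose == 87.5

    def test_quantized_fixed_point(self):
        dose = shape_dose(87.5, 87.5, TherapyLimits(), y=5.0, in_band=False)
        assert dose == 87.5

    def test_ties_round_down(self):
        # 6.25 is exactly between 0 and 12.5
        assert shape_dose(6.25, 0.0, TherapyLimits(), 5.0, False) == 0.0
        assert shape_dose(18.75, 12.5, TherapyLimits(), 5.0, False) == 12.5

    def test_negative_command_floors_at_zero(self):
        assert shape_dose(-100.0, 12.5, TherapyLimits(), 20.0, False) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        u=st.floats(-500, 500),
        prev_steps=st.integers(0, 16),
        in_band=st.booleans(),
    )
    def test_invariants_hold_for_any_command(self, u, prev_steps, in_band):
        """Safety, rate-bound and quantization for arbitrary raw output."""
        limits = TherapyLimits()
        prev = prev_steps * limits.dose_quantum
        dose = shape_dose(u, prev, limits, y=10.0, in_band=in_band)
        assert 0.0 <= dose <= limits.dose_max
        assert abs(dose - prev) <= limits.max_step + 1e-12
        assert (dose / limits.dose_quantum) == pytest.approx(
            round(dose / limits.dose_quantum), abs=1e-9
        )


class TestClosedLoop:
    def test_nominal_staircase_then_constant(self, controller):
        """Reference 13 ng/L: doses rise by one quantum per visit until the
        band is reached, then stay constant; final FT4 is euthyroid."""
        res = run_closed_loop(
            nominal_patient(), controller, ReferenceSchedule.constant(13.0)
        )
        doses = res.doses
        steps = np.diff(doses)
        changed = steps[steps != 0]
        assert doses[0] == 12.5
        assert np.all(changed == 12.5)
        # once in band the dose freezes
        assert doses[-1] == doses[-2]
        assert 9.2 <= res.final_ft4 <= 16.0

    def test_settles_within_18_visits_for_any_band_reference(self, controller):
        for ref in (9.5, 13.0, 16.0):
            res = run_closed_loop(
                nominal_patient(), controller, ReferenceSchedule.constant(ref),
                duration_h=20 * 672.0,
            )
            month_ft4 = res.month_end_ft4()
            assert np.any((month_ft4[:18] >= 9.2) & (month_ft4[:18] <= 16.0))
            assert np.all(res.doses[18:] == res.doses[18])

    def test_overreplaced_patient_titrates_down_until_in_band(self, controller):
        """Doses fall one quantum per visit until FT4 re-enters the band."""
        patient = nominal_patient()
        patient.advance(200.0, 24.0 * 300)  # grossly over-replaced
        res = run_closed_loop(
            patient, controller, ReferenceSchedule.constant(13.0),
            duration_h=18 * 672.0, initial_dose=200.0,
        )
        d = res.doses
        assert np.all(np.diff(d) <= 0)
        month_ft4 = res.month_end_ft4()
        inside = np.nonzero((month_ft4 >= 9.2) & (month_ft4 <= 16.0))[0]
        assert inside.size > 0
        # frozen once back in band
        assert np.all(d[inside[0] + 1 :] == d[inside[0] + 1])

    def test_reference_drop_reacts_at_most_one_quantum(self, controller):
        """16 ng/L for 18 months then 12 ng/L: the loop may react only at
        the switch visit (one quantum at most) and the patient, already
        euthyroid, then stays in band on a constant dose."""
        Td = 672.0
        refs = ReferenceSchedule(
            np.array([0.0, 18 * Td]), np.array([16.0, 12.0])
        )
        res = run_closed_loop(
            nominal_patient(), controller, refs, duration_h=36 * Td
        )
        after = res.doses[17:]
        assert np.max(np.abs(np.diff(after))) <= 12.5
        assert np.all(after[2:] == after[2])
        assert 9.2 <= res.final_ft4 <= 16.0

    def test_steady_state_hold_from_matched_start(self, controller):
        """A patient continuing a dose-matched regimen keeps it unchanged."""
        patient = nominal_patient()
        patient.advance(87.5, 24.0 * 300)  # settle on a maintenance dose
        state_ft4 = float(np.mean(patient.ft4_history[-24:]))
        assert 9.2 <= state_ft4 <= 16.0
        res = run_closed_loop(
            patient, controller, ReferenceSchedule.constant(13.0),
            duration_h=6 * 672.0, initial_dose=87.5,
        )
        assert np.all(res.doses == 87.5)

    def test_randomized_patients_respect_limits(self, controller, rng):
        """Safety, rate and quantization invariants on random patients."""
        from thyrodose import CohortConfig, generate_patient

        cfg = CohortConfig(n_patients=4, master_seed=7, months=8)
        limits = TherapyLimits()
        for i in range(cfg.n_patients):
            patient = generate_patient(cfg, i)
            res = run_closed_loop(
                patient, controller, ReferenceSchedule.constant(13.0),
                limits=limits, duration_h=8 * 672.0,
            )
            d = res.doses
            assert np.all((d >= 0) & (d <= limits.dose_max))
            assert np.all(np.abs(np.diff(d)) <= limits.max_step + 1e-12)
            assert np.allclose(d % limits.dose_quantum, 0.0)

    def test_duration_must_align_with_visits(self, controller):
        with pytest.raises(ValueError, match="multiple"):
            run_closed_loop(
                nominal_patient(), controller,
                ReferenceSchedule.constant(13.0), duration_h=1000.0,
            )


class TestLimitsValidation:
    def test_orderings_enforced(self):
        with pytest.raises(ValueError):
            TherapyLimits(dose_quantum=25.0, max_step=12.5)
        with pytest.raises(ValueError):
            TherapyLimits(range_lo=16.0, range_hi=9.2)

    def test_reference_schedule_validation(self):
        with pytest.raises(ValueError):
            ReferenceSchedule(np.array([5.0]), np.array([13.0]))
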