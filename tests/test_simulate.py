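"""Scenario integration: pulses, entrainment, orderings, fixed-point stability."""

import numpy as np
import pytest

import hpaxis
from hpaxis.simulate import (
    PerturbationSchedule,
    PulseEvent,
    ScenarioConfig,
    Trajectory,
    apply_pulse,
    clock_to_minutes,
    find_fixed_point_and_stability,
    integrate,
    kindling_schedule,
    minutes_to_clock,
)


class TestClockHelpers:
    def test_round_trip(self):
        assert clock_to_minutes("21:12", day=2) == 1440 + 21 * 60 + 12
        assert minutes_to_clock(clock_to_minutes("06:30", day=3)) == "06:30"

    def test_invalid_clock_rejected(self):
        with pytest.raises(ValueError):
            clock_to_minutes("25:00")


class TestApplyPulse:
    def test_crh_pulse_adds_exactly(self):
        state = hpaxis.initial_state().with_concentration("CRH", 2e-13)
        out = apply_pulse(state, "CRH", 5e-8)
        assert out["CRH"] == 5e-8 + 2e-13
        for name in hpaxis.SPECIES:
            if name != "CRH":
                assert out[name] == state[name]
        assert out.time == state.time

    def test_zero_increment_is_identity(self):
        state = hpaxis.initial_state()
        out = apply_pulse(state, "CRH", 0.0)
        np.testing.assert_array_equal(out.concentrations, state.concentrations)

    def test_two_pulses_equal_one_summed_pulse(self):
        state = hpaxis.initial_state()
        ab = apply_pulse(apply_pulse(state, "CRH", 3e-8), "CRH", 2e-8)
        once = apply_pulse(state, "CRH", 5e-8)
        np.testing.assert_array_equal(ab.concentrations, once.concentrations)

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            apply_pulse(hpaxis.initial_state(), "CORTISOL", 1e-9)


class TestKindlingSchedule:
    def test_default_is_75_pulses_inside_the_window(self):
        start = clock_to_minutes("21:12", day=2)
        sched = kindling_schedule(start)
        assert len(sched) == 75
        t = sched.times()
        assert t[0] == start
        assert np.allclose(np.diff(t), 40.0 / 60.0)
        assert t[-1] < start + 50.0  # no pulse at or after the window end
        assert t[-1] == pytest.approx(start + 74 * 40.0 / 60.0)

    def test_zero_duration_gives_empty_schedule(self):
        assert len(kindling_schedule(100.0, duration_min=0.0)) == 0

    def test_schedule_times_must_increase(self):
        with pytest.raises(ValueError):
            PerturbationSchedule(events=(
                PulseEvent(10.0, "CRH", 1e-9), PulseEvent(10.0, "CRH", 1e-9),
            ))


class TestScenarioValidation:
    def test_bad_time_span(self):
        with pytest.raises(ValueError):
            ScenarioConfig(t_start=100.0, t_end=100.0)

    def test_nonstiff_method_rejected(self):
        with pytest.raises(ValueError, match="stiff"):
            ScenarioConfig(method="RK45")

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            ScenarioConfig(condition="kindled")


class TestControlDynamics:
    def test_all_species_stay_positive(self, control5_strict):
        assert control5_strict.states.min() > 0.0

    def test_entrainment_to_daily_forcing(self, control5_strict):
        """After the transient day, consecutive-day means differ < 1%."""
        means = [control5_strict.day_mean(d) for d in range(2, 6)]
        for a, b in zip(means, means[1:]):
            assert abs(b - a) / a < 0.01

    def test_relaxed_tolerances_preserve_daily_means(self, control5_strict, control5_fast):
        """Strict vs fast solver presets agree on day-2..5 daily means within 1%."""
        for d in range(2, 6):
            strict = control5_strict.day_mean(d)
            fast = control5_fast.day_mean(d)
            assert abs(fast - strict) / strict < 0.01

    def test_deterministic_rerun_is_bit_identical(self):
        sc = hpaxis.control_scenario(days=1.0).with_tolerances("fast")
        a, b = integrate(sc), integrate(sc)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.times, b.times)

    def test_output_spacing_at_most_one_minute(self, control5_strict):
        assert np.diff(control5_strict.times).max() <= 1.0 + 1e-9


class TestKindling:
    def test_every_scheduled_pulse_applied_exactly(self, lhk3_strict):
        recs = lhk3_strict.pulse_records
        assert len(recs) == len(lhk3_strict.scenario.schedule)
        for r in recs:
            assert (r.post_value - r.pre_value) == pytest.approx(r.increment, rel=1e-15)

    def test_trajectory_times_strictly_increasing(self, lhk3_strict):
        assert np.all(np.diff(lhk3_strict.times) > 0)

    def test_corticosterone_ordering_lhk_sham_control(
        self, lhk3_strict, sham5_strict, control5_strict, kindle_start
    ):
        """Kindling-window mean CTS: kindled > sham > control."""
        window = (kindle_start, kindle_start + 50.0)
        lhk = lhk3_strict.window(*window)[1].mean()
        sham = sham5_strict.window(*window)[1].mean()
        ctrl = control5_strict.window(*window)[1].mean()
        assert lhk > sham > ctrl

    def test_transient_recovery_into_sham_envelope(
        self, lhk3_strict, sham5_strict
    ):
        """Within 3 h of the last pulse the kindled CTS re-enters the sham
        min-max envelope of the same clock window."""
        last = lhk3_strict.pulse_records[-1].time
        _, sham = sham5_strict.window(last, last + 180.0)
        lo, hi = sham.min(), sham.max()
        _, kindled = lhk3_strict.window(last, last + 180.0)
        assert np.any((kindled >= lo) & (kindled <= hi))

    def test_sham_elevates_daily_corticosterone(self, sham5_strict, control5_strict):
        for d in range(2, 6):
            assert sham5_strict.day_mean(d) > control5_strict.day_mean(d)


class TestTrajectoryIO:
    def test_csv_round_trip_is_lossless(self, lhk3_strict, tmp_path):
        path = tmp_path / "traj.csv"
        lhk3_strict.to_csv(path)
        back = Trajectory.from_csv(path)
        np.testing.assert_array_equal(back.times, lhk3_strict.times)
        np.testing.assert_array_equal(back.states, lhk3_strict.states)


class TestFixedPoint:
    def test_root_residual_and_cort_balance(self):
        ss, _ = find_fixed_point_and_stability()
        resid = hpaxis.mass_action_rhs(
            ss, circadian_factor=float(np.mean(hpaxis.circadian_drive(np.arange(1440.0))))
        )
        assert np.abs(resid).max() <= 1e-18
        k = hpaxis.RATE_CONSTANTS
        assert k["k13"] * ss["HPGS"] - k["k23"] * ss["CORT"] == pytest.approx(
            0.0, abs=1e-18
        )

    def test_unstable_focus_sustains_oscillations(self):
        """At the period-mean drive the steady state is an unstable focus."""
        _, eigvals = find_fixed_point_and_stability()
        leading = max(eigvals, key=lambda z: z.real)
        assert leading.real > 0
        assert abs(leading.imag) > 0
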