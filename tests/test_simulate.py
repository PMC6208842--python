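"""Simulator: signal-detection choices, trace generation, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gonogo.performance_stats import classify_response
from gonogo.profiles import control_profile, expert_profile
from gonogo.pupillometry import extract_pupil_outcomes
from gonogo.simulate import (
    simulate_decision,
    simulate_gaze_trial,
    simulate_hand_trial,
    simulate_pupil_trial,
    simulate_rtt_presses,
    simulate_session,
)
from gonogo.task_design import (
    generate_rtt_schedule,
    generate_session_schedules,
    stimulus_position_clamped,
)
from gonogo.trace_processing import extract_eye_outcomes, extract_hand_outcomes
from tests.conftest import make_spec, quiet_profile


def _touch_rates(profile, n, rng):
    go = sum(
        simulate_decision(profile, make_spec(is_go=True), rng).touch_intended
        for _ in range(n)
    )
    nogo = sum(
        simulate_decision(profile, make_spec(is_go=False, location=1), rng).touch_intended
        for _ in range(n)
    )
    return go / n, nogo / n


class TestDecision:
    def test_chance_responder(self):
        profile = control_profile(
            dprime_by_speed={485.0: 0.0}, criterion_lambda=0.0)
        h, f = _touch_rates(profile, 2000, np.random.default_rng(0))
        assert abs(h - 0.5) < 0.03 and abs(f - 0.5) < 0.03

    def test_hit_and_fa_rates_match_normal_cdf(self):
        # d'=2, threshold 1: hit rate Phi(1), false-alarm rate Phi(-1)
        profile = control_profile(
            dprime_by_speed={485.0: 2.0}, criterion_lambda=1.0)
        h, f = _touch_rates(profile, 4000, np.random.default_rng(1))
        assert abs(h - norm.cdf(1.0)) < 0.02
        assert abs(f - norm.cdf(-1.0)) < 0.02

    def test_extreme_criterion_never_touches(self):
        profile = control_profile(criterion_lambda=1e9)
        rng = np.random.default_rng(2)
        assert all(
            not simulate_decision(profile, make_spec(), rng).touch_intended
            for _ in range(100)
        )

    def test_planned_touch_is_reaction_plus_movement(self):
        profile = quiet_profile(hand_rt_mean_ms=350.0, hand_movement_ms=170.0,
                                criterion_lambda=-1e9)
        dec = simulate_decision(profile, make_spec(), np.random.default_rng(0))
        assert dec.touch_intended
        assert dec.planned_touch_ms == pytest.approx(520.0)


class TestGaze:
    def test_perfect_tracking_equals_stimulus_path(self, geometry):
        profile = quiet_profile(pursuit_gain=1.0, pursuit_lag_ms=0.0,
                                saccade_latency_mean_ms=0.0)
        spec = make_spec(flight=585.0, location=6)
        rng = np.random.default_rng(0)
        t, gx, gy, truth = simulate_gaze_trial(profile, spec, geometry, rng)
        onset = spec.stimulus_onset_ms
        expect = stimulus_position_clamped(spec, geometry, t - onset)
        mask = t >= onset
        assert np.allclose(gx[mask], expect[mask, 0], atol=1e-9)
        assert np.allclose(gy[mask], expect[mask, 1], atol=1e-9)
        pre = ~mask
        assert np.allclose(gx[pre], geometry.fixation_pos[0])
        assert np.allclose(gy[pre], geometry.fixation_pos[1])

    def test_latency_fixture_recovered_by_detector(self, geometry):
        profile = quiet_profile(saccade_latency_mean_ms=180.0)
        spec = make_spec(flight=485.0, location=6)
        t, gx, gy, truth = simulate_gaze_trial(
            profile, spec, geometry, np.random.default_rng(0))
        assert truth["saccade_latency_ms"] == 180.0
        out = extract_eye_outcomes(t, gx, gy, spec, geometry)
        assert out["eye_rt_ms"] == pytest.approx(180.0, abs=5.0)

    def test_zero_gain_pursuit_loses_the_stimulus(self, geometry):
        profile = quiet_profile(pursuit_gain=0.01, saccade_latency_mean_ms=200.0)
        spec = make_spec(flight=585.0, location=6)
        t, gx, gy, _ = simulate_gaze_trial(
            profile, spec, geometry, np.random.default_rng(0))
        out = extract_eye_outcomes(t, gx, gy, spec, geometry)
        assert out["tracking_pct"] < 100.0
        # late stimulus positions are > 8 deg from the frozen gaze
        end = stimulus_position_clamped(spec, geometry, spec.effective_flight_ms)
        i_end = np.argmin(np.abs(t - spec.stimulus_end_ms))
        assert np.hypot(gx[i_end] - end[0], gy[i_end] - end[1]) > 8.0


class TestPupil:
    def test_flat_profile_gives_constant_baseline(self):
        profile = quiet_profile(pupil_amplitude_mm=0.0,
                                pupil_fixation_slope_mm_s=0.0)
        spec = make_spec()
        t, pupil, _ = simulate_pupil_trial(profile, spec, np.random.default_rng(0))
        assert np.allclose(pupil, profile.pupil_baseline_mm)
        out = extract_pupil_outcomes(t, pupil, spec)
        assert out["peak_size_change_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_latency_to_peak_fixture_recovered(self):
        profile = quiet_profile()
        profile.pupil_latency_to_peak_ms[(390.0, 585.0)] = 900.0
        spec = make_spec(fixation=390.0, flight=585.0)
        t, pupil, truth = simulate_pupil_trial(profile, spec, np.random.default_rng(0))
        assert truth["pupil_t_peak_ms"] == 900.0
        out = extract_pupil_outcomes(t, pupil, spec)
        assert out["latency_to_peak_ms"] == pytest.approx(900.0, abs=5.0)

    def test_fixation_ramp_slope_recovered_exactly(self):
        profile = quiet_profile(pupil_amplitude_mm=0.0,
                                pupil_fixation_slope_mm_s=0.27)
        spec = make_spec(fixation=890.0)
        t, pupil, _ = simulate_pupil_trial(profile, spec, np.random.default_rng(0))
        out = extract_pupil_outcomes(t, pupil, spec)
        assert out["slope_fixation_mm_s"] == pytest.approx(0.27, abs=1e-9)


class TestHand:
    def test_no_touch_trial_stays_subthreshold(self, geometry):
        profile = quiet_profile()
        dec = simulate_decision(
            quiet_profile(criterion_lambda=1e9), make_spec(), np.random.default_rng(0))
        t, speed, hx, hy, event = simulate_hand_trial(
            profile, make_spec(), dec, geometry, np.random.default_rng(1))
        assert not event["touched"]
        assert np.all(speed < 20.0)

    def test_reaction_and_touch_fixture_recovered(self, geometry):
        profile = quiet_profile(hand_rt_mean_ms=350.0, hand_movement_ms=170.0,
                                criterion_lambda=-1e9)
        spec = make_spec(flight=585.0)
        rng = np.random.default_rng(3)
        dec = simulate_decision(profile, spec, rng)
        t, speed, hx, hy, event = simulate_hand_trial(
            profile, spec, dec, geometry, rng)
        out = extract_hand_outcomes(t, speed, event, spec)
        assert out["hand_rt_ms"] == pytest.approx(350.0, abs=5.0)
        assert out["touch_time_ms"] == pytest.approx(520.0, abs=5.0)

    def test_late_touch_on_go_trial_is_a_miss(self, geometry):
        profile = quiet_profile(hand_rt_mean_ms=400.0, criterion_lambda=-1e9)
        spec = make_spec(flight=385.0, is_go=True)
        dec = simulate_decision(profile, spec, np.random.default_rng(0))
        assert dec.planned_touch_ms > spec.effective_flight_ms
        assert classify_response(spec, dec.touch_intended, dec.planned_touch_ms) == "miss"


class TestSession:
    def test_determinism_and_shape(self, geometry):
        schedules = generate_session_schedules(geometry, n_blocks=3, seed=0)
        profile = expert_profile()
        a = simulate_session(profile, schedules, geometry, seed=7, subject="x")
        b = simulate_session(profile, schedules, geometry, seed=7, subject="x")
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert len(a.events) == 240
        assert len(a.truth) == 240
        c = simulate_session(profile, schedules, geometry, seed=8, subject="x")
        assert not a.samples.equals(c.samples)

    def test_sampling_rate_is_200hz(self, geometry):
        schedules = generate_session_schedules(geometry, n_blocks=1, seed=1)
        traces = simulate_session(quiet_profile(), schedules[:1], geometry, seed=1)
        for _, g in traces.samples.groupby(["block", "trial"]):
            assert np.allclose(np.diff(g["t_ms"]), 5.0)

    def test_rtt_press_simulation(self):
        sched = generate_rtt_schedule(seed=0)
        presses = simulate_rtt_presses(control_profile(), sched,
                                       np.random.default_rng(0))
        assert len(presses) == 50
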