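"""QC, velocity computation, and the eye/hand outcome detectors."""

import numpy as np
import pandas as pd
import pytest

from gonogo.profiles import control_profile
from gonogo.simulate import _trapezoid_distance, simulate_session
from gonogo.task_design import TptDesign, generate_session_schedules
from gonogo.trace_processing import (
    DetectorConfig,
    angular_velocity,
    clean_trace,
    extract_eye_outcomes,
    extract_hand_outcomes,
    extract_outcomes,
    reliability_gate,
)
from tests.conftest import make_spec, quiet_profile

SMALL_DESIGN = TptDesign(reps_per_speed_location=1, probes_per_location=0)


@pytest.fixture()
def small_session(geometry):
    schedules = generate_session_schedules(
        geometry, n_blocks=1, design=SMALL_DESIGN, seed=3)
    return simulate_session(quiet_profile(), schedules, geometry, seed=3)


class TestCleanTrace:
    def test_blink_free_trial_valid_and_unchanged(self, small_session):
        clean = clean_trace(small_session)
        assert clean.validity["valid"].all()
        pd.testing.assert_frame_equal(clean.samples, small_session.samples)

    def test_long_blink_over_stimulus_onset_rejected(self, small_session):
        s = small_session
        block, trial = 0, s.events["trial"].iloc[0]
        spec = s.specs[(block, trial)]
        mask = (
            (s.samples["trial"] == trial)
            & (s.samples["t_ms"] >= spec.stimulus_onset_ms - 200)
            & (s.samples["t_ms"] < spec.stimulus_onset_ms + 200)
        )
        s.samples.loc[mask, ["gaze_x_deg", "gaze_y_deg", "pupil_mm"]] = np.nan
        s.samples.loc[mask, "blink"] = 1
        clean = clean_trace(s)
        row = clean.validity.set_index("trial").loc[trial]
        assert not row["valid"]
        assert row["reason"] == "blink"

    def test_excessive_missingness_rejected(self, small_session):
        s = small_session
        trial = s.events["trial"].iloc[1]
        mask = s.samples["trial"] == trial
        idx = s.samples.index[mask]
        drop = idx[: int(0.4 * len(idx))]
        s.samples.loc[drop, ["gaze_x_deg", "gaze_y_deg", "pupil_mm"]] = np.nan
        clean = clean_trace(s)
        row = clean.validity.set_index("trial").loc[trial]
        assert not row["valid"]
        assert row["reason"] == "missing"

    def test_short_blink_is_interpolated(self, small_session):
        s = small_session
        trial = s.events["trial"].iloc[2]
        spec = s.specs[(0, trial)]
        # 50 ms blink in the middle of fixation, clear of critical windows
        mask = (
            (s.samples["trial"] == trial)
            & (s.samples["t_ms"] >= 150) & (s.samples["t_ms"] < 200)
        )
        s.samples.loc[mask, ["gaze_x_deg", "gaze_y_deg", "pupil_mm"]] = np.nan
        s.samples.loc[mask, "blink"] = 1
        clean = clean_trace(s)
        assert clean.validity.set_index("trial").loc[trial, "valid"]
        g = clean.samples[clean.samples["trial"] == trial]
        assert g["gaze_x_deg"].notna().all()
        assert g["pupil_mm"].notna().all()

    def test_non_monotone_timestamps_raise(self, small_session):
        s = small_session
        s.samples.loc[5, "t_ms"] = s.samples.loc[4, "t_ms"]
        with pytest.raises(ValueError, match="monotone"):
            clean_trace(s)


class TestAngularVelocity:
    def test_constant_position_zero_speed(self):
        v = angular_velocity(np.full(100, 2.0), np.full(100, -1.0))
        assert np.allclose(v, 0.0)

    def test_linear_motion_exact_speed(self):
        n = 201  # 1 s at 200 Hz
        x = np.linspace(0.0, 30.0, n)
        v = angular_velocity(x, np.zeros(n))
        assert np.allclose(v[5:-5], 30.0, atol=1e-9)

    def test_step_displacement_peak_matches_central_difference(self):
        # 5 deg step across one 5 ms interval: the unsmoothed central
        # difference spans 10 ms, so the peak is 5 deg / 10 ms = 500 deg/s
        x = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        v = angular_velocity(x, np.zeros(20), smooth_samples=1)
        assert v.max() == pytest.approx(500.0)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            angular_velocity(np.zeros(2), np.zeros(2))


class TestEyeOutcomes:
    def test_gaze_on_stimulus_tracks_everything(self, geometry):
        from gonogo.task_design import stimulus_position_clamped

        spec = make_spec(fixation=390.0, flight=585.0, location=6)
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        pos = stimulus_position_clamped(spec, geometry, t - spec.stimulus_onset_ms)
        out = extract_eye_outcomes(t, pos[:, 0], pos[:, 1], spec, geometry)
        assert out["tracking_pct"] == pytest.approx(100.0)
        assert out["mean_gsd_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_static_gaze_tracks_only_nearby_stimulus(self, geometry):
        spec = make_spec(fixation=390.0, flight=585.0, location=6)
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        fx, fy = geometry.fixation_pos
        out = extract_eye_outcomes(
            t, np.full_like(t, fx), np.full_like(t, fy), spec, geometry)
        # geometry oracle on the straight-line path
        loc = np.asarray(geometry.final_locations[spec.final_location_index - 1])
        path_len = np.hypot(*(loc - np.asarray(geometry.fixation_pos)))
        taus = np.arange(0, spec.effective_flight_ms, 5.0)
        dists = taus / spec.effective_flight_ms * path_len
        near = dists < 8.0
        assert out["tracking_ms"] == pytest.approx(near.sum() * 5.0)
        assert out["mean_gsd_deg"] == pytest.approx(dists[near].mean(), abs=1e-9)
        assert out["eye_rt_reason"] == "no saccade"
        assert np.isnan(out["eye_rt_ms"])
        assert out["fixation_error_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_saccade_latency_and_amplitude(self, geometry):
        spec = make_spec(fixation=390.0, flight=585.0, location=6)
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        onset = spec.stimulus_onset_ms + 200.0  # latency 200 ms
        amp, vmax = 12.0, 200.0
        dur = amp / vmax * 1000.0 + 10.0
        s = _trapezoid_distance(np.clip(t - onset, 0, dur), vmax, dur)
        gx = np.zeros_like(t)
        gy = 20.0 - s  # straight downward saccade
        out = extract_eye_outcomes(t, gx, gy, spec, geometry)
        assert out["eye_rt_ms"] == pytest.approx(200.0, abs=5.0)
        assert out["saccade_amp_deg"] == pytest.approx(12.0, abs=0.5)

    def test_threshold_monotonicity(self, small_session, geometry):
        """Raising the velocity threshold never shortens eye response time."""
        g = small_session.samples
        for (_, trial), grp in list(g.groupby(["block", "trial"]))[:6]:
            spec = small_session.specs[(0, trial)]
            t = grp["t_ms"].to_numpy()
            gx = grp["gaze_x_deg"].to_numpy()
            gy = grp["gaze_y_deg"].to_numpy()
            prev = -np.inf
            for thr in (30.0, 50.0, 80.0, 120.0):
                cfg = DetectorConfig(saccade_velocity_deg_s=thr)
                rt = extract_eye_outcomes(t, gx, gy, spec, geometry, cfg)["eye_rt_ms"]
                if np.isnan(rt):
                    break
                assert rt >= prev
                prev = rt


class TestHandOutcomes:
    def test_subthreshold_speed_never_detected(self):
        spec = make_spec()
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        event = {"touched": True, "touch_t_ms": spec.stimulus_onset_ms + 400.0}
        out = extract_hand_outcomes(t, np.full_like(t, 19.9), event, spec)
        assert np.isnan(out["hand_rt_ms"])
        assert out["hand_reason"] == "no movement"

    def test_no_touch_trial_fields_absent(self):
        spec = make_spec()
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        out = extract_hand_outcomes(t, np.zeros_like(t), {"touched": False}, spec)
        assert np.isnan(out["hand_rt_ms"]) and np.isnan(out["touch_time_ms"])
        assert out["hand_reason"] == "no touch"

    def test_touch_before_movement_flags_inconsistency(self):
        spec = make_spec()
        t = np.arange(0, spec.trial_end_ms + 2.5, 5.0)
        speed = np.where(t > spec.stimulus_onset_ms + 300.0, 100.0, 0.0)
        event = {"touched": True, "touch_t_ms": spec.stimulus_onset_ms + 100.0}
        out = extract_hand_outcomes(t, speed, event, spec)
        assert out["hand_flag"] == "inconsistent kinematics"


class TestReliabilityGate:
    @pytest.mark.parametrize("n_valid,included", [(9, False), (10, True), (0, False)])
    def test_min_trial_rule(self, n_valid, included):
        rows = [{"subject": "s1", "valid": True, "latency_to_peak_ms": 700.0}
                for _ in range(n_valid)]
        rows += [{"subject": "s1", "valid": False, "latency_to_peak_ms": np.nan}
                 for _ in range(12 - n_valid)]
        gate = reliability_gate(pd.DataFrame(rows),
                                parameters=("latency_to_peak_ms",))
        assert bool(gate["included"].iloc[0]) == included
        assert int(gate["n_reliable"].iloc[0]) == n_valid


class TestExtractionInvariants:
    def test_tracking_time_and_percentage_consistent(self, small_session):
        clean = clean_trace(small_session)
        out = extract_outcomes(clean)
        valid = out[out["valid"]]
        flight = valid["flight_ms"] + [
            small_session.specs[(0, t)].jitter_ms for t in valid["trial"]
        ]
        assert np.allclose(valid["tracking_ms"] / flight * 100.0,
                           valid["tracking_pct"])
        assert (valid["tracking_pct"] <= 100.0 + 1e-9).all()
        gsd = valid["mean_gsd_deg"].dropna()
        assert (gsd < 8.0).all()
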