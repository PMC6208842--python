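import numpy as np
import pytest

from gonogo.profiles import control_profile
from gonogo.task_design import TrialSpec, build_geometry


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


def quiet_profile(**overrides):
    """Noise-free control subject for oracle-equivalence tests: no gaze or
    pupil noise, no drift, no blinks, deterministic latencies, and a saccade
    peak velocity pinned to 200 deg/s so the velocity-threshold detector
    locates onsets within one sample."""
    base = dict(
        gaze_noise_sd_deg=0.0,
        fixation_drift_deg_s=0.0,
        blink_rate_per_min=0.0,
        pupil_noise_sd_mm=0.0,
        saccade_latency_sd_ms=0.0,
        hand_rt_sd_ms=0.0,
        saccade_peak_velocity_min=200.0,
        saccade_peak_velocity_max=200.0,
        pursuit_gain=0.3,
    )
    base.update(overrides)
    return control_profile(**base)


def make_spec(fixation=390.0, flight=485.0, jitter=0.0, location=2,
              is_go=True, is_probe=False, trial_id=0):
    return TrialSpec(
        trial_id=trial_id,
        fixation_duration_ms=fixation,
        flight_duration_ms=flight,
        jitter_ms=jitter,
        final_location_index=location,
        is_go=is_go,
        is_probe=is_probe,
    )
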