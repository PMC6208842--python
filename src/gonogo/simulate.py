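"""Synthetic session simulator.

Generates complete sessions — go/no-go choices plus 200 Hz gaze, pupil and
hand traces — from a :class:`~gonogo.profiles.SubjectProfile`, together with
the hidden ground truth (intended responses, saccade latencies, pupil peak
times, hand reaction times) so that every downstream extraction stage can be
tested by parameter recovery.

Trial timeline (all times in ms from trial onset):

* ``[0, fixation)``             fixation cross; gaze = cross + drift + noise,
  pupil = baseline + linear ramp
* ``[fixation, fixation+flight)``  stimulus flight; after a saccadic latency
  the gaze jumps to the stimulus and pursues it with lag and gain; the pupil
  dilation component (a smooth, unimodal Erlang-style kernel) rises toward
  its condition-dependent peak
* ``[.., +500 ms]``             feedback; traces simply continue (no modeled
  gaze shift)

Movement speed profiles (saccades, hand) are trapezoidal with a 10 ms rise,
so a velocity-threshold detector locates the true onset to within one
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import SubjectProfile
from .task_design import (
    SAMPLE_INTERVAL_MS,
    BlockSchedule,
    RttSchedule,
    TaskGeometry,
    TrialSpec,
    stimulus_position_clamped,
)

_RISE_MS = 10.0  # rise/fall time of the trapezoidal speed profiles


@dataclass
class Decision:
    """Ground truth of one simulated go/no-go decision."""

    touch_intended: bool
    evidence: float
    hand_rt_ms: float | None = None  # movement onset, relative to stimulus onset
    planned_touch_ms: float | None = None  # touch, relative to stimulus onset


@dataclass
class SessionTraces:
    """Per-trial 200 Hz samples plus events, specs and generator truth."""

    subject: str
    samples: pd.DataFrame  # long format, one row per 5 ms sample
    events: pd.DataFrame  # one row per trial: touched, touch_t_ms, touch_x, touch_y
    truth: pd.DataFrame  # one row per trial: hidden generator parameters
    specs: dict = field(default_factory=dict)  # (block, trial_id) -> TrialSpec
    geometry: TaskGeometry | None = None


def simulate_decision(profile: SubjectProfile, spec: TrialSpec, rng) -> Decision:
    """Equal-variance signal-detection choice plus response timing.

    Evidence ``e ~ Normal(d'(speed) * 1{go}, 1)``; the subject touches iff
    ``e`` exceeds the profile's criterion (absolute threshold on the evidence
    axis).  When a touch is intended, movement onset is the hand reaction
    draw and the touch lands one movement duration later — occasionally
    after flight end on fast trials, which downstream classification counts
    as a miss (lateness as a second miss mechanism).
    """
    mean = profile.dprime_for(spec.flight_duration_ms) if spec.is_go else 0.0
    e = float(rng.normal(mean, 1.0))
    touch = e > profile.criterion_lambda
    if not touch:
        return Decision(touch_intended=False, evidence=e)
    hand_rt = max(0.0, float(rng.normal(profile.hand_rt_mean_ms, profile.hand_rt_sd_ms)))
    return Decision(
        touch_intended=True,
        evidence=e,
        hand_rt_ms=hand_rt,
        planned_touch_ms=hand_rt + profile.hand_movement_ms,
    )


def _saccade_kinematics(profile: SubjectProfile, amplitude_deg: float):
    """Peak velocity (deg/s) and duration (ms) for a saccade of the given
    amplitude; peak velocity scales with amplitude between a floor and cap."""
    vmax = float(
        np.clip(
            profile.saccade_peak_velocity_scale * amplitude_deg,
            profile.saccade_peak_velocity_min,
            profile.saccade_peak_velocity_max,
        )
    )
    dur = amplitude_deg / vmax * 1000.0 + _RISE_MS
    if dur < 2 * _RISE_MS:  # tiny movement: triangular profile over 2*rise
        dur = 2 * _RISE_MS
        vmax = amplitude_deg * 1000.0 / _RISE_MS
    return vmax, dur


def _trapezoid_speed(tau_ms, vmax, dur_ms, rise_ms=_RISE_MS):
    """Speed (deg/s) of a trapezoidal profile at ``tau_ms`` after onset."""
    tau = np.asarray(tau_ms, dtype=float)
    up = np.clip(tau / rise_ms, 0.0, 1.0)
    down = np.clip((dur_ms - tau) / rise_ms, 0.0, 1.0)
    inside = (tau >= 0) & (tau <= dur_ms)
    return vmax * np.minimum(up, down) * inside


def _trapezoid_distance(tau_ms, vmax, dur_ms, rise_ms=_RISE_MS):
    """Distance travelled (deg) by ``tau_ms`` under the trapezoidal profile."""
    tau = np.clip(np.asarray(tau_ms, dtype=float), 0.0, dur_ms)
    total = vmax * (dur_ms - rise_ms) / 1000.0
    s = np.where(
        tau <= rise_ms,
        vmax * tau**2 / (2 * rise_ms) / 1000.0,
        np.where(
            tau <= dur_ms - rise_ms,
            vmax * (rise_ms / 2 + (tau - rise_ms)) / 1000.0,
            total - vmax * (dur_ms - tau) ** 2 / (2 * rise_ms) / 1000.0,
        ),
    )
    return s


def _trial_times(spec: TrialSpec) -> np.ndarray:
    n = int(round(spec.trial_end_ms / SAMPLE_INTERVAL_MS)) + 1
    return np.arange(n) * SAMPLE_INTERVAL_MS


def simulate_gaze_trial(
    profile: SubjectProfile,
    spec: TrialSpec,
    geometry: TaskGeometry,
    rng,
    t_ms: np.ndarray | None = None,
):
    """Gaze x/y for one trial.

    Fixation-period gaze is the cross position plus a slow drift (rate set by
    the profile's fixation-stability parameter) and white noise.  After a
    saccadic latency draw the gaze makes a saccade aimed at the stimulus
    position expected at saccade landing, then pursues the stimulus with the
    profile's lag and gain.  Returns ``(t, gx, gy, truth)`` where ``truth``
    records the latency, amplitude and landing time actually generated.
    """
    t = _trial_times(spec) if t_ms is None else t_ms
    onset = spec.stimulus_onset_ms
    flight_end = spec.stimulus_end_ms
    fx, fy = geometry.fixation_pos

    theta = rng.uniform(0.0, 2 * np.pi)
    drift = profile.fixation_drift_deg_s * np.array([np.cos(theta), np.sin(theta)])
    latency = max(0.0, float(rng.normal(profile.saccade_latency_mean_ms,
                                        profile.saccade_latency_sd_ms)))
    t_on = onset + latency

    def stim(at_ms):
        return stimulus_position_clamped(spec, geometry, np.asarray(at_ms) - onset)

    g0 = np.array([fx, fy]) + drift * (t_on / 1000.0)
    # aim at the stimulus position expected at landing (one fixed-point step)
    amp0 = float(np.hypot(*(stim(t_on) - g0)))
    _, d0 = _saccade_kinematics(profile, amp0) if amp0 > 1e-9 else (0.0, 0.0)
    target = stim(t_on + d0)
    amp = float(np.hypot(*(target - g0)))
    if amp > 1e-9:
        vmax, dur = _saccade_kinematics(profile, amp)
        unit = (target - g0) / amp
    else:
        vmax, dur = 0.0, 0.0
        unit = np.zeros(2)
        target = g0
    t_end_sacc = t_on + dur

    lag = profile.pursuit_lag_ms
    gain = profile.pursuit_gain
    anchor = stim(t_end_sacc - lag)

    gx = np.empty_like(t)
    gy = np.empty_like(t)

    pre = t < t_on
    gx[pre] = fx + drift[0] * t[pre] / 1000.0
    gy[pre] = fy + drift[1] * t[pre] / 1000.0

    sacc = (t >= t_on) & (t < t_end_sacc)
    if np.any(sacc):
        s = _trapezoid_distance(t[sacc] - t_on, vmax, dur)
        gx[sacc] = g0[0] + unit[0] * s
        gy[sacc] = g0[1] + unit[1] * s

    post = t >= t_end_sacc
    if np.any(post):
        p = stim(t[post] - lag)
        gx[post] = target[0] + gain * (p[:, 0] - anchor[0])
        gy[post] = target[1] + gain * (p[:, 1] - anchor[1])

    if profile.gaze_noise_sd_deg > 0:
        gx = gx + rng.normal(0.0, profile.gaze_noise_sd_deg, size=t.shape)
        gy = gy + rng.normal(0.0, profile.gaze_noise_sd_deg, size=t.shape)

    truth = {
        "saccade_latency_ms": latency,
        "saccade_onset_ms": t_on,
        "saccade_amp_deg": amp,
        "saccade_end_ms": t_end_sacc,
        "saccade_peak_speed_deg_s": vmax,
    }
    return t, gx, gy, truth


def simulate_pupil_trial(
    profile: SubjectProfile,
    spec: TrialSpec,
    rng,
    t_ms: np.ndarray | None = None,
):
    """Pupil diameter (mm) for one trial.

    Baseline plus a linear ramp across the fixation period (profile's
    fixation slope, mm/s) plus a task-evoked dilation: an Erlang-style
    unimodal kernel anchored at stimulus onset and peaking at the profile's
    per-condition latency-to-peak (measured from trial onset).  Returns
    ``(t, pupil, truth)``.
    """
    t = _trial_times(spec) if t_ms is None else t_ms
    fix = spec.fixation_duration_ms
    t_peak = profile.latency_to_peak_for(fix, spec.flight_duration_ms)
    if t_peak <= fix:
        raise ValueError("latency_to_peak must fall after fixation end")
    tau = t - fix
    scale = t_peak - fix
    z = np.clip(tau / scale, 0.0, None)
    s = profile.pupil_kernel_shape
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = np.where(z > 0, z**s * np.exp(s * (1.0 - z)), 0.0)
    pupil = (
        profile.pupil_baseline_mm
        + profile.pupil_fixation_slope_mm_s * np.clip(t, 0.0, fix) / 1000.0
        + profile.pupil_amplitude_mm * kernel
    )
    if profile.pupil_noise_sd_mm > 0:
        pupil = pupil + rng.normal(0.0, profile.pupil_noise_sd_mm, size=t.shape)
    pupil = np.maximum(pupil, 0.2)
    truth = {
        "pupil_t_peak_ms": t_peak,
        "pupil_fixation_slope_mm_s": profile.pupil_fixation_slope_mm_s,
        "pupil_amplitude_mm": profile.pupil_amplitude_mm,
    }
    return t, pupil, truth


def simulate_hand_trial(
    profile: SubjectProfile,
    spec: TrialSpec,
    decision: Decision,
    geometry: TaskGeometry,
    rng,
    t_ms: np.ndarray | None = None,
):
    """Hand speed/position for one trial plus the touch event (or none).

    On no-touch trials the speed channel is sub-threshold noise (clipped
    strictly below the 20 deg/s detection threshold).  On touch trials a
    trapezoidal speed burst starts at the hand reaction time and the touch
    registers at the planned touch time at the (noisy) predicted endpoint.
    """
    t = _trial_times(spec) if t_ms is None else t_ms
    onset = spec.stimulus_onset_ms
    noise = np.abs(rng.normal(0.0, profile.hand_noise_sd_deg_s, size=t.shape))
    speed = np.minimum(noise, 15.0)
    rest = np.array([0.0, -geometry.screen_halfheight_deg - 1.0])
    hx = np.full_like(t, rest[0])
    hy = np.full_like(t, rest[1])

    if not decision.touch_intended:
        event = {"touched": False, "touch_t_ms": np.nan,
                 "touch_x_deg": np.nan, "touch_y_deg": np.nan}
        return t, speed, hx, hy, event

    move_on = onset + decision.hand_rt_ms
    dur = profile.hand_movement_ms
    burst = _trapezoid_speed(t - move_on, profile.hand_peak_speed_deg_s, dur)
    speed = np.maximum(speed, burst)

    loc = np.asarray(geometry.final_locations[spec.final_location_index - 1])
    touch_pos = loc + rng.normal(0.0, profile.touch_error_sd_deg, size=2)
    total = _trapezoid_distance(dur, profile.hand_peak_speed_deg_s, dur)
    frac = _trapezoid_distance(np.clip(t - move_on, 0.0, dur),
                               profile.hand_peak_speed_deg_s, dur) / max(total, 1e-9)
    hx = rest[0] + (touch_pos[0] - rest[0]) * frac
    hy = rest[1] + (touch_pos[1] - rest[1]) * frac

    event = {
        "touched": True,
        "touch_t_ms": onset + decision.planned_touch_ms,
        "touch_x_deg": float(touch_pos[0]),
        "touch_y_deg": float(touch_pos[1]),
    }
    return t, speed, hx, hy, event


def _apply_blinks(profile: SubjectProfile, t, channels, rng):
    """Poisson blink onsets; affected samples are flagged and blanked."""
    blink = np.zeros(t.shape, dtype=bool)
    total_ms = t[-1] if len(t) else 0.0
    n = rng.poisson(profile.blink_rate_per_min * total_ms / 60000.0)
    for onset in np.sort(rng.uniform(0.0, total_ms, size=n)):
        blink |= (t >= onset) & (t < onset + profile.blink_duration_ms)
    for ch in channels:
        ch[blink] = np.nan
    return blink


def simulate_trial(profile, spec, geometry, rng):
    decision = simulate_decision(profile, spec, rng)
    t, gx, gy, gaze_truth = simulate_gaze_trial(profile, spec, geometry, rng)
    _, pupil, pupil_truth = simulate_pupil_trial(profile, spec, rng, t_ms=t)
    _, speed, hx, hy, event = simulate_hand_trial(
        profile, spec, decision, geometry, rng, t_ms=t
    )
    blink = _apply_blinks(profile, t, [gx, gy, pupil], rng)
    truth = {
        "is_go": spec.is_go,
        "flight_ms": spec.flight_duration_ms,
        "fixation_ms": spec.fixation_duration_ms,
        "dprime": profile.dprime_for(spec.flight_duration_ms),
        "evidence": decision.evidence,
        "touch_intended": decision.touch_intended,
        "hand_rt_ms": decision.hand_rt_ms if decision.hand_rt_ms is not None else np.nan,
        "planned_touch_ms": (
            decision.planned_touch_ms if decision.planned_touch_ms is not None else np.nan
        ),
        **gaze_truth,
        **pupil_truth,
    }
    samples = {
        "t_ms": t, "gaze_x_deg": gx, "gaze_y_deg": gy, "pupil_mm": pupil,
        "hand_speed_deg_s": speed, "hand_x_deg": hx, "hand_y_deg": hy,
        "blink": blink.astype(int),
    }
    return samples, event, truth


def simulate_session(
    profile: SubjectProfile,
    schedules: list[BlockSchedule],
    geometry: TaskGeometry,
    seed: int,
    subject: str = "s0",
) -> SessionTraces:
    """Simulate a full session over the given block schedules.

    Deterministic: identical (profile, schedules, seed) give identical
    traces, events and truth.  Each trial consumes an independent child
    stream spawned from the session seed.
    """
    master = np.random.default_rng(seed)
    n_trials = sum(len(b) for b in schedules)
    streams = master.spawn(n_trials)

    sample_frames = []
    events = []
    truths = []
    specs = {}
    k = 0
    for block in schedules:
        for spec in block.trials:
            rng = streams[k]
            k += 1
            samples, event, truth = simulate_trial(profile, spec, geometry, rng)
            n = len(samples["t_ms"])
            frame = pd.DataFrame(samples)
            frame.insert(0, "trial", spec.trial_id)
            frame.insert(0, "block", block.block_index)
            frame.insert(0, "subject", subject)
            sample_frames.append(frame)
            events.append({"subject": subject, "block": block.block_index,
                           "trial": spec.trial_id, **event})
            truths.append({"subject": subject, "block": block.block_index,
                           "trial": spec.trial_id, **truth})
            specs[(block.block_index, spec.trial_id)] = spec

    return SessionTraces(
        subject=subject,
        samples=pd.concat(sample_frames, ignore_index=True),
        events=pd.DataFrame(events),
        truth=pd.DataFrame(truths),
        specs=specs,
        geometry=geometry,
    )


def simulate_rtt_presses(profile: SubjectProfile, schedule: RttSchedule, rng):
    """Key-press times (ms after stimulus onset) for the reaction-time task.

    Mostly Gaussian reaction times around the profile mean; a small fraction
    of anticipations (presses inside the 125 ms catch window) and lapses
    (no press) exercise the downstream filters.
    """
    presses = np.empty(schedule.n_trials)
    for i in range(schedule.n_trials):
        u = rng.uniform()
        if u < 0.02:  # anticipation -> catch trial
            presses[i] = rng.uniform(0.0, schedule.catch_threshold_ms)
        elif u < 0.04:  # lapse
            presses[i] = np.nan
        else:
            presses[i] = max(0.0, rng.normal(profile.rtt_rt_mean_ms, profile.rtt_rt_sd_ms))
    return presses
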