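"""Generative parameters of a simulated subject.

A :class:`SubjectProfile` collects every parameter the session simulator
needs: simple reaction time, saccade latency and kinematics, pursuit lag and
gain, fixation stability, blink statistics, the task-evoked pupillary
response (baseline, fixation ramp slope, dilation amplitude and per-condition
latency to peak), hand kinematics, and the signal-detection decision model
(per-speed sensitivity d' and a fixed criterion).

Two presets are provided.  ``control`` is a neutral observer.  ``expert``
shifts the parameters in the directions reported for elite athletes on this
task: higher d' at every flight speed, earlier pupil peak at the short
fixation duration, later peak at the long fixation duration, and a steadier
fixation (smaller drift, hence smaller fixation error on long fixations).
The shift magnitudes are package defaults chosen to be physiologically
plausible, not claims about human effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .task_design import (
    FIXATION_DURATIONS_MS,
    FLIGHT_DURATIONS_MS,
    PROBE_FIXATION_MS,
    PROBE_FLIGHT_MS,
)


def _latency_table(short_shift_ms: float = 0.0, long_shift_ms: float = 0.0) -> dict:
    """Latency-to-peak of the pupil response per (fixation, flight) condition,
    measured from trial (fixation) onset.

    Baseline rule: the peak falls at fixation end plus 60% of the flight for
    short/normal fixations; for the long (1900 ms) fixation arousal has
    largely ramped during fixation, so the peak sits earlier within the
    flight (20%).  Group shifts apply to the short and long fixation rows.
    All values stay inside the trial (fixation + flight).
    """
    table: dict[tuple[float, float], float] = {}
    for fix in FIXATION_DURATIONS_MS:
        for flight in FLIGHT_DURATIONS_MS:
            if fix == 390.0:
                t = fix + 0.6 * flight + short_shift_ms
            elif fix == 1900.0:
                t = fix + 0.2 * flight + long_shift_ms
            else:
                t = fix + 0.6 * flight
            table[(fix, flight)] = t
    table[(PROBE_FIXATION_MS, PROBE_FLIGHT_MS)] = PROBE_FIXATION_MS + 0.5 * PROBE_FLIGHT_MS
    return table


@dataclass
class SubjectProfile:
    group: str = "control"

    # simple reaction-time task
    rtt_rt_mean_ms: float = 312.0
    rtt_rt_sd_ms: float = 35.0

    # saccades
    saccade_latency_mean_ms: float = 210.0
    saccade_latency_sd_ms: float = 25.0
    saccade_peak_velocity_scale: float = 30.0  # deg/s per deg of amplitude
    saccade_peak_velocity_min: float = 80.0
    saccade_peak_velocity_max: float = 600.0

    # pursuit
    pursuit_lag_ms: float = 100.0
    pursuit_gain: float = 0.5

    # fixation stability
    gaze_noise_sd_deg: float = 0.3
    fixation_drift_deg_s: float = 0.35

    # blinks
    blink_rate_per_min: float = 12.0
    blink_duration_ms: float = 150.0

    # pupil
    pupil_baseline_mm: float = 3.6
    pupil_amplitude_mm: float = 0.4
    pupil_noise_sd_mm: float = 0.015
    pupil_fixation_slope_mm_s: float = 0.12
    pupil_latency_to_peak_ms: dict = field(default_factory=_latency_table)
    pupil_kernel_shape: float = 4.0

    # hand
    hand_rt_mean_ms: float = 180.0
    hand_rt_sd_ms: float = 30.0
    hand_movement_ms: float = 150.0
    hand_peak_speed_deg_s: float = 220.0
    hand_noise_sd_deg_s: float = 3.0
    touch_error_sd_deg: float = 1.2

    # decision (equal-variance SDT); criterion_lambda is the absolute
    # threshold on the evidence axis: respond iff evidence > lambda.
    dprime_by_speed: dict = field(
        default_factory=lambda: {385.0: 1.14, 485.0: 1.99, 585.0: 2.25, 985.0: 2.40}
    )
    criterion_lambda: float = 0.8

    def __post_init__(self):
        for name in ("rtt_rt_sd_ms", "saccade_latency_sd_ms", "gaze_noise_sd_deg",
                     "pupil_noise_sd_mm", "hand_rt_sd_ms", "touch_error_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.pursuit_gain <= 1.2):
            raise ValueError("pursuit_gain must lie in (0, 1.2]")
        for speed, d in self.dprime_by_speed.items():
            if not (d == d and abs(d) < float("inf")):
                raise ValueError(f"d' for speed {speed} must be finite")

    def dprime_for(self, flight_ms: float) -> float:
        return self.dprime_by_speed[float(flight_ms)]

    def latency_to_peak_for(self, fixation_ms: float, flight_ms: float) -> float:
        return self.pupil_latency_to_peak_ms[(float(fixation_ms), float(flight_ms))]


def control_profile(**overrides) -> SubjectProfile:
    return replace(SubjectProfile(group="control"), **overrides) if overrides else SubjectProfile(group="control")


def expert_profile(**overrides) -> SubjectProfile:
    p = SubjectProfile(
        group="expert",
        rtt_rt_mean_ms=310.0,
        fixation_drift_deg_s=0.15,
        pursuit_gain=0.45,
        pursuit_lag_ms=90.0,
        pupil_latency_to_peak_ms=_latency_table(short_shift_ms=-75.0, long_shift_ms=250.0),
        dprime_by_speed={385.0: 1.48, 485.0: 2.19, 585.0: 2.57, 985.0: 2.70},
    )
    return replace(p, **overrides) if overrides else p


PRESETS = {"control": control_profile, "expert": expert_profile}


def get_profile(name: str, **overrides) -> SubjectProfile:
    try:
        return PRESETS[name](**overrides)
    except KeyError:
        raise ValueError(f"unknown profile preset {name!r}; choose from {sorted(PRESETS)}")
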