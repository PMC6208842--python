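"""Trial QC and the motor-visual outcome parameters.

Implements the seven eye-movement outcomes (total tracking time in ms and as
a percentage of flight, mean gaze-stimulus distance, eye response time,
primary saccade amplitude, fixation error) and the two hand outcomes (hand
response time, touch time), plus an automated per-trial quality gate that
replaces manual blind rating with explicit rules: blink overlap of critical
windows, long uninterpolatable gaps, excessive missingness, off-screen gaze.

All detectors are first-crossing with strict (">") comparisons: a saccade
starts at the first post-onset sample whose angular gaze velocity exceeds
50 deg/s, the hand moves at the first sample whose finger speed exceeds
20 deg/s, and tracking counts the flight samples whose gaze-stimulus
distance is below 8 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SessionTraces
from .task_design import SAMPLE_INTERVAL_MS, TaskGeometry, TrialSpec, stimulus_position_clamped


@dataclass
class QcConfig:
    max_interp_ms: float = 200.0  # longest gap that is still interpolated
    max_missing_frac: float = 0.3
    max_offscreen_frac: float = 0.2
    critical_edge_ms: float = 100.0  # protected window at trial start / stimulus end
    critical_onset_halfwidth_ms: float = 50.0  # protected window around stimulus onset


@dataclass
class DetectorConfig:
    saccade_velocity_deg_s: float = 50.0
    tracking_radius_deg: float = 8.0
    hand_velocity_deg_s: float = 20.0
    window_ms: float = 100.0  # pupil window means
    min_window_samples: int = 10
    smooth_samples: int = 5
    saccade_offset_samples: int = 2  # consecutive sub-threshold samples ending a saccade
    min_reliable_trials: int = 10


@dataclass
class CleanSession:
    """Blink-interpolated samples with a per-trial validity table."""

    subject: str
    samples: pd.DataFrame
    validity: pd.DataFrame  # subject, block, trial, valid, reason
    events: pd.DataFrame
    specs: dict
    geometry: TaskGeometry


def _interp_nan(t, y, max_span_ms):
    """Linearly interpolate NaN runs no longer than ``max_span_ms``.
    Returns (interpolated series, True if a longer run remains)."""
    y = y.astype(float).copy()
    isnan = np.isnan(y)
    if not isnan.any():
        return y, False
    long_gap = False
    n = len(y)
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        span = (j - i) * SAMPLE_INTERVAL_MS
        if span > max_span_ms or i == 0 or j == n:
            long_gap = long_gap or span > max_span_ms
        i = j
    good = ~isnan
    if good.sum() >= 2:
        y[isnan] = np.interp(t[isnan], t[good], y[good])
    return y, long_gap


def clean_trace(
    traces: SessionTraces,
    qc: QcConfig | None = None,
) -> CleanSession:
    """Blink/gap interpolation and automated trial rejection.

    A trial is invalid with reason

    * ``"blink"``   — a missing-sample run overlaps a critical window (first
      100 ms of the trial, stimulus onset +/- 50 ms, last 100 ms of the
      stimulus presentation) or exceeds the maximum interpolation span,
    * ``"missing"`` — more than 30% of samples are missing,
    * ``"offscreen"`` — gaze is off the screen in more than 20% of samples.

    Raises ``ValueError`` on non-monotone timestamps.
    """
    qc = qc or QcConfig()
    geom = traces.geometry
    frames = []
    rows = []
    for (block, trial), g in traces.samples.groupby(["block", "trial"], sort=False):
        spec: TrialSpec = traces.specs[(block, trial)]
        t = g["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone timestamps in block {block} trial {trial}")
        gx = g["gaze_x_deg"].to_numpy(float)
        gy = g["gaze_y_deg"].to_numpy(float)
        pu = g["pupil_mm"].to_numpy(float)
        blink = g["blink"].to_numpy() > 0
        missing = blink | np.isnan(gx) | np.isnan(gy) | np.isnan(pu)

        reason = None
        onset = spec.stimulus_onset_ms
        stim_end = spec.stimulus_end_ms
        windows = [
            (0.0, qc.critical_edge_ms),
            (onset - qc.critical_onset_halfwidth_ms, onset + qc.critical_onset_halfwidth_ms),
            (stim_end - qc.critical_edge_ms, stim_end),
        ]
        in_critical = np.zeros_like(missing)
        for lo, hi in windows:
            in_critical |= (t >= lo) & (t <= hi)
        if np.mean(missing) > qc.max_missing_frac:
            reason = "missing"
        elif np.any(missing & in_critical):
            reason = "blink"

        gx2 = np.where(missing, np.nan, gx)
        gy2 = np.where(missing, np.nan, gy)
        pu2 = np.where(missing, np.nan, pu)
        gx2, long1 = _interp_nan(t, gx2, qc.max_interp_ms)
        gy2, long2 = _interp_nan(t, gy2, qc.max_interp_ms)
        pu2, long3 = _interp_nan(t, pu2, qc.max_interp_ms)
        if reason is None and (long1 or long2 or long3):
            reason = "blink"

        if reason is None and geom is not None:
            off = (np.abs(gx2) > geom.screen_halfwidth_deg) | (
                np.abs(gy2) > geom.screen_halfheight_deg
            )
            if np.mean(off) > qc.max_offscreen_frac:
                reason = "offscreen"

        out = g.copy()
        out["gaze_x_deg"] = gx2
        out["gaze_y_deg"] = gy2
        out["pupil_mm"] = pu2
        frames.append(out)
        rows.append({
            "subject": traces.subject, "block": block, "trial": trial,
            "valid": reason is None, "reason": reason,
        })
    return CleanSession(
        subject=traces.subject,
        samples=pd.concat(frames, ignore_index=True),
        validity=pd.DataFrame(rows),
        events=traces.events,
        specs=traces.specs,
        geometry=geom,
    )


def angular_velocity(gaze_x, gaze_y, dt_ms: float = SAMPLE_INTERVAL_MS,
                     smooth_samples: int = 5) -> np.ndarray:
    """Angular gaze speed (deg/s): moving-average smoothing of position
    followed by a central-difference derivative.  Length-preserving."""
    x = np.asarray(gaze_x, float)
    y = np.asarray(gaze_y, float)
    if len(x) < 3:
        raise ValueError("angular_velocity needs at least 3 samples")
    if smooth_samples > 1:
        pad = smooth_samples // 2
        kernel = np.ones(smooth_samples) / smooth_samples
        x = np.convolve(np.pad(x, pad, mode="edge"), kernel, mode="valid")
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    vx = np.gradient(x, dt_ms / 1000.0)
    vy = np.gradient(y, dt_ms / 1000.0)
    return np.hypot(vx, vy)


def extract_eye_outcomes(
    t: np.ndarray,
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
    spec: TrialSpec,
    geometry: TaskGeometry,
    config: DetectorConfig | None = None,
) -> dict:
    """Eye outcomes for one (cleaned) trial.

    Fields: ``fixation_error_deg`` (mean distance to the cross over the
    fixation period), ``eye_rt_ms`` (stimulus onset to first velocity
    crossing), ``saccade_amp_deg`` (displacement from saccade onset to
    offset), ``tracking_ms`` / ``tracking_pct`` (time with gaze within the
    tracking radius of the stimulus during flight), ``mean_gsd_deg`` (mean
    gaze-stimulus distance over tracking samples only).
    """
    cfg = config or DetectorConfig()
    onset = spec.stimulus_onset_ms
    flight = spec.effective_flight_ms
    stim_end = spec.stimulus_end_ms
    out: dict = {}

    fx, fy = geometry.fixation_pos
    fix_mask = t < onset
    out["fixation_error_deg"] = (
        float(np.nanmean(np.hypot(gaze_x[fix_mask] - fx, gaze_y[fix_mask] - fy)))
        if fix_mask.any() else np.nan
    )

    speed = angular_velocity(gaze_x, gaze_y, smooth_samples=cfg.smooth_samples)
    post = np.flatnonzero((t >= onset) & (speed > cfg.saccade_velocity_deg_s))
    if len(post) == 0:
        out["eye_rt_ms"] = np.nan
        out["saccade_amp_deg"] = np.nan
        out["eye_rt_reason"] = "no saccade"
    else:
        i_on = post[0]
        out["eye_rt_ms"] = float(t[i_on] - onset)
        out["eye_rt_reason"] = None
        below = speed <= cfg.saccade_velocity_deg_s
        i_off = None
        run = cfg.saccade_offset_samples
        for i in range(i_on + 1, len(t) - run + 1):
            if below[i:i + run].all():
                i_off = i
                break
        if i_off is None:
            i_off = len(t) - 1
        out["saccade_amp_deg"] = float(
            np.hypot(gaze_x[i_off] - gaze_x[i_on], gaze_y[i_off] - gaze_y[i_on])
        )

    flight_mask = (t >= onset) & (t < stim_end)
    stim = stimulus_position_clamped(spec, geometry, t[flight_mask] - onset)
    gsd = np.hypot(gaze_x[flight_mask] - stim[:, 0], gaze_y[flight_mask] - stim[:, 1])
    tracking = gsd < cfg.tracking_radius_deg
    out["tracking_ms"] = float(tracking.sum() * SAMPLE_INTERVAL_MS)
    out["tracking_pct"] = out["tracking_ms"] / flight * 100.0
    if tracking.any():
        out["mean_gsd_deg"] = float(np.mean(gsd[tracking]))
        out["tracking_reason"] = None
    else:
        out["mean_gsd_deg"] = np.nan
        out["tracking_reason"] = "no tracking"
    return out


def extract_hand_outcomes(
    t: np.ndarray,
    hand_speed: np.ndarray,
    event: dict,
    spec: TrialSpec,
    config: DetectorConfig | None = None,
) -> dict:
    """Hand response time (first post-onset speed crossing) and touch time
    (touch event minus stimulus onset); both absent on no-touch trials."""
    cfg = config or DetectorConfig()
    onset = spec.stimulus_onset_ms
    out: dict = {"hand_flag": None}
    if not bool(event.get("touched", False)):
        out["hand_rt_ms"] = np.nan
        out["touch_time_ms"] = np.nan
        out["hand_reason"] = "no touch"
        return out
    out["hand_reason"] = None
    out["touch_time_ms"] = float(event["touch_t_ms"] - onset)
    idx = np.flatnonzero((t >= onset) & (hand_speed > cfg.hand_velocity_deg_s))
    if len(idx) == 0:
        out["hand_rt_ms"] = np.nan
        out["hand_reason"] = "no movement"
    else:
        out["hand_rt_ms"] = float(t[idx[0]] - onset)
        if out["touch_time_ms"] < out["hand_rt_ms"]:
            out["hand_flag"] = "inconsistent kinematics"
    return out


def extract_outcomes(
    clean: CleanSession,
    config: DetectorConfig | None = None,
) -> pd.DataFrame:
    """Per-trial outcome table: eye + hand + pupil outcomes with validity
    flags and reason codes.  Invalid trials keep their condition columns but
    carry NaN outcomes."""
    from .pupillometry import extract_pupil_outcomes

    cfg = config or DetectorConfig()
    valid_map = {
        (r.block, r.trial): (r.valid, r.reason)
        for r in clean.validity.itertuples()
    }
    event_map = {
        (r["block"], r["trial"]): r for _, r in clean.events.iterrows()
    }
    rows = []
    for (block, trial), g in clean.samples.groupby(["block", "trial"], sort=False):
        spec: TrialSpec = clean.specs[(block, trial)]
        valid, reason = valid_map[(block, trial)]
        row = {
            "subject": clean.subject, "block": block, "trial": trial,
            "valid": valid, "qc_reason": reason,
            "is_go": spec.is_go, "is_probe": spec.is_probe,
            "flight_ms": spec.flight_duration_ms,
            "fixation_ms": spec.fixation_duration_ms,
            "location": spec.final_location_index,
        }
        event = event_map[(block, trial)]
        row["touched"] = bool(event["touched"])
        row["touch_t_abs_ms"] = event["touch_t_ms"]
        if valid:
            t = g["t_ms"].to_numpy()
            gx = g["gaze_x_deg"].to_numpy(float)
            gy = g["gaze_y_deg"].to_numpy(float)
            row.update(extract_eye_outcomes(t, gx, gy, spec, clean.geometry, cfg))
            row.update(extract_hand_outcomes(
                t, g["hand_speed_deg_s"].to_numpy(float), event, spec, cfg))
            row.update(extract_pupil_outcomes(
                t, g["pupil_mm"].to_numpy(float), spec, cfg))
        rows.append(row)
    return pd.DataFrame(rows)


#: outcome columns subject to the reliability rule
OUTCOME_PARAMETERS = (
    "tracking_ms", "tracking_pct", "mean_gsd_deg", "eye_rt_ms",
    "saccade_amp_deg", "fixation_error_deg", "hand_rt_ms", "touch_time_ms",
    "baseline_mm", "end_fixation_mm", "end_stimulus_mm", "slope_overall_mm_s",
    "slope_fixation_mm_s", "slope_flight_mm_s", "peak_size_change_mm",
    "latency_to_peak_ms",
)


def reliability_gate(
    outcomes: pd.DataFrame,
    parameters=OUTCOME_PARAMETERS,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Inclusion table: a parameter enters the subject-level analysis only
    when at least ``min_trials`` reliable (valid, non-missing) trials
    contribute."""
    rows = []
    for subject, g in outcomes.groupby("subject"):
        for param in parameters:
            n = int(g.loc[g["valid"], param].notna().sum()) if param in g else 0
            rows.append({
                "subject": subject, "parameter": param,
                "n_reliable": n, "included": n >= min_trials,
            })
    return pd.DataFrame(rows)
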