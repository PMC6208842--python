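"""Task-evoked pupillary response outcomes.

Eight per-trial measures of the pupil diameter trace: window means at
baseline (first 100 ms of the trial), end of fixation and end of stimulus
presentation (last 100 ms of each period); ordinary-least-squares slopes of
diameter against time over the whole trial, the fixation period and the
flight; and the amplitude/timing of the response peak (maximum diameter
minus baseline, and the time of that maximum).

"Whole trial" runs from fixation onset through the end of the stimulus
presentation: feedback is excluded, and latency-to-peak is reported from
trial (fixation) onset, with an auxiliary stimulus-onset-referenced column
so either convention can be analyzed downstream.
"""

from __future__ import annotations

import numpy as np

from .task_design import TrialSpec
from .trace_processing import DetectorConfig


def segment_slope(t_ms, pupil_mm, t0: float, t1: float) -> float:
    """OLS slope (mm/s) of diameter vs time over ``[t0, t1)``.

    Returns NaN when fewer than 2 finite samples fall in the window.
    Invariant to adding a constant to all diameters; antisymmetric under
    time reversal within the window.
    """
    t = np.asarray(t_ms, float)
    y = np.asarray(pupil_mm, float)
    mask = (t >= t0) & (t < t1) & np.isfinite(y)
    if mask.sum() < 2:
        return float("nan")
    return float(np.polyfit(t[mask] / 1000.0, y[mask], 1)[0])


def _window_mean(t, y, t0, t1, min_samples):
    mask = (t >= t0) & (t < t1) & np.isfinite(y)
    if mask.sum() < min_samples:
        return float("nan")
    return float(np.mean(y[mask]))


def extract_pupil_outcomes(
    t: np.ndarray,
    pupil: np.ndarray,
    spec: TrialSpec,
    config: DetectorConfig | None = None,
) -> dict:
    """The eight pupillary outcomes for one (cleaned) trial.

    Window means require at least ``config.min_window_samples`` finite
    samples, otherwise the field is NaN.  Ties at the maximum resolve to the
    earliest time.
    """
    cfg = config or DetectorConfig()
    t = np.asarray(t, float)
    pupil = np.asarray(pupil, float)
    onset = spec.stimulus_onset_ms
    stim_end = spec.stimulus_end_ms
    w = cfg.window_ms
    out: dict = {}

    if not np.isfinite(pupil).any():
        for key in ("baseline_mm", "end_fixation_mm", "end_stimulus_mm",
                    "slope_overall_mm_s", "slope_fixation_mm_s", "slope_flight_mm_s",
                    "peak_size_change_mm", "latency_to_peak_ms",
                    "latency_to_peak_from_onset_ms"):
            out[key] = np.nan
        out["pupil_reason"] = "no pupil"
        return out
    out["pupil_reason"] = None

    out["baseline_mm"] = _window_mean(t, pupil, 0.0, w, cfg.min_window_samples)
    out["end_fixation_mm"] = _window_mean(t, pupil, onset - w, onset, cfg.min_window_samples)
    out["end_stimulus_mm"] = _window_mean(
        t, pupil, stim_end - w, stim_end, cfg.min_window_samples)

    out["slope_overall_mm_s"] = segment_slope(t, pupil, 0.0, stim_end)
    out["slope_fixation_mm_s"] = segment_slope(t, pupil, 0.0, onset)
    out["slope_flight_mm_s"] = segment_slope(t, pupil, onset, stim_end)

    trial_mask = (t >= 0) & (t <= stim_end) & np.isfinite(pupil)
    if trial_mask.any():
        tt = t[trial_mask]
        yy = pupil[trial_mask]
        i = int(np.argmax(yy))  # argmax returns the first maximum: earliest tie wins
        out["latency_to_peak_ms"] = float(tt[i])
        out["latency_to_peak_from_onset_ms"] = float(tt[i] - onset)
        base = out["baseline_mm"]
        out["peak_size_change_mm"] = float(yy[i] - base) if np.isfinite(base) else np.nan
    else:
        out["latency_to_peak_ms"] = np.nan
        out["latency_to_peak_from_onset_ms"] = np.nan
        out["peak_size_change_mm"] = np.nan
    return out
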