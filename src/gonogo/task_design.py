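"""Task geometry and counterbalanced schedule generation.

The trajectory-prediction task (TPT): a fixation cross at 20 deg above screen
center is replaced by a dot that flies in a straight line to one of eight
final locations arranged on a 4x2 grid around a 10x10 deg target square.
Four locations fall inside the square (go trials), four outside it, two on
each lateral side (no-go trials).  Flight durations are 385/485/585 ms
(plus a rare 985 ms probe), fixation durations 390/890/1900 ms (probes use
1000 ms); all stimulus durations jitter by +/-5 ms because the 60 Hz screen
is not locked to the 200 Hz recording clock.

A simple reaction-time task (RTT) precedes the TPT: 50 trials, 500 ms
stimulus, intertrial intervals uniform in [1.5, 4] s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

FIXATION_DURATIONS_MS: tuple[float, ...] = (390.0, 890.0, 1900.0)
FLIGHT_DURATIONS_MS: tuple[float, ...] = (385.0, 485.0, 585.0)
PROBE_FLIGHT_MS: float = 985.0
PROBE_FIXATION_MS: float = 1000.0
FEEDBACK_MS: float = 500.0
JITTER_CHOICES_MS: tuple[float, ...] = (-5.0, 0.0, 5.0)
SAMPLE_INTERVAL_MS: float = 5.0  # 200 Hz acquisition clock


@dataclass(frozen=True)
class TaskGeometry:
    """Screen and stimulus geometry in degrees of visual angle.

    Origin is the screen center, y points up.  ``final_locations`` holds the
    eight grid points (index 0..7); ``go_labels[i]`` is True when location i
    lies inside the target square.
    """

    screen_halfwidth_deg: float = 37.5
    screen_halfheight_deg: float = 23.0
    fixation_pos: tuple[float, float] = (0.0, 20.0)
    target_center: tuple[float, float] = (0.0, -15.0)
    target_side_deg: float = 10.0
    viewing_distance_mm: float = 460.0
    final_locations: tuple[tuple[float, float], ...] = ()
    go_labels: tuple[bool, ...] = ()

    @property
    def n_locations(self) -> int:
        return len(self.final_locations)


def _grid_locations(center: tuple[float, float], side: float):
    """4 columns x 2 rows; columns at +/- side/4 (inside) and +/- 3*side/4
    (outside, two per lateral side); rows split the target's vertical span
    symmetrically.  Neighboring points are equidistant (side/2) both ways."""
    cx, cy = center
    xs = [cx - 0.75 * side, cx - 0.25 * side, cx + 0.25 * side, cx + 0.75 * side]
    ys = [cy + 0.25 * side, cy - 0.25 * side]
    return tuple((x, y) for y in ys for x in xs)


def build_geometry(
    screen_halfwidth_deg: float = 37.5,
    screen_halfheight_deg: float = 23.0,
    fixation_pos: tuple[float, float] = (0.0, 20.0),
    target_center: tuple[float, float] = (0.0, -15.0),
    target_side_deg: float = 10.0,
    viewing_distance_mm: float = 460.0,
) -> TaskGeometry:
    """Construct and validate the task geometry.

    Defaults give the 75 x 46 deg screen (at 460 mm), fixation cross at
    (0, +20) deg and a 10 x 10 deg target square near the bottom of the
    screen.

    Raises
    ------
    ValueError
        If the screen extent is non-positive, the target square does not fit,
        or the derived grid violates the go/no-go layout invariants.
    """
    if screen_halfwidth_deg <= 0 or screen_halfheight_deg <= 0:
        raise ValueError("screen extent must be positive")
    if target_side_deg <= 0:
        raise ValueError("target side must be positive")
    if target_side_deg > 2 * screen_halfheight_deg:
        raise ValueError("target side exceeds screen height")

    locations = _grid_locations(target_center, target_side_deg)
    half = target_side_deg / 2.0
    cx, cy = target_center

    def inside(p):
        return abs(p[0] - cx) < half and abs(p[1] - cy) < half

    labels = tuple(inside(p) for p in locations)
    geom = TaskGeometry(
        screen_halfwidth_deg=screen_halfwidth_deg,
        screen_halfheight_deg=screen_halfheight_deg,
        fixation_pos=tuple(fixation_pos),
        target_center=tuple(target_center),
        target_side_deg=target_side_deg,
        viewing_distance_mm=viewing_distance_mm,
        final_locations=locations,
        go_labels=labels,
    )
    _validate_geometry(geom)
    return geom


def _validate_geometry(geom: TaskGeometry) -> None:
    if sum(geom.go_labels) != 4:
        raise ValueError("expected exactly 4 go locations inside the target square")
    cx, _ = geom.target_center
    half = geom.target_side_deg / 2.0
    left = sum(
        1 for p, go in zip(geom.final_locations, geom.go_labels)
        if not go and p[0] < cx - half
    )
    right = sum(
        1 for p, go in zip(geom.final_locations, geom.go_labels)
        if not go and p[0] > cx + half
    )
    if left != 2 or right != 2:
        raise ValueError("no-go locations must lie outside the target, two per side")
    if geom.fixation_pos[1] <= geom.target_center[1]:
        raise ValueError("fixation cross must sit above the target center")
    for x, y in geom.final_locations:
        if abs(x) > geom.screen_halfwidth_deg or abs(y) > geom.screen_halfheight_deg:
            raise ValueError("final location falls off the screen")


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the trajectory-prediction task."""

    trial_id: int
    fixation_duration_ms: float
    flight_duration_ms: float
    jitter_ms: float
    final_location_index: int  # 1-based, 1..8
    is_go: bool
    is_probe: bool
    feedback_duration_ms: float = FEEDBACK_MS

    @property
    def effective_flight_ms(self) -> float:
        return self.flight_duration_ms + self.jitter_ms

    @property
    def stimulus_onset_ms(self) -> float:
        """Time of stimulus onset relative to trial (fixation) onset."""
        return self.fixation_duration_ms

    @property
    def stimulus_end_ms(self) -> float:
        return self.fixation_duration_ms + self.effective_flight_ms

    @property
    def trial_end_ms(self) -> float:
        return self.stimulus_end_ms + self.feedback_duration_ms


@dataclass
class TptDesign:
    """Counts and levels for one TPT block; defaults are the standard design
    (3 speeds x 8 locations x 3 reps + 8 probes = 80 trials)."""

    flight_durations_ms: tuple[float, ...] = FLIGHT_DURATIONS_MS
    fixation_durations_ms: tuple[float, ...] = FIXATION_DURATIONS_MS
    reps_per_speed_location: int = 3
    probes_per_location: int = 1
    probe_flight_ms: float = PROBE_FLIGHT_MS
    probe_fixation_ms: float = PROBE_FIXATION_MS
    jitter_choices_ms: tuple[float, ...] = JITTER_CHOICES_MS

    @property
    def n_trials(self) -> int:
        n_loc = 8
        return (
            len(self.flight_durations_ms) * n_loc * self.reps_per_speed_location
            + n_loc * self.probes_per_location
        )


# fMRI variant of the task: two speeds, 96 trials/block.  Exposed as a config
# preset only; untested against imaging data.
FMRI_DESIGN = TptDesign(
    flight_durations_ms=(370.0, 500.0),
    reps_per_speed_location=6,
    probes_per_location=0,
)


@dataclass
class BlockSchedule:
    trials: list[TrialSpec]
    block_index: int
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


def generate_tpt_block(
    geometry: TaskGeometry,
    design: TptDesign | None = None,
    seed: int = 0,
    block_index: int = 0,
) -> BlockSchedule:
    """Generate one counterbalanced, pseudo-randomized TPT block.

    Counterbalancing is exact, not sampled: fixation durations are assigned
    to the (location, speed, rep) cells by a cyclic (Latin-square-style)
    rule whose labels and phase are seeded, which guarantees
    * each speed appears ``reps`` times per final location,
    * each fixation duration appears equally often per location, and
    * every (speed, fixation) cell receives the same trial count,
    after which the trial order is a seeded permutation.  Identical
    (design, seed, block_index) always yield the identical schedule.

    Raises
    ------
    ValueError
        If the requested counts admit no exact counterbalancing.
    """
    design = design or TptDesign()
    n_loc = geometry.n_locations
    if n_loc == 0:
        raise ValueError("geometry defines no final locations")
    ns = len(design.flight_durations_ms)
    nf = len(design.fixation_durations_ms)
    reps = design.reps_per_speed_location

    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []

    if reps > 0:
        if nf == 0 or (ns * reps) % nf != 0:
            raise ValueError(
                "infeasible design: speeds x reps per location "
                f"({ns} x {reps}) not divisible by {nf} fixation durations"
            )
        speeds = rng.permutation(np.asarray(design.flight_durations_ms))
        fixations = rng.permutation(np.asarray(design.fixation_durations_ms))
        phase = int(rng.integers(nf))
        for loc in range(n_loc):
            for si, speed in enumerate(speeds):
                for r in range(reps):
                    k = si * reps + r
                    fix = fixations[(k + loc + phase) % nf]
                    trials.append(
                        TrialSpec(
                            trial_id=-1,
                            fixation_duration_ms=float(fix),
                            flight_duration_ms=float(speed),
                            jitter_ms=float(rng.choice(design.jitter_choices_ms)),
                            final_location_index=loc + 1,
                            is_go=geometry.go_labels[loc],
                            is_probe=False,
                        )
                    )
    for loc in range(n_loc):
        for _ in range(design.probes_per_location):
            trials.append(
                TrialSpec(
                    trial_id=-1,
                    fixation_duration_ms=design.probe_fixation_ms,
                    flight_duration_ms=design.probe_flight_ms,
                    jitter_ms=float(rng.choice(design.jitter_choices_ms)),
                    final_location_index=loc + 1,
                    is_go=geometry.go_labels[loc],
                    is_probe=True,
                )
            )

    order = rng.permutation(len(trials))
    shuffled = [
        TrialSpec(
            trial_id=block_index * 1000 + i,
            fixation_duration_ms=trials[j].fixation_duration_ms,
            flight_duration_ms=trials[j].flight_duration_ms,
            jitter_ms=trials[j].jitter_ms,
            final_location_index=trials[j].final_location_index,
            is_go=trials[j].is_go,
            is_probe=trials[j].is_probe,
        )
        for i, j in enumerate(order)
    ]
    return BlockSchedule(trials=shuffled, block_index=block_index, seed=seed)


def generate_session_schedules(
    geometry: TaskGeometry,
    n_blocks: int = 3,
    design: TptDesign | None = None,
    seed: int = 0,
) -> list[BlockSchedule]:
    """Standard session: ``n_blocks`` blocks (default 3 x 80 trials)."""
    return [
        generate_tpt_block(geometry, design=design, seed=seed + 7919 * b, block_index=b)
        for b in range(n_blocks)
    ]


@dataclass
class RttSchedule:
    """Simple reaction-time task: 50 trials with a break after 25."""

    itis_ms: np.ndarray
    stimulus_duration_ms: float = 500.0
    break_after: int = 25
    catch_threshold_ms: float = 125.0
    max_rt_ms: float = 750.0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.itis_ms)


def generate_rtt_schedule(seed: int = 0, n_trials: int = 50) -> RttSchedule:
    """50 trials; intertrial intervals drawn uniformly in [1500, 4000] ms."""
    rng = np.random.default_rng(seed)
    itis = rng.uniform(1500.0, 4000.0, size=n_trials)
    return RttSchedule(itis_ms=itis, seed=seed)


def stimulus_position(spec: TrialSpec, geometry: TaskGeometry, t_ms):
    """Stimulus position ``t_ms`` after stimulus onset.

    The dot travels at constant speed in a straight line from the fixation
    cross to the trial's final location over the effective (jittered) flight
    duration.  ``t_ms`` may be a scalar or array; values outside
    [0, effective flight] raise.
    """
    t = np.asarray(t_ms, dtype=float)
    dur = spec.effective_flight_ms
    if np.any(t < 0) or np.any(t > dur):
        raise ValueError(f"t outside flight window [0, {dur}] ms")
    fx, fy = geometry.fixation_pos
    tx, ty = geometry.final_locations[spec.final_location_index - 1]
    frac = t / dur
    return np.stack([fx + (tx - fx) * frac, fy + (ty - fy) * frac], axis=-1)


def stimulus_position_clamped(spec: TrialSpec, geometry: TaskGeometry, t_ms):
    """As :func:`stimulus_position` but clamping t into the flight window
    (pre-onset times map to the start, post-flight to the final location)."""
    t = np.clip(np.asarray(t_ms, dtype=float), 0.0, spec.effective_flight_ms)
    return stimulus_position(spec, geometry, t)


# ---------------------------------------------------------------------------
# schedule file I/O (JSON)

def schedules_to_json(geometry: TaskGeometry, blocks: list[BlockSchedule]) -> dict:
    return {
        "schema_version": 1,
        "geometry": asdict(geometry),
        "blocks": [
            {
                "block_index": b.block_index,
                "seed": b.seed,
                "trials": [asdict(t) for t in b.trials],
            }
            for b in blocks
        ],
    }


def write_schedules(path, geometry: TaskGeometry, blocks: list[BlockSchedule]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schedules_to_json(geometry, blocks), fh, indent=1)


def read_schedules(path) -> tuple[TaskGeometry, list[BlockSchedule]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    g = payload["geometry"]
    geometry = TaskGeometry(
        screen_halfwidth_deg=g["screen_halfwidth_deg"],
        screen_halfheight_deg=g["screen_halfheight_deg"],
        fixation_pos=tuple(g["fixation_pos"]),
        target_center=tuple(g["target_center"]),
        target_side_deg=g["target_side_deg"],
        viewing_distance_mm=g["viewing_distance_mm"],
        final_locations=tuple(tuple(p) for p in g["final_locations"]),
        go_labels=tuple(bool(x) for x in g["go_labels"]),
    )
    blocks = [
        BlockSchedule(
            trials=[TrialSpec(**t) for t in b["trials"]],
            block_index=b["block_index"],
            seed=b["seed"],
        )
        for b in payload["blocks"]
    ]
    return geometry, blocks
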