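"""File formats and pipeline configuration.

Session traces travel as a long-format CSV (one row per 5 ms sample) with
touch events folded into dedicated columns on the touched sample's row;
generator ground truth is written as a sibling JSON.  Schedules are JSON
(see :mod:`gonogo.task_design`).  The pipeline configuration is a single
YAML/JSON document whose defaults are the task's printed constants; every
threshold is echoed into the output manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SessionTraces
from .task_design import SAMPLE_INTERVAL_MS, TaskGeometry, TptDesign, read_schedules
from .trace_processing import DetectorConfig, QcConfig

SCHEMA_VERSION = 1

SESSION_COLUMNS = [
    "subject", "block", "trial", "t_ms", "gaze_x_deg", "gaze_y_deg",
    "pupil_mm", "hand_speed_deg_s", "hand_x_deg", "hand_y_deg", "blink",
    "touch", "touch_t_ms", "touch_x_deg", "touch_y_deg",
]


class SchemaError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline; defaults are the task's
    printed constants."""

    seed: int = 0
    n_blocks: int = 3
    subjects_per_group: int = 2
    design: TptDesign = field(default_factory=TptDesign)
    qc: QcConfig = field(default_factory=QcConfig)
    detectors: DetectorConfig = field(default_factory=DetectorConfig)
    sdt_correction: str = "loglinear"
    rtt_catch_ms: float = 125.0
    rtt_max_rt_ms: float = 750.0
    include_probes: bool = False
    geometry_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "design" in d and isinstance(d["design"], dict):
            dd = dict(d["design"])
            for k in ("flight_durations_ms", "fixation_durations_ms", "jitter_choices_ms"):
                if k in dd:
                    dd[k] = tuple(dd[k])
            d["design"] = TptDesign(**dd)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcConfig(**d["qc"])
        if "detectors" in d and isinstance(d["detectors"], dict):
            d["detectors"] = DetectorConfig(**d["detectors"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix in (".yaml", ".yml"):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))


def write_session(path, traces: SessionTraces) -> None:
    """Write a session to the documented CSV dialect (UTF-8, header row).
    Each touch event is stored on the sample row nearest its time so the
    file round-trips exactly; ground truth goes to ``<path>.truth.json``."""
    df = traces.samples.copy()
    df["touch"] = 0
    df["touch_t_ms"] = np.nan
    df["touch_x_deg"] = np.nan
    df["touch_y_deg"] = np.nan
    for r in traces.events.itertuples():
        if not r.touched:
            continue
        mask = (df["block"] == r.block) & (df["trial"] == r.trial)
        sub = df.loc[mask, "t_ms"]
        idx = (sub - r.touch_t_ms).abs().idxmin()
        df.loc[idx, ["touch", "touch_t_ms", "touch_x_deg", "touch_y_deg"]] = [
            1, r.touch_t_ms, r.touch_x_deg, r.touch_y_deg]
    df[SESSION_COLUMNS].to_csv(path, index=False)
    truth_path = Path(str(path) + ".truth.json")
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"schema_version": SCHEMA_VERSION,
             "subject": traces.subject,
             "truth": traces.truth.to_dict(orient="records")},
            fh, default=float)


def read_session(path, geometry: TaskGeometry, specs: dict,
                 spacing_tol_ms: float = 0.1) -> SessionTraces:
    """Read a session CSV, checking the schema and the 200 Hz spacing.

    Raises :class:`SchemaError` naming any missing column or reporting
    sample spacing that deviates from 5 ms beyond ``spacing_tol_ms``.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"session file missing columns: {', '.join(missing)}")
    for (_, _), g in df.groupby(["block", "trial"], sort=False):
        dt = np.diff(g["t_ms"].to_numpy())
        if len(dt) and np.any(np.abs(dt - SAMPLE_INTERVAL_MS) > spacing_tol_ms):
            bad = float(dt[np.argmax(np.abs(dt - SAMPLE_INTERVAL_MS))])
            raise SchemaError(
                f"sample spacing {bad:g} ms deviates from "
                f"{SAMPLE_INTERVAL_MS:g} ms (200 Hz) beyond tolerance")
    ev_rows = []
    for (block, trial), g in df.groupby(["block", "trial"], sort=False):
        touched = g["touch"].to_numpy() > 0
        if touched.any():
            r = g[touched].iloc[0]
            ev_rows.append({"subject": r["subject"], "block": block, "trial": trial,
                            "touched": True, "touch_t_ms": float(r["touch_t_ms"]),
                            "touch_x_deg": float(r["touch_x_deg"]),
                            "touch_y_deg": float(r["touch_y_deg"])})
        else:
            ev_rows.append({"subject": g["subject"].iloc[0], "block": block,
                            "trial": trial, "touched": False, "touch_t_ms": np.nan,
                            "touch_x_deg": np.nan, "touch_y_deg": np.nan})
    truth_path = Path(str(path) + ".truth.json")
    truth = pd.DataFrame()
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            truth = pd.DataFrame(json.load(fh)["truth"])
    subject = str(df["subject"].iloc[0])
    samples = df.drop(columns=["touch", "touch_t_ms", "touch_x_deg", "touch_y_deg"])
    return SessionTraces(subject=subject, samples=samples,
                         events=pd.DataFrame(ev_rows), truth=truth,
                         specs=specs, geometry=geometry)
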