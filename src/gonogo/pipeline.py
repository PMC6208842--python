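"""End-to-end pipeline: design -> simulate -> extract -> summarize -> compare.

Every stage is seeded from the single config seed, logged, and its outputs
written into the artifact directory together with a manifest recording the
package version, seeds, config hash and QC rejection counts.  Any stage
failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, write_session
from .performance_stats import (
    build_response_records,
    group_compare,
    rtt_reaction_times,
    summarize_performance,
)
from .profiles import control_profile, expert_profile
from .simulate import simulate_rtt_presses, simulate_session
from .task_design import (
    build_geometry,
    generate_rtt_schedule,
    generate_session_schedules,
    write_schedules,
)
from .trace_processing import clean_trace, extract_outcomes, reliability_gate

log = logging.getLogger("gonogo.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline and return the manifest.

    Simulates ``subjects_per_group`` experts and controls over ``n_blocks``
    TPT blocks plus one RTT session each, extracts all outcome parameters,
    summarizes performance and d' per condition, and compares the groups on
    a default set of outcomes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # ---- design -----------------------------------------------------------
    stage = "design"
    try:
        geometry = build_geometry(**config.geometry_overrides)
        schedules = generate_session_schedules(
            geometry, n_blocks=config.n_blocks, design=config.design,
            seed=config.seed)
        rtt = generate_rtt_schedule(seed=config.seed)
        write_schedules(outdir / "schedules.json", geometry, schedules)
        manifest["stages"][stage] = {
            "n_blocks": len(schedules),
            "trials_per_block": len(schedules[0]) if schedules else 0,
            "rtt_trials": rtt.n_trials,
        }
        log.info("design: %d blocks x %d trials", len(schedules),
                 len(schedules[0]) if schedules else 0)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        subjects = []
        for i in range(config.subjects_per_group):
            subjects.append((f"expert_{i:02d}", expert_profile()))
            subjects.append((f"control_{i:02d}", control_profile()))
        sessions = {}
        rtt_tables = []
        master = np.random.default_rng(config.seed)
        for sid, profile in subjects:
            seed_i = int(master.integers(2**31 - 1))
            traces = simulate_session(profile, schedules, geometry,
                                      seed=seed_i, subject=sid)
            sessions[sid] = (profile, traces)
            write_session(outdir / f"session_{sid}.csv", traces)
            presses = simulate_rtt_presses(profile, rtt, np.random.default_rng(seed_i + 1))
            _, rtt_summary = rtt_reaction_times(presses, rtt)
            rtt_tables.append({"subject": sid, "group": profile.group, **rtt_summary})
        manifest["stages"][stage] = {"n_subjects": len(subjects)}
        log.info("simulate: %d subjects", len(subjects))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- extract ----------------------------------------------------------
    stage = "extract"
    try:
        all_outcomes = []
        qc_counts = {}
        for sid, (profile, traces) in sessions.items():
            clean = clean_trace(traces, config.qc)
            outcomes = extract_outcomes(clean, config.detectors)
            outcomes["group"] = profile.group
            records = build_response_records(outcomes, traces.specs)
            all_outcomes.append(records)
            qc_counts[sid] = int((~clean.validity["valid"]).sum())
        outcome_table = pd.concat(all_outcomes, ignore_index=True)
        outcome_table.to_csv(outdir / "outcomes.csv", index=False)
        gate = reliability_gate(outcome_table,
                                min_trials=config.detectors.min_reliable_trials)
        gate.to_csv(outdir / "reliability.csv", index=False)
        manifest["stages"][stage] = {
            "n_trials": int(len(outcome_table)),
            "qc_rejected": qc_counts,
        }
        log.info("extract: %d trials, QC rejected %s", len(outcome_table), qc_counts)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- summarize --------------------------------------------------------
    stage = "summarize"
    try:
        summary = summarize_performance(outcome_table,
                                        include_probes=config.include_probes,
                                        correction=config.sdt_correction)
        groups = outcome_table[["subject", "group"]].drop_duplicates()
        for name in ("percent_by_block", "percent_by_speed", "percent_by_fixation",
                     "percent_by_cell", "rates_by_speed"):
            tbl = getattr(summary, name).merge(groups, on="subject", how="left")
            tbl.to_csv(outdir / f"summary_{name}.csv", index=False)
        pd.DataFrame(rtt_tables).to_csv(outdir / "summary_rtt.csv", index=False)
        manifest["stages"][stage] = {"tables": 6}
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- compare ----------------------------------------------------------
    stage = "compare"
    try:
        per_subject = (
            outcome_table[outcome_table["valid"]]
            .groupby(["subject", "group"])
            .agg(percent_correct=("correct", lambda c: 100.0 * c.mean()),
                 mean_gsd_deg=("mean_gsd_deg", "mean"),
                 latency_to_peak_ms=("latency_to_peak_ms", "mean"))
            .reset_index()
        )
        reports = {}
        for dv in ("percent_correct", "mean_gsd_deg", "latency_to_peak_ms"):
            try:
                reports[dv] = group_compare(per_subject, dv=dv, between="group")
            except ValueError as err:
                reports[dv] = {"dv": dv, "error": str(err)}
        with open(outdir / "statistics.json", "w", encoding="utf-8") as fh:
            json.dump(reports, fh, indent=1, default=float)
        manifest["stages"][stage] = {"outcomes_compared": list(reports)}
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
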