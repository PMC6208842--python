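"""Trial classification, performance summaries, signal detection, and the
group-comparison statistics.

Response types follow the go/no-go contingency table: touch before flight
end on a go trial is a hit, no touch (or a late touch) on a go trial a miss,
no touch on a no-go trial a correct rejection, any touch on a no-go trial a
false alarm.  Sensitivity is the classic equal-variance d' = z(H) - z(F)
with a configurable extreme-rate correction, and the response bias is
c = -(z(H) + z(F)) / 2.

Group comparisons follow a normality-gated scheme: Shapiro-Wilk at
alpha = .05 decides between parametric tests (ANOVA / repeated-measures
ANOVA with Bonferroni-corrected post-hocs, independent-sample t tests) and
the Mann-Whitney U fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task_design import RttSchedule, TrialSpec

RESPONSE_TYPES = ("hit", "miss", "correct_rejection", "false_alarm")


def classify_response(spec: TrialSpec, touched: bool, touch_time_ms=None) -> str:
    """Classify one trial.  ``touch_time_ms`` is relative to stimulus onset;
    a go-trial touch that lands after the stimulus reached its final
    position counts as a miss."""
    if touch_time_ms is not None and not np.isnan(touch_time_ms) and not touched:
        raise ValueError("touch_time given but touched is False")
    if spec.is_go:
        if not touched:
            return "miss"
        if touch_time_ms is not None and not np.isnan(touch_time_ms) \
                and touch_time_ms > spec.effective_flight_ms:
            return "miss"
        return "hit"
    return "false_alarm" if touched else "correct_rejection"


def build_response_records(outcomes: pd.DataFrame, specs: dict) -> pd.DataFrame:
    """Attach a ``response_type`` column to a per-trial outcome table."""
    types = []
    for r in outcomes.itertuples():
        spec = specs[(r.block, r.trial)]
        touch_time = getattr(r, "touch_time_ms", np.nan)
        types.append(classify_response(spec, bool(r.touched), touch_time))
    out = outcomes.copy()
    out["response_type"] = types
    out["correct"] = out["response_type"].isin(["hit", "correct_rejection"])
    return out


@dataclass
class SDTResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_go: int
    n_nogo: int
    correction_applied: bool
    correction: str


def dprime(hits: int, n_go: int, fas: int, n_nogo: int,
           correction: str = "loglinear") -> SDTResult:
    """Sensitivity and bias from response counts.

    ``correction`` handles extreme rates before the z-transform:

    * ``"loglinear"`` — add 0.5 to every cell (applied always),
    * ``"clamp"``     — replace 0 with 1/(2N) and 1 with 1 - 1/(2N),
    * ``"none"``      — no adjustment (infinite d' at extreme rates).
    """
    if n_go == 0 or n_nogo == 0:
        raise ValueError("need at least one go and one no-go trial")
    raw_h = hits / n_go
    raw_f = fas / n_nogo
    if correction == "loglinear":
        h = (hits + 0.5) / (n_go + 1)
        f = (fas + 0.5) / (n_nogo + 1)
        applied = True
    elif correction == "clamp":
        h, f, applied = raw_h, raw_f, False
        if h == 0.0:
            h, applied = 1 / (2 * n_go), True
        elif h == 1.0:
            h, applied = 1 - 1 / (2 * n_go), True
        if f == 0.0:
            f, applied = 1 / (2 * n_nogo), applied or True
        elif f == 1.0:
            f, applied = 1 - 1 / (2 * n_nogo), True
    elif correction == "none":
        h, f, applied = raw_h, raw_f, False
    else:
        raise ValueError(f"unknown correction {correction!r}")
    zh = sps.norm.ppf(h)
    zf = sps.norm.ppf(f)
    return SDTResult(
        hit_rate=raw_h, fa_rate=raw_f,
        dprime=float(zh - zf), criterion=float(-(zh + zf) / 2),
        n_go=n_go, n_nogo=n_nogo,
        correction_applied=applied, correction=correction,
    )


def dprime_from_rates(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int,
                      correction: str = "loglinear") -> SDTResult:
    """Convenience wrapper taking proportions rather than counts."""
    return dprime(int(round(hit_rate * n_go)), n_go,
                  int(round(fa_rate * n_nogo)), n_nogo, correction)


@dataclass
class ConditionSummary:
    percent_by_block: pd.DataFrame
    percent_by_speed: pd.DataFrame
    percent_by_fixation: pd.DataFrame
    percent_by_cell: pd.DataFrame  # speed x fixation
    rates_by_speed: pd.DataFrame  # hit/miss/CR/FA rates + d' per speed
    include_probes: bool


def _percent_correct(g: pd.DataFrame) -> float:
    return float(g["correct"].mean() * 100.0)


def summarize_performance(
    records: pd.DataFrame,
    include_probes: bool = False,
    correction: str = "loglinear",
) -> ConditionSummary:
    """Percent correct per block / speed / fixation / speed-x-fixation cell
    and the signal-detection breakdown per speed.

    Hit rate = correct go trials / all go trials, false-alarm rate =
    incorrect no-go trials / all no-go trials.  Probe (985 ms) trials are
    excluded from the condition tables by default.  Empty cells are omitted.
    """
    recs = records[records["valid"]] if "valid" in records else records
    if not include_probes and "is_probe" in recs:
        recs = recs[~recs["is_probe"]]
    if len(recs) == 0:
        raise ValueError("no records to summarize")

    group_cols = ["subject"] if "subject" in recs else []

    def table(by):
        return (
            recs.groupby(group_cols + by)
            .apply(_percent_correct, include_groups=False)
            .rename("percent_correct")
            .reset_index()
        )

    rates = []
    for keys, g in recs.groupby(group_cols + ["flight_ms"]):
        keys = keys if isinstance(keys, tuple) else (keys,)
        go = g[g["is_go"]]
        nogo = g[~g["is_go"]]
        if len(go) == 0 or len(nogo) == 0:
            continue
        hits = int((go["response_type"] == "hit").sum())
        fas = int((nogo["response_type"] == "false_alarm").sum())
        res = dprime(hits, len(go), fas, len(nogo), correction)
        rates.append({
            **dict(zip(group_cols + ["flight_ms"], keys)),
            "hit_rate": res.hit_rate,
            "miss_rate": 1.0 - res.hit_rate,
            "fa_rate": res.fa_rate,
            "cr_rate": 1.0 - res.fa_rate,
            "dprime": res.dprime,
            "criterion": res.criterion,
            "n_go": res.n_go,
            "n_nogo": res.n_nogo,
        })

    return ConditionSummary(
        percent_by_block=table(["block"]),
        percent_by_speed=table(["flight_ms"]),
        percent_by_fixation=table(["fixation_ms"]),
        percent_by_cell=table(["flight_ms", "fixation_ms"]),
        rates_by_speed=pd.DataFrame(rates),
        include_probes=include_probes,
    )


def rtt_reaction_times(press_times_ms, schedule: RttSchedule):
    """Filter reaction-time-task presses and summarize.

    Presses inside the catch window (< 125 ms) are catch trials; presses
    slower than the 750 ms limit, missing presses, and presses before
    stimulus onset are invalid.  Returns ``(per-trial table, summary)`` with
    the summary mean/SD over the included trials.
    """
    presses = np.asarray(press_times_ms, float)
    rows = []
    for i, p in enumerate(presses):
        if np.isnan(p):
            status = "no_press"
        elif p < 0:
            status = "premature"
        elif p < schedule.catch_threshold_ms:
            status = "catch"
        elif p > schedule.max_rt_ms:
            status = "too_slow"
        else:
            status = "ok"
        rows.append({"trial": i, "press_ms": p, "status": status,
                     "included": status == "ok"})
    table = pd.DataFrame(rows)
    ok = table.loc[table["included"], "press_ms"]
    summary = {
        "n_included": int(len(ok)),
        "n_excluded": int(len(table) - len(ok)),
        "mean_rt_ms": float(ok.mean()) if len(ok) else float("nan"),
        "sd_rt_ms": float(ok.std(ddof=1)) if len(ok) > 1 else float("nan"),
    }
    return table, summary


def group_compare(
    table: pd.DataFrame,
    dv: str,
    between: str = "group",
    within: str | None = None,
    subject: str = "subject",
    alpha: float = 0.05,
    one_tailed: bool = False,
) -> dict:
    """Compare an outcome between groups, normality-gated.

    ``table`` holds one row per subject (or per subject x within-level).
    The Shapiro-Wilk test (alpha = .05, per group) gates the route: when all
    groups look normal, a two-group design uses the independent-samples t
    test (or a mixed ANOVA when ``within`` is given, with
    Bonferroni-corrected post-hoc t tests); otherwise the Mann-Whitney U
    test.  Groups smaller than the Shapiro minimum (n = 3) route to the
    nonparametric branch.  Raises for fewer than 2 subjects in any group.
    """
    groups = table[between].unique()
    per_group = [table.loc[table[between] == g, dv].dropna().to_numpy() for g in groups]
    if any(len(v) < 2 for v in per_group) or len(groups) < 2:
        raise ValueError("need at least 2 subjects per group")

    normal = True
    gate = []
    for g, v in zip(groups, per_group):
        if len(v) < 3 or np.ptp(v) == 0:
            ok, p = False, float("nan")
        else:
            stat, p = sps.shapiro(v)
            ok = p > alpha
        gate.append({"group": str(g), "shapiro_p": float(p), "normal": bool(ok)})
        normal = normal and ok

    report: dict = {"dv": dv, "alpha": alpha, "normality": gate}
    alternative = "less" if one_tailed else "two-sided"

    if normal and within is not None:
        import pingouin as pg

        aov = pg.mixed_anova(data=table, dv=dv, within=within,
                             subject=subject, between=between)
        post = pg.pairwise_tests(data=table, dv=dv, within=within,
                                 subject=subject, between=between,
                                 padjust="bonf")
        report.update({
            "test": "mixed_anova",
            "anova": aov.to_dict(orient="records"),
            "posthoc": post.to_dict(orient="records"),
            "correction": "bonferroni",
        })
    elif normal:
        if len(groups) == 2:
            res = sps.ttest_ind(per_group[0], per_group[1], alternative=alternative)
            report.update({
                "test": "t_ind", "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "df": len(per_group[0]) + len(per_group[1]) - 2,
                "significant": bool(res.pvalue < alpha),
            })
        else:
            f, p = sps.f_oneway(*per_group)
            report.update({"test": "anova", "statistic": float(f), "p": float(p),
                           "significant": bool(p < alpha)})
    else:
        res = sps.mannwhitneyu(per_group[0], per_group[1], alternative=alternative)
        report.update({
            "test": "mannwhitneyu", "statistic": float(res.statistic),
            "p": float(res.pvalue), "significant": bool(res.pvalue < alpha),
        })
    return report
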