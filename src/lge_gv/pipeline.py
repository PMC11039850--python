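"""End-to-end orchestration: traces + food logs -> LGE, GV, associations.

Processing per participant-assessment:

1. plausibility screen on the raw trace (>95% of readings >= 70 mg/dL);
2. gap-aware 5-min interpolation for meal matching and windowing;
3. food-log consolidation (15-min chain merge, >=25 kcal) and +/-5-min
   preprandial matching;
4. valid-day flags (>=2 matched events on a plausible trace) and the
   3-valid-days-per-week inclusion rule;
5. LGE% against the fasting-derived threshold (carry-forward by default);
6. the GV metric battery at native cadence; glucotype fractions from a
   cohort-pooled spectral model.

Change scores and the correlation/weight-adjusted-regression analysis follow
for the included, paired participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import association as assoc
from .cgm_io import GlucoseTrace, assess_plausibility, resample_trace, traces_from_frame
from .errors import UndefinedResultError
from .glucotyping import classify_fractions, fit_glucotypes, window_trace
from .gv_metrics import GVProfile, gv_profile
from .lge import LgeResult, compute_lge, derive_threshold
from .meal_events import (consolidate_events, decide_inclusion, find_valid_days,
                          match_preprandial, records_from_frame)

logger = logging.getLogger(__name__)

#: GV measures entering the change-score association analysis.
GV_MEASURES = ["mean_mg_dl", "sd_mg_dl", "conga_mmol", "li_mmol2_per_h",
               "j_index", "hbgi", "lbgi", "adrr", "grade", "mage_mmol",
               "modd_mmol", "m_value", "frac_low", "frac_moderate", "frac_severe"]


@dataclass
class AssessmentResult:
    participant_id: str
    week: int
    plausible: bool
    n_valid_days: int
    lge: LgeResult | None
    profile: GVProfile | None
    windows: list = field(default_factory=list)
    error: str = ""


@dataclass
class PipelineResult:
    measures: pd.DataFrame       # one row per included participant-week
    inclusion: pd.DataFrame      # per-participant valid-day counts + decision
    changes: pd.DataFrame        # change scores for paired included participants
    associations: pd.DataFrame   # per-GV-measure correlation/regression results
    assessments: list[AssessmentResult] = field(default_factory=list)


def process_assessment(
    trace: GlucoseTrace,
    meal_frame: pd.DataFrame,
    threshold,
    compute_windows: bool = True,
) -> AssessmentResult:
    """Run steps 1-6 (minus glucotype model fitting) for one assessment."""
    plaus = assess_plausibility(trace)
    grid = resample_trace(trace)
    events = consolidate_events(records_from_frame(meal_frame))
    events = match_preprandial(events, grid)
    valid = find_valid_days(events, trace)
    n_valid = sum(valid.values())
    try:
        lge_result = compute_lge(events, threshold)
    except UndefinedResultError as exc:
        return AssessmentResult(trace.participant_id, trace.week, plaus.plausible,
                                n_valid, None, None, error=str(exc))
    profile = gv_profile(trace)
    windows = window_trace(grid) if compute_windows else []
    return AssessmentResult(trace.participant_id, trace.week, plaus.plausible,
                            n_valid, lge_result, profile, windows)


def run_cohort(
    cgm: pd.DataFrame,
    food_logs: pd.DataFrame,
    anthropometrics: pd.DataFrame,
    *,
    threshold_mode: str = "carry_forward",
    min_valid_days: int = 3,
    glucotype_seed: int = 0,
    weeks: tuple[int, int] = (0, 16),
) -> PipelineResult:
    """Full analysis on the three input tables.

    ``threshold_mode`` is ``"carry_forward"`` (week-0 threshold reused at
    week 16, the default) or ``"per_assessment"`` (each week's fasting draws
    when present).
    """
    traces = traces_from_frame(cgm).by_assessment()
    anthro = anthropometrics.copy()
    anthro["participant_id"] = anthro["participant_id"].astype(str)
    anthro = anthro.set_index(["participant_id", "week"]).sort_index()
    food_logs = food_logs.copy()
    food_logs["participant_id"] = food_logs["participant_id"].astype(str)
    food_logs["timestamp"] = pd.to_datetime(food_logs["timestamp"])

    assessments: list[AssessmentResult] = []
    for (pid, week), trace in sorted(traces.items()):
        thr_week = weeks[0] if (threshold_mode == "carry_forward") else week
        try:
            row = anthro.loc[(pid, thr_week)]
        except KeyError:
            if thr_week != week:
                row = anthro.loc[(pid, week)]
            else:
                raise
        threshold = derive_threshold(pid, week,
                                     (row["fasting1_mg_dl"], row["fasting2_mg_dl"]))
        meals = food_logs[(food_logs["participant_id"] == pid)
                          & (food_logs["week"] == week)]
        meals = meals.rename(columns={"energy_kcal": "kcal"})
        assessments.append(process_assessment(trace, meals, threshold))

    # inclusion per participant
    by_pid: dict[str, dict[int, int]] = {}
    for a in assessments:
        by_pid.setdefault(a.participant_id, {})[a.week] = a.n_valid_days
    decisions = [decide_inclusion(pid, counts, min_valid_days=min_valid_days,
                                  weeks=weeks)
                 for pid, counts in sorted(by_pid.items())]
    inclusion = pd.DataFrame([{
        "participant_id": d.participant_id,
        "valid_days_week0": d.valid_days_week0,
        "valid_days_week16": d.valid_days_week16,
        "included": d.included, "reason": d.reason,
    } for d in decisions])
    included_ids = {d.participant_id for d in decisions if d.included}

    usable = [a for a in assessments
              if a.participant_id in included_ids and a.lge is not None
              and a.profile is not None]

    # pooled, self-trained glucotype model
    pooled = [w for a in usable for w in a.windows]
    if pooled:
        model = fit_glucotypes(pooled, seed=glucotype_seed)
        for a in usable:
            if a.windows:
                a.profile.glucotype_fractions = classify_fractions(model, a.windows)

    rows = []
    for a in usable:
        rec = a.profile.as_dict()
        rec["lge_percent"] = a.lge.lge_percent
        rec["n_events_included"] = a.lge.n_events_included
        rec["n_events_lge"] = a.lge.n_events_lge
        w = anthro.loc[(a.participant_id, a.week)]
        rec["weight_kg"] = float(w["weight_kg"])
        rows.append(rec)
    measures = pd.DataFrame(rows)

    gv_cols = [c for c in GV_MEASURES if c in measures.columns]
    changes = assoc.compute_changes(measures, gv_columns=gv_cols, weeks=weeks)
    associations = _associate_safe(changes, gv_cols)
    return PipelineResult(measures=measures, inclusion=inclusion, changes=changes,
                          associations=associations, assessments=assessments)


def _associate_safe(changes: pd.DataFrame, gv_cols: list[str]) -> pd.DataFrame:
    ok = []
    for m in gv_cols:
        col = f"d{m}_pct"
        vals = changes[col]
        if vals.notna().sum() >= 4 and vals.std(skipna=True) > 0:
            ok.append(m)
        else:
            logger.warning("skipping association for %s (degenerate change scores)", m)
    if not ok:
        return pd.DataFrame()
    return assoc.associate_all(changes, ok)
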