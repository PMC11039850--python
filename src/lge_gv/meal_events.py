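"""Eating-event validation, consolidation and CGM timestamp matching.

Raw food-log records become discrete, valid eating events by (1) chain-merging
records reported less than 15 min apart — their energy and macros are summed
and the merged event takes the earliest timestamp — and (2) dropping merged
events below 25 kcal.  Each surviving event is then matched to a preprandial
glucose reading on a 5-min interpolated CGM grid within +/-5 min of the meal
timestamp; events without a reading in that window are excluded from the
low-glucose-eating denominator.

Participant inclusion follows the valid-day rule: a calendar day is valid when
it carries at least two matched eating events on a plausible trace, and a
participant is included when both assessments have at least three valid days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cgm_io import GlucoseTrace, assess_plausibility
from .errors import SchemaError

#: Records closer together than this are aggregated into one event.
MERGE_WINDOW_MINUTES = 15.0

#: Minimum energy for a merged event to count as a valid eating event.
MIN_EVENT_KCAL = 25.0

#: Half-width of the meal-to-CGM matching window.
MATCH_WINDOW_MINUTES = 5.0

MACRO_FIELDS = ("carb_g", "fat_g", "protein_g")


@dataclass(frozen=True)
class MealRecord:
    """One raw food-log row (a reported meal, snack or beverage)."""

    participant_id: str
    week: int
    timestamp: pd.Timestamp
    energy_kcal: float
    macros: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_kcal) or self.energy_kcal < 0:
            raise ValueError("energy_kcal must be finite and >= 0")
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))


@dataclass(frozen=True)
class EatingEvent:
    """A consolidated, valid eating event (>=25 kcal, >=15 min separated)."""

    timestamp: pd.Timestamp
    energy_kcal: float
    macros: Mapping[str, float] | None = None
    preprandial_glucose: float | None = None
    matched: bool | None = None
    is_lge: bool | None = None


@dataclass(frozen=True)
class InclusionDecision:
    participant_id: str
    valid_days_week0: int | None
    valid_days_week16: int | None
    included: bool
    reason: str = ""


def read_food_log_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a food-log CSV (``participant_id,week,timestamp,kcal[,macros]``)."""
    df = pd.read_csv(path)
    colmap = dict(column_map or {})
    required = ("participant_id", "week", "timestamp", "kcal")
    rename = {colmap.get(std, std): std for std in required}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"food log missing column(s): {missing}")
    df = df.rename(columns=rename)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def records_from_frame(df: pd.DataFrame) -> list[MealRecord]:
    recs = []
    for row in df.itertuples(index=False):
        macros = {m: float(getattr(row, m)) for m in MACRO_FIELDS
                  if hasattr(row, m) and np.isfinite(getattr(row, m))} or None
        recs.append(MealRecord(str(row.participant_id), int(row.week),
                               pd.Timestamp(row.timestamp), float(row.kcal), macros))
    return recs


def consolidate_events(records: Sequence[MealRecord] | Sequence[EatingEvent]) -> list[EatingEvent]:
    """Chain-merge sub-15-min records, then drop merged events under 25 kcal.

    Merging is a chain: if A–B and B–C are each under 15 min apart, A, B and C
    form one event even when A–C is not.  The merged event carries the summed
    energy/macros and the earliest timestamp.  The kcal filter applies after
    merging, so two small items eaten together can jointly qualify.  Idempotent.
    """
    if not records:
        return []
    items = sorted(records, key=lambda r: pd.Timestamp(r.timestamp))
    groups: list[list] = [[items[0]]]
    for rec in items[1:]:
        prev = groups[-1][-1]
        gap_min = (pd.Timestamp(rec.timestamp) - pd.Timestamp(prev.timestamp)).total_seconds() / 60.0
        if gap_min < MERGE_WINDOW_MINUTES:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    events: list[EatingEvent] = []
    for grp in groups:
        energy = float(sum(_energy(g) for g in grp))
        macros: dict[str, float] = {}
        for g in grp:
            for k, v in (_macros(g) or {}).items():
                macros[k] = macros.get(k, 0.0) + v
        if energy < MIN_EVENT_KCAL:
            continue
        events.append(EatingEvent(timestamp=pd.Timestamp(grp[0].timestamp),
                                  energy_kcal=energy, macros=macros or None))
    return events


def _energy(rec) -> float:
    return rec.energy_kcal


def _macros(rec):
    return rec.macros


def match_preprandial(
    events: Sequence[EatingEvent],
    grid_trace: GlucoseTrace,
    window_minutes: float = MATCH_WINDOW_MINUTES,
) -> list[EatingEvent]:
    """Attach the nearest-grid glucose within +/-``window_minutes`` to each event.

    On a distance tie the reading at or before the meal wins (preprandial
    semantics).  Events with no grid reading inside the window come back with
    ``matched=False`` and no glucose value.
    """
    out: list[EatingEvent] = []
    grid_ns = grid_trace.timestamps.asi8
    win_ns = window_minutes * 60e9
    for ev in events:
        t = pd.Timestamp(ev.timestamp).value
        i = int(np.searchsorted(grid_ns, t))
        candidates = []
        if i > 0 and t - grid_ns[i - 1] <= win_ns + 1e3:
            candidates.append(i - 1)
        if i < len(grid_ns) and grid_ns[i] - t <= win_ns + 1e3:
            candidates.append(i)
        if not candidates:
            out.append(replace(ev, matched=False, preprandial_glucose=None))
            continue
        # nearest wins; tie prefers the at-or-before reading (listed first)
        best = min(candidates, key=lambda j: (abs(grid_ns[j] - t), grid_ns[j] > t))
        out.append(replace(ev, matched=True,
                           preprandial_glucose=float(grid_trace.values[best])))
    return out


def find_valid_days(events: Sequence[EatingEvent], trace: GlucoseTrace) -> dict[date, bool]:
    """Flag each trace calendar day valid iff >=2 matched events and plausible CGM."""
    plausible = assess_plausibility(trace).plausible
    counts: dict[date, int] = {}
    for ev in events:
        if ev.matched:
            d = pd.Timestamp(ev.timestamp).date()
            counts[d] = counts.get(d, 0) + 1
    days = {ts.date() for ts in trace.timestamps}
    return {d: plausible and counts.get(d, 0) >= 2 for d in sorted(days)}


def decide_inclusion(
    participant_id: str,
    valid_days_by_week: Mapping[int, int],
    min_valid_days: int = 3,
    weeks: tuple[int, int] = (0, 16),
) -> InclusionDecision:
    """Include a participant iff both assessments have >= ``min_valid_days``."""
    w0, w16 = weeks
    c0 = valid_days_by_week.get(w0)
    c16 = valid_days_by_week.get(w16)
    if c0 is None or c16 is None:
        missing = [w for w, c in ((w0, c0), (w16, c16)) if c is None]
        return InclusionDecision(participant_id, c0, c16, False,
                                 reason=f"missing assessment week(s) {missing}")
    included = c0 >= min_valid_days and c16 >= min_valid_days
    reason = "" if included else f"valid days ({c0}, {c16}) below {min_valid_days}"
    return InclusionDecision(participant_id, c0, c16, included, reason)
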