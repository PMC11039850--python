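"""Personalized glucose thresholds and the low-glucose-eating statistic.

Low-glucose eating (LGE) is the percentage of a participant's included eating
events whose preprandial glucose sits at or below a personalized threshold.
The threshold is the arithmetic mean of exactly two morning fasting glucose
readings; "at or below" is inclusive.  Only events successfully matched to a
CGM reading enter either the numerator or the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cgm_io import GlucoseTrace
from .errors import UndefinedResultError
from .meal_events import EatingEvent


@dataclass(frozen=True)
class GlucoseThreshold:
    """A participant-assessment's personalized fasting-derived threshold."""

    participant_id: str
    week: int
    threshold_mg_dl: float
    source_values: tuple[float, float]


@dataclass(frozen=True)
class LgeResult:
    participant_id: str
    week: int
    n_events_included: int
    n_events_lge: int
    lge_percent: float


def derive_threshold(
    participant_id: str, week: int, fasting_values: Sequence[float]
) -> GlucoseThreshold:
    """Average exactly two positive morning fasting readings (unrounded).

    A single value is never silently accepted: the threshold definition calls
    for two independent morning draws.
    """
    vals = [float(v) for v in fasting_values]
    if len(vals) != 2:
        raise ValueError(f"need exactly 2 fasting values, got {len(vals)}")
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise ValueError("fasting values must be positive and finite")
    return GlucoseThreshold(participant_id, week, (vals[0] + vals[1]) / 2.0,
                            (vals[0], vals[1]))


def classify_event(event: EatingEvent, threshold: GlucoseThreshold | float) -> bool:
    """True iff the event's preprandial glucose is at or below the threshold."""
    if not event.matched or event.preprandial_glucose is None:
        raise UndefinedResultError("cannot classify an unmatched event")
    thr = threshold.threshold_mg_dl if isinstance(threshold, GlucoseThreshold) else float(threshold)
    return event.preprandial_glucose <= thr


def compute_lge(
    events: Sequence[EatingEvent], threshold: GlucoseThreshold
) -> LgeResult:
    """LGE% = 100 x (matched events at/below threshold) / (matched events)."""
    included = [ev for ev in events if ev.matched]
    if not included:
        raise UndefinedResultError(
            f"{threshold.participant_id}/wk{threshold.week}: no matched eating events")
    n_lge = sum(classify_event(ev, threshold) for ev in included)
    return LgeResult(threshold.participant_id, threshold.week,
                     len(included), int(n_lge),
                     100.0 * n_lge / len(included))


def classify_events(
    events: Sequence[EatingEvent], threshold: GlucoseThreshold
) -> list[EatingEvent]:
    """Return events with ``is_lge`` filled for matched ones."""
    out = []
    for ev in events:
        if ev.matched:
            out.append(replace(ev, is_lge=classify_event(ev, threshold)))
        else:
            out.append(ev)
    return out


def estimate_morning_fasting(
    trace: GlucoseTrace,
    first_meal_time: pd.Timestamp | None = None,
    window: tuple[int, int] = (6, 8),
) -> float:
    """Fallback estimate of morning fasting glucose from the CGM itself.

    Mean of readings between ``window`` hours (default 06:00-08:00) that
    precede the day's first meal.  The anthropometrics file takes precedence
    when it supplies fasting draws; this helper exists for data sets without
    them.
    """
    hours = trace.timestamps.hour
    mask = (hours >= window[0]) & (hours < window[1])
    if first_meal_time is not None:
        mask &= trace.timestamps < pd.Timestamp(first_meal_time)
    if not mask.any():
        raise UndefinedResultError("no pre-meal readings in the morning window")
    return float(np.mean(trace.values[mask]))
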