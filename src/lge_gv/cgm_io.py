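"""Reading, validating, resampling and segmenting CGM glucose traces.

A :class:`GlucoseTrace` holds one participant-assessment's time-ordered
interstitial glucose readings in mg/dL (FreeStyle Libre Pro-style exports
report every ~15 min).  Traces are screened with a physiologic-plausibility
rule — a trace is plausible when more than 95% of readings are at or above
70 mg/dL, the lower bound of the physiological range expected in a
non-insulin-treated population without diabetes.

All internal time handling is timezone-naive (single-site assumption) and
uses half-open intervals; calendar days split at local midnight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientDataError, SchemaError

logger = logging.getLogger(__name__)

#: mg/dL floor of the physiological range used by the plausibility screen.
PHYSIOLOGIC_FLOOR_MGDL = 70.0

#: Fraction of readings that must sit at/above the floor (strict inequality).
PLAUSIBILITY_FRACTION = 0.95

#: Default interpolation grid (minutes) used for meal matching.
DEFAULT_GRID_MINUTES = 5

#: Raw gaps longer than this are never interpolated across.
DEFAULT_MAX_GAP_MINUTES = 60

_STANDARD_COLUMNS = ("participant_id", "week", "timestamp", "glucose_mg_dl")


@dataclass(frozen=True)
class GlucoseTrace:
    """Time-ordered CGM readings for one participant-assessment.

    Parameters
    ----------
    participant_id : str
        Participant identifier.
    week : int
        Assessment label (0 or 16 in a two-timepoint design).
    timestamps : pandas.DatetimeIndex
        Strictly increasing, timezone-naive reading instants.
    values : numpy.ndarray
        Glucose in mg/dL, positive and finite, aligned with ``timestamps``.
    cadence_minutes : float
        Nominal spacing between readings in minutes.
    """

    participant_id: str
    week: int
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    cadence_minutes: float = 15.0

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if len(ts) == 0:
            raise EmptyInputError("trace has no readings")
        if len(ts) != len(vals):
            raise ValueError("timestamps and values differ in length")
        if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("glucose values must be positive and finite")
        if self.cadence_minutes <= 0:
            raise ValueError("cadence_minutes must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def seconds(self) -> np.ndarray:
        """Reading times as seconds since the first reading."""
        return (self.timestamps.asi8 - self.timestamps.asi8[0]) / 1e9

    @property
    def span_hours(self) -> float:
        return float((self.timestamps[-1] - self.timestamps[0]).total_seconds() / 3600.0)

    def replace_values(self, values: np.ndarray) -> "GlucoseTrace":
        return GlucoseTrace(self.participant_id, self.week, self.timestamps,
                            np.asarray(values, float), self.cadence_minutes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "week": self.week,
            "timestamp": self.timestamps,
            "glucose_mg_dl": self.values,
        })


@dataclass(frozen=True)
class PlausibilityReport:
    """Outcome of the >95%-of-wear-at-or-above-70-mg/dL screen."""

    fraction_in_physiologic_range: float
    plausible: bool
    n_readings: int


@dataclass
class CgmReadResult:
    """Traces parsed from a CGM CSV plus a log of dropped rows."""

    traces: list[GlucoseTrace]
    n_dropped_unparseable: int = 0
    n_dropped_nonpositive: int = 0
    n_dropped_duplicates: int = 0
    log: list[str] = field(default_factory=list)

    def by_assessment(self) -> dict[tuple[str, int], GlucoseTrace]:
        return {(t.participant_id, t.week): t for t in self.traces}


def read_cgm_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    cadence_minutes: float = 15.0,
) -> CgmReadResult:
    """Read a CGM CSV into one :class:`GlucoseTrace` per participant-week.

    The expected header is ``participant_id,week,timestamp,glucose_mg_dl``;
    ``column_map`` remaps standard names to dialect columns (e.g. a Libre Pro
    export's "Historic Glucose (mg/dL)").  Rows with unparseable timestamps or
    non-positive glucose are dropped and counted; duplicate timestamps within
    a participant-week keep the first occurrence.
    """
    df = pd.read_csv(path)
    colmap = dict(column_map or {})
    rename = {colmap.get(std, std): std for std in _STANDARD_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    df = df.rename(columns=rename)[list(_STANDARD_COLUMNS)]
    return traces_from_frame(df, cadence_minutes=cadence_minutes)


def traces_from_frame(df: pd.DataFrame, cadence_minutes: float = 15.0) -> CgmReadResult:
    """Build validated traces from a long-format CGM DataFrame."""
    missing = [c for c in _STANDARD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    result = CgmReadResult(traces=[])
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    bad_ts = ts.isna()
    bad_val = ~bad_ts & (glucose.isna() | (glucose <= 0))
    result.n_dropped_unparseable = int(bad_ts.sum())
    result.n_dropped_nonpositive = int(bad_val.sum())
    keep = ~(bad_ts | bad_val)
    if result.n_dropped_unparseable:
        result.log.append(f"dropped {result.n_dropped_unparseable} unparseable-timestamp rows")
    if result.n_dropped_nonpositive:
        result.log.append(f"dropped {result.n_dropped_nonpositive} non-positive glucose rows")
    clean = pd.DataFrame({
        "participant_id": df.loc[keep, "participant_id"].astype(str),
        "week": df.loc[keep, "week"].astype(int),
        "timestamp": ts[keep],
        "glucose_mg_dl": glucose[keep].astype(float),
    })
    if clean.empty:
        raise EmptyInputError("no parseable CGM rows")
    for (pid, week), grp in clean.groupby(["participant_id", "week"], sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        dup = grp["timestamp"].duplicated(keep="first")
        if dup.any():
            result.n_dropped_duplicates += int(dup.sum())
            result.log.append(f"{pid}/wk{week}: kept first of {int(dup.sum())} duplicate timestamps")
            grp = grp[~dup]
        result.traces.append(GlucoseTrace(
            participant_id=str(pid), week=int(week),
            timestamps=pd.DatetimeIndex(grp["timestamp"]),
            values=grp["glucose_mg_dl"].to_numpy(),
            cadence_minutes=cadence_minutes,
        ))
    return result


def assess_plausibility(trace: GlucoseTrace) -> PlausibilityReport:
    """Apply the physiologic-plausibility screen to a trace.

    The fraction of readings at or above 70 mg/dL proxies the fraction of
    wear time (readings are evenly spaced); the trace is plausible iff that
    fraction strictly exceeds 0.95.
    """
    n = len(trace)
    frac = float(np.mean(trace.values >= PHYSIOLOGIC_FLOOR_MGDL))
    return PlausibilityReport(
        fraction_in_physiologic_range=frac,
        plausible=frac > PLAUSIBILITY_FRACTION,
        n_readings=n,
    )


def resample_trace(
    trace: GlucoseTrace,
    grid_minutes: int = DEFAULT_GRID_MINUTES,
    max_gap_minutes: int = DEFAULT_MAX_GAP_MINUTES,
) -> GlucoseTrace:
    """Linearly interpolate a trace onto a regular grid anchored at its start.

    Grid points that fall strictly inside a raw gap longer than
    ``max_gap_minutes`` are omitted rather than synthesized, so the output may
    itself contain holes.  Resampling an already-gridded trace at the same
    grid is the identity.
    """
    if grid_minutes < 1:
        raise ValueError("grid_minutes must be >= 1")
    if len(trace) < 2:
        raise EmptyInputError("need at least 2 readings to resample")
    sec = trace.seconds
    step = grid_minutes * 60.0
    grid = np.arange(0.0, sec[-1] + 0.5 * step, step)
    grid = grid[grid <= sec[-1] + 1e-9]
    interp = np.interp(grid, sec, trace.values)
    # mask grid points strictly inside over-long raw gaps
    gaps = np.diff(sec)
    keep = np.ones(len(grid), dtype=bool)
    for i in np.nonzero(gaps > max_gap_minutes * 60.0 + 1e-9)[0]:
        keep &= ~((grid > sec[i] + 1e-9) & (grid < sec[i + 1] - 1e-9))
    ts0 = trace.timestamps[0]
    new_ts = ts0 + pd.to_timedelta(grid[keep], unit="s")
    return GlucoseTrace(trace.participant_id, trace.week,
                        pd.DatetimeIndex(new_ts), interp[keep],
                        cadence_minutes=float(grid_minutes))


def split_days(trace: GlucoseTrace) -> list[GlucoseTrace]:
    """Partition a trace into per-calendar-day sub-traces (midnight bounds).

    The parts are disjoint and their concatenation reproduces the input.
    Parts may hold a single reading (e.g. a trace starting 23:50).
    """
    dates = trace.timestamps.normalize()
    parts: list[GlucoseTrace] = []
    for day in dates.unique():
        mask = dates == day
        parts.append(GlucoseTrace(trace.participant_id, trace.week,
                                  trace.timestamps[mask], trace.values[mask],
                                  trace.cadence_minutes))
    return parts


def concat_traces(parts: Sequence[GlucoseTrace]) -> GlucoseTrace:
    """Re-join day parts produced by :func:`split_days`."""
    if not parts:
        raise EmptyInputError("nothing to concatenate")
    ts = pd.DatetimeIndex(np.concatenate([p.timestamps.asi8 for p in parts]).view("M8[ns]"))
    vals = np.concatenate([p.values for p in parts])
    first = parts[0]
    return GlucoseTrace(first.participant_id, first.week, ts, vals, first.cadence_minutes)


def require_span(trace: GlucoseTrace, hours: float, what: str) -> None:
    if trace.span_hours <= hours:
        raise InsufficientDataError(f"{what}: trace spans {trace.span_hours:.1f} h <= {hours} h")
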