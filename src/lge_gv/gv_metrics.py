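"""Glycemic-variability metric battery for CGM traces.

Implements the classic CGM variability statistics — mean, SD, CONGA, LI,
J-index, LBGI/HBGI, ADRR, GRADE, MAGE, MODD and the M-value — with every
formula fixed explicitly and unit conventions documented per metric.  The
canonical internal unit is mg/dL; metrics conventionally reported in mmol/L
(CONGA, MAGE, MODD) are converted with K = 18.016 mg/dL per mmol/L.

Conventions (see docs/methods.md for rationale):

* CONGA: sample SD (N-1 divisor) of lagged differences, default lag 60 min,
  pair tolerance = half the cadence; reported in mmol/L.
* LI: squared successive differences at a 60-min grid divided by the elapsed
  hours, summed and normalized per day of observation; (mmol/L)^2/h.
* LBGI/HBGI: Kovatchev risk transform f(G) = 1.509[(ln G)^1.084 - 5.381],
  risk r = 10 f^2 split into low/high sides, averaged over readings.
* ADRR: mean over calendar days of (max low risk + max high risk); days with
  fewer than 12 readings are excluded as degenerate.
* GRADE: mean of 425[log10(log10(G_mmol)) + 0.16]^2 capped at 50 per reading.
* MAGE: three-point turning points (plateaus collapsed), excursions counted in
  both directions when their amplitude exceeds the whole-trace sample SD.
* M-value: mean |10 log10(G/ref)|^3 with ref 120 mg/dL, no sparse-sampling
  range correction.

All metrics operate on the trace at its native cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgm_io import GlucoseTrace, split_days
from .errors import DomainError, InsufficientDataError

#: Unit conversion: mg/dL per mmol/L of glucose.
MGDL_PER_MMOL = 18.016

#: Zero-risk glucose of the Kovatchev transform, exp(5.381**(1/1.084)) mg/dL.
RISK_ROOT_MGDL = float(np.exp(5.381 ** (1 / 1.084)))

GRADE_CAP = 50.0
ADRR_MIN_READINGS_PER_DAY = 12
M_VALUE_REFERENCE_MGDL = 120.0


@dataclass
class GVProfile:
    """The full metric battery for one participant-assessment."""

    participant_id: str
    week: int
    mean_mg_dl: float
    sd_mg_dl: float
    conga_mmol: float
    li_mmol2_per_h: float
    j_index: float
    hbgi: float
    lbgi: float
    adrr: float
    grade: float
    mage_mmol: float
    modd_mmol: float
    m_value: float
    mage_no_excursions: bool = False
    glucotype_fractions: tuple[float, float, float] | None = None

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id, "week": self.week,
            "mean_mg_dl": self.mean_mg_dl, "sd_mg_dl": self.sd_mg_dl,
            "conga_mmol": self.conga_mmol, "li_mmol2_per_h": self.li_mmol2_per_h,
            "j_index": self.j_index, "hbgi": self.hbgi, "lbgi": self.lbgi,
            "adrr": self.adrr, "grade": self.grade, "mage_mmol": self.mage_mmol,
            "modd_mmol": self.modd_mmol, "m_value": self.m_value,
            "mage_no_excursions": self.mage_no_excursions,
        }
        if self.glucotype_fractions is not None:
            d["frac_low"], d["frac_moderate"], d["frac_severe"] = self.glucotype_fractions
        return d


def mean_sd(trace: GlucoseTrace) -> tuple[float, float]:
    """Arithmetic mean and sample SD (N-1 divisor), both in mg/dL."""
    if len(trace) < 2:
        raise InsufficientDataError("sd needs at least 2 readings")
    return float(np.mean(trace.values)), float(np.std(trace.values, ddof=1))


def conga(trace: GlucoseTrace, lag_minutes: float = 60.0) -> float:
    """CONGA: sample SD of G_t - G_{t-lag} over valid pairs, in mmol/L.

    A pair is valid when a reading exists lag +/- (cadence/2) before t.
    """
    sec = trace.seconds
    lag = lag_minutes * 60.0
    tol = trace.cadence_minutes * 60.0 / 2.0
    diffs = _lagged_differences(sec, trace.values, lag, tol)
    if len(diffs) < 2:
        raise InsufficientDataError("conga needs >= 2 lagged pairs")
    return float(np.std(diffs, ddof=1)) / MGDL_PER_MMOL


def _lagged_differences(sec: np.ndarray, vals: np.ndarray, lag: float, tol: float) -> np.ndarray:
    targets = sec - lag
    idx = np.searchsorted(sec, targets)
    out = []
    for i, (t, j) in enumerate(zip(targets, idx)):
        best, best_d = -1, tol + 1e-9
        for k in (j - 1, j):
            if 0 <= k < len(sec) and abs(sec[k] - t) < best_d:
                best, best_d = k, abs(sec[k] - t)
        if best >= 0:
            out.append(vals[i] - vals[best])
    return np.asarray(out)


def li(trace: GlucoseTrace, interval_minutes: float = 60.0) -> float:
    """Lability index at a fixed interval grid, (mmol/L)^2 per hour per day.

    Readings are sampled at t0 + k*interval (nearest within half a cadence);
    LI = sum (dG_mmol)^2 / dt_hours over successive grid readings, divided by
    the days of observation (span/24 h, floored at one day).
    """
    sec = trace.seconds
    tol = trace.cadence_minutes * 60.0 / 2.0
    step = interval_minutes * 60.0
    targets = np.arange(0.0, sec[-1] + tol, step)
    picked_t, picked_v = [], []
    for t in targets:
        j = int(np.searchsorted(sec, t))
        best, best_d = -1, tol + 1e-9
        for k in (j - 1, j):
            if 0 <= k < len(sec) and abs(sec[k] - t) < best_d:
                best, best_d = k, abs(sec[k] - t)
        if best >= 0 and (not picked_t or best != picked_t[-1]):
            picked_t.append(best)
            picked_v.append(trace.values[best])
    if len(picked_v) < 2:
        raise InsufficientDataError("li needs >= 2 grid readings")
    tsel = sec[np.asarray(picked_t)]
    vsel = np.asarray(picked_v) / MGDL_PER_MMOL
    dt_h = np.diff(tsel) / 3600.0
    total = np.sum(np.diff(vsel) ** 2 / dt_h)
    days = max((sec[-1] - sec[0]) / 86400.0, 1.0)
    return float(total / days)


def j_index(trace: GlucoseTrace) -> float:
    """J = 0.001 x (mean + SD)^2 with mean and SD in mg/dL."""
    m, s = mean_sd(trace)
    return 0.001 * (m + s) ** 2


def risk_transform(values: np.ndarray) -> np.ndarray:
    """Kovatchev symmetrizing transform f(G), G in mg/dL."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise DomainError("risk transform needs positive glucose")
    return 1.509 * (np.log(values) ** 1.084 - 5.381)


def _risk_sides(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = risk_transform(values)
    r = 10.0 * f ** 2
    return np.where(f < 0, r, 0.0), np.where(f > 0, r, 0.0)


def bgi(trace: GlucoseTrace) -> tuple[float, float]:
    """(LBGI, HBGI): mean low-side and high-side Kovatchev risk."""
    rl, rh = _risk_sides(trace.values)
    return float(np.mean(rl)), float(np.mean(rh))


def adrr(trace: GlucoseTrace) -> float:
    """Average daily risk range: mean over days of (max rl + max rh).

    Calendar days with fewer than 12 readings are excluded; with no
    qualifying day the statistic is undefined.
    """
    daily = []
    for day in split_days(trace):
        if len(day) < ADRR_MIN_READINGS_PER_DAY:
            continue
        rl, rh = _risk_sides(day.values)
        daily.append(float(np.max(rl) + np.max(rh)))
    if not daily:
        raise InsufficientDataError("adrr: no day with >= 12 readings")
    return float(np.mean(daily))


def grade(trace: GlucoseTrace) -> float:
    """GRADE: mean capped log-log penalty around euglycemia.

    h(G) = min(50, 425 [log10(log10(G_mmol)) + 0.16]^2).  Readings at or
    below 1 mmol/L fall outside the log-log domain and are excluded; if all
    readings are excluded the statistic is undefined.
    """
    g_mmol = trace.values / MGDL_PER_MMOL
    ok = g_mmol > 1.0
    if not ok.any():
        raise DomainError("grade: no readings above 1 mmol/L")
    h = 425.0 * (np.log10(np.log10(g_mmol[ok])) + 0.16) ** 2
    return float(np.mean(np.minimum(h, GRADE_CAP)))


def mage_excursion_amplitudes(trace: GlucoseTrace) -> list[float]:
    """Amplitudes (mg/dL) of qualifying glucose excursions.

    Turning points are alternating interior extrema of the plateau-collapsed
    reading sequence (three-point rule); an excursion between successive
    turning points qualifies when its amplitude exceeds the whole-trace
    sample SD.  Both rising and falling excursions are counted.
    """
    if len(trace) < 4:
        raise InsufficientDataError("mage needs >= 4 readings")
    v = trace.values
    sd = float(np.std(v, ddof=1))
    # collapse plateaus (runs of equal consecutive values)
    keep = np.concatenate(([True], np.diff(v) != 0))
    w = v[keep]
    if len(w) < 3 or sd == 0:
        return []
    turning = []
    for i in range(1, len(w) - 1):
        if (w[i] > w[i - 1] and w[i] > w[i + 1]) or (w[i] < w[i - 1] and w[i] < w[i + 1]):
            turning.append(w[i])
    amps = [abs(b - a) for a, b in zip(turning, turning[1:])]
    return [a for a in amps if a > sd]


def mage(trace: GlucoseTrace) -> float:
    """MAGE in mmol/L; 0 when no excursion exceeds the trace SD."""
    amps = mage_excursion_amplitudes(trace)
    if not amps:
        return 0.0
    return float(np.mean(amps)) / MGDL_PER_MMOL


def modd(trace: GlucoseTrace) -> float:
    """Mean of daily differences: mean |G_t - G_{t+24h}| in mmol/L.

    Pairs are readings exactly 24 h apart within half a cadence.
    """
    sec = trace.seconds
    diffs = _lagged_differences(sec, trace.values, 86400.0,
                                trace.cadence_minutes * 60.0 / 2.0)
    if len(diffs) == 0:
        raise InsufficientDataError("modd: no 24-h reading pairs")
    return float(np.mean(np.abs(diffs))) / MGDL_PER_MMOL


def m_value(trace: GlucoseTrace, reference: float = M_VALUE_REFERENCE_MGDL) -> float:
    """M-value: mean |10 log10(G/reference)|^3 (no range correction)."""
    if (trace.values <= 0).any():
        raise DomainError("m_value needs positive glucose")
    return float(np.mean(np.abs(10.0 * np.log10(trace.values / reference)) ** 3))


def gv_profile(
    trace: GlucoseTrace,
    conga_lag_minutes: float = 60.0,
    li_interval_minutes: float = 60.0,
    m_reference: float = M_VALUE_REFERENCE_MGDL,
) -> GVProfile:
    """Compute the full battery on one trace at native cadence."""
    m, s = mean_sd(trace)
    lbgi, hbgi = bgi(trace)
    amps = mage_excursion_amplitudes(trace)
    return GVProfile(
        participant_id=trace.participant_id, week=trace.week,
        mean_mg_dl=m, sd_mg_dl=s,
        conga_mmol=conga(trace, conga_lag_minutes),
        li_mmol2_per_h=li(trace, li_interval_minutes),
        j_index=j_index(trace), hbgi=hbgi, lbgi=lbgi,
        adrr=adrr(trace), grade=grade(trace),
        mage_mmol=(float(np.mean(amps)) / MGDL_PER_MMOL) if amps else 0.0,
        modd_mmol=modd(trace), m_value=m_value(trace, m_reference),
        mage_no_excursions=not amps,
    )
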