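"""Synthetic two-timepoint CGM/food-log cohort generator.

Emulates a cohort of postmenopausal women without diabetes wearing a blinded
15-min CGM for several days at weeks 0 and 16 while keeping timestamped food
records.  Each participant-assessment trace is

    G(t) = baseline + circadian sinusoid + sum of post-meal excursions
           + AR(1) sensor noise,  clipped at 40 mg/dL,

with the circadian term crossing zero at 09:00/21:00 (trough near 03:00, so
morning fasting glucose tracks the baseline).  A post-meal excursion rises
linearly for 30 min to its amplitude and decays exponentially afterwards.

Meal timing encodes low-glucose-eating behavior: with probability equal to a
participant's LGE propensity, a meal is placed at the eligible daytime slot
where current simulated glucose is lowest — and only if that glucose is at or
below the participant's fasting-derived threshold (otherwise the intended
low-glucose meal is skipped); other meals land at random daytime slots.  A
configurable fraction of sub-25-kcal "snack noise" records exercises the
downstream energy filter; snacks carry no glucose excursion.

Across assessments, week-16 propensities are week-0 propensities plus
heterogeneous shifts, and week-16 meal amplitudes are shifted by
``effect_size x (propensity shift)`` plus an independent drift, planting a
negative association between change in LGE and change in glycemic
variability.  A ``truth`` table records the planted propensities and GV
levels (meal amplitudes) for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cgm_io import GlucoseTrace
from .errors import InvalidConfigError

CLIP_FLOOR_MGDL = 40.0
MEAL_RISE_MINUTES = 30.0
MIN_RECORD_SEPARATION_MINUTES = 30.0
MEAL_WINDOW_HOURS = (6.0, 22.0)
WEEK0_START = pd.Timestamp("2021-03-01 00:00:00")
WEEK16_OFFSET_DAYS = 112


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the two-timepoint cohort the pipeline targets: 17
    participants, 7 days of 15-min CGM per assessment, baseline glucose near
    97 mg/dL with ~8 mg/dL between-person spread, fasting thresholds in the
    85-110 mg/dL band, 2-6 meals/day, week-0 LGE propensities averaging ~0.3,
    and a negative planted effect of propensity change on meal-excursion
    amplitude (the simulated GV level).
    """

    n_participants: int = 17
    days_per_assessment: int = 7
    cadence_minutes: int = 15
    baseline_mean: float = 97.0
    baseline_between_sd: float = 8.0
    circadian_amplitude: float = 10.0
    meal_amplitude_range: tuple[float, float] = (40.0, 80.0)
    meal_decay_minutes: float = 60.0
    ar_coefficient: float = 0.6
    noise_sd: float = 5.0
    fasting_noise_sd: float = 2.0  # lab-assay scatter of the two morning draws
    lge_propensity_range: tuple[float, float] = (0.05, 0.6)
    propensity_shift_max: float = 0.4
    effect_size: float = -40.0
    gv_drift_sd: float = 5.0
    meals_per_day: tuple[int, int] = (2, 6)
    snack_noise_fraction: float = 0.1
    weight_mean: float = 92.5
    weight_sd: float = 18.5
    weight_change_mean: float = -6.9
    weight_change_sd: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")
        if not (3 <= self.days_per_assessment <= 10):
            raise InvalidConfigError("days_per_assessment must be in 3..10")
        if self.cadence_minutes < 1 or 1440 % self.cadence_minutes != 0:
            raise InvalidConfigError("cadence_minutes must divide 1440")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        lo, hi = self.lge_propensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("lge_propensity_range must lie within [0, 1]")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise InvalidConfigError("ar_coefficient must be in [0, 1)")
        mlo, mhi = self.meals_per_day
        if not (1 <= mlo <= mhi):
            raise InvalidConfigError("meals_per_day bounds must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.snack_noise_fraction < 1.0):
            raise InvalidConfigError("snack_noise_fraction must be in [0, 1)")
        if self.meal_amplitude_range[0] <= 0:
            raise InvalidConfigError("meal amplitudes must be positive")


@dataclass
class ParticipantParams:
    """Per participant-assessment generative parameters."""

    participant_id: str
    week: int
    baseline: float
    circadian_amplitude: float
    meal_amplitude: float
    threshold: float
    start: pd.Timestamp
    n_days: int
    meals: list[tuple[float, float]] = field(default_factory=list)  # (sec, amplitude)


@dataclass
class SyntheticCohort:
    """In-memory cohort: the three input tables plus the planted truth."""

    config: SimConfig
    cgm: pd.DataFrame             # participant_id, week, timestamp, glucose_mg_dl
    food_logs: pd.DataFrame       # participant_id, week, timestamp, kcal
    anthropometrics: pd.DataFrame  # participant_id, week, weight_kg, fasting1/2_mg_dl
    truth: pd.DataFrame           # planted propensities and GV levels per participant

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("cgm", self.cgm), ("meals", self.food_logs),
                         ("anthro", self.anthropometrics), ("truth", self.truth)):
            p = out / f"{name}.csv"
            frame = df.copy()
            for col in frame.columns:
                if pd.api.types.is_datetime64_any_dtype(frame[col]):
                    frame[col] = frame[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
            frame.to_csv(p, index=False)
            paths[name] = p
        return paths


def _circadian(seconds_of_day: np.ndarray, amplitude: float) -> np.ndarray:
    # zero-crossings at 09:00 and 21:00; trough near 03:00
    hours = seconds_of_day / 3600.0
    return amplitude * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)


def _meal_response(sec: np.ndarray, meals: list[tuple[float, float]],
                   decay_minutes: float) -> np.ndarray:
    out = np.zeros_like(sec, dtype=float)
    rise = MEAL_RISE_MINUTES * 60.0
    decay = decay_minutes * 60.0
    for t_m, amp in meals:
        dt = sec - t_m
        rising = (dt >= 0) & (dt <= rise)
        falling = dt > rise
        out[rising] += amp * dt[rising] / rise
        out[falling] += amp * np.exp(-(dt[falling] - rise) / decay)
    return out


def ar1_noise(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) fluctuation series with marginal SD ``noise_sd``."""
    if config.noise_sd == 0:
        return np.zeros(n)
    phi = config.ar_coefficient
    innov_sd = config.noise_sd * np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, config.noise_sd)
    for i in range(1, n):
        noise[i] = phi * noise[i - 1] + eps[i]
    return noise


def simulate_trace(
    config: SimConfig,
    params: ParticipantParams,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
) -> GlucoseTrace:
    """Simulate one assessment's CGM trace on the cadence grid.

    With ``rng`` and ``noise`` omitted (or ``noise_sd`` 0) the trace is the
    deterministic baseline + circadian + meal-response curve; otherwise
    stationary AR(1) fluctuations with marginal SD ``noise_sd`` are added —
    either the precomputed ``noise`` series (so meal scheduling can condition
    on the same glucose state the sensor records) or one drawn from ``rng``.
    Values are clipped at the 40 mg/dL sensor floor.
    """
    if params.n_days * 86400.0 <= 86400.0:
        raise InvalidConfigError("trace duration must exceed 24 h")
    step = config.cadence_minutes * 60.0
    sec = np.arange(0.0, params.n_days * 86400.0, step)
    g = (params.baseline
         + _circadian(sec % 86400.0, params.circadian_amplitude)
         + _meal_response(sec, params.meals, config.meal_decay_minutes))
    if noise is None and rng is not None:
        noise = ar1_noise(config, len(sec), rng)
    if noise is not None:
        g = g + noise
    g = np.maximum(g, CLIP_FLOOR_MGDL)
    ts = params.start + pd.to_timedelta(sec, unit="s")
    return GlucoseTrace(params.participant_id, params.week,
                        pd.DatetimeIndex(ts), g,
                        cadence_minutes=float(config.cadence_minutes))


def _deterministic_glucose(config: SimConfig, params: ParticipantParams,
                           sec: np.ndarray) -> np.ndarray:
    return (params.baseline
            + _circadian(sec % 86400.0, params.circadian_amplitude)
            + _meal_response(sec, params.meals, config.meal_decay_minutes))


def simulate_meals(
    config: SimConfig,
    params: ParticipantParams,
    lge_propensity: float,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> pd.DataFrame:
    """Schedule one assessment's food-log records; updates ``params.meals``.

    Meals sit on the cadence grid between 06:00 and 22:00, separated by at
    least 30 min.  LGE-intent meals go to the eligible slot with the lowest
    current glucose — the deterministic curve plus the participant's ``noise``
    fluctuation series when given (the eater responds to their actual glucose
    state, which is also what the sensor records) — provided that glucose is
    at or below the threshold; intent meals with no qualifying slot are
    skipped.  Snack-noise records (< 25 kcal, no excursion) are interleaved
    at the configured rate.
    """
    if not (0.0 <= lge_propensity <= 1.0):
        raise InvalidConfigError("lge_propensity must be in [0, 1]")
    step = config.cadence_minutes * 60.0
    lo_h, hi_h = MEAL_WINDOW_HOURS
    day_slots = np.arange(lo_h * 3600.0, hi_h * 3600.0, step)

    def glucose_at(slots: np.ndarray) -> np.ndarray:
        g = _deterministic_glucose(config, params, slots)
        if noise is not None:
            g = g + noise[(slots / step).astype(int)]
        return g
    min_sep = MIN_RECORD_SEPARATION_MINUTES * 60.0
    rows = []
    occupied: list[float] = []
    mlo, mhi = config.meals_per_day
    f = config.snack_noise_fraction
    last_meal_time = -np.inf
    for day in range(params.n_days):
        n_meals = int(rng.integers(mlo, mhi + 1))
        intents = rng.random(n_meals) < lge_propensity
        placed_today = 0
        # meals are placed in chronological order so that a later placement
        # can never perturb the preprandial glucose of an earlier meal
        for is_lge_intent in intents:
            slots = day * 86400.0 + day_slots
            free = np.array([s for s in slots
                             if s >= last_meal_time + min_sep
                             and all(abs(s - o) >= min_sep for o in occupied)])
            if len(free) == 0:
                continue
            if is_lge_intent:
                g = glucose_at(free)
                eligible = free[g <= params.threshold + 1e-9]
                if len(eligible) == 0:
                    continue  # no low-glucose opportunity: the intent meal is skipped
                t = float(eligible[int(np.argmin(g[g <= params.threshold + 1e-9]))])
            else:
                t = float(rng.choice(free))
            amp = params.meal_amplitude * rng.uniform(0.8, 1.2)
            params.meals.append((t, amp))
            params.meals.sort()
            occupied.append(t)
            last_meal_time = max(last_meal_time, t)
            placed_today += 1
            rows.append({"sec": t, "kcal": float(rng.uniform(150.0, 700.0))})
        if f > 0 and placed_today:
            n_snacks = int(rng.poisson(placed_today * f / (1.0 - f)))
            for _ in range(n_snacks):
                slots = day * 86400.0 + day_slots
                free = [s for s in slots if all(abs(s - o) >= min_sep for o in occupied)]
                if not free:
                    break
                t = float(rng.choice(free))
                occupied.append(t)
                rows.append({"sec": t, "kcal": float(rng.uniform(5.0, 24.0))})
    rows.sort(key=lambda r: r["sec"])
    return pd.DataFrame({
        "participant_id": params.participant_id,
        "week": params.week,
        "timestamp": params.start + pd.to_timedelta([r["sec"] for r in rows], unit="s"),
        "kcal": [r["kcal"] for r in rows],
    })


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full two-timepoint cohort (deterministic given the seed)."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_participants)
    cgm_frames, food_frames, anthro_rows, truth_rows = [], [], [], []
    for i in range(config.n_participants):
        rng = np.random.default_rng(child_seeds[i])
        pid = f"P{i + 1:03d}"
        baseline = float(rng.normal(config.baseline_mean, config.baseline_between_sd))
        p0 = float(rng.uniform(*config.lge_propensity_range))
        shift = float(rng.uniform(-config.propensity_shift_max,
                                  config.propensity_shift_max))
        p16 = float(np.clip(p0 + shift, 0.0, 1.0))
        amp0 = float(rng.uniform(*config.meal_amplitude_range))
        drift = float(rng.normal(0.0, config.gv_drift_sd))
        amp16 = float(np.clip(amp0 + drift + config.effect_size * (p16 - p0),
                              10.0, None))
        weight0 = float(rng.normal(config.weight_mean, config.weight_sd))
        weight16 = weight0 + float(rng.normal(config.weight_change_mean,
                                              config.weight_change_sd))
        thresholds = {}
        for week, prop, amp, weight in ((0, p0, amp0, weight0),
                                        (16, p16, amp16, weight16)):
            start = WEEK0_START + pd.Timedelta(days=WEEK16_OFFSET_DAYS * (week // 16))
            fasting = baseline + rng.normal(0.0, config.fasting_noise_sd, size=2)
            fasting = np.maximum(fasting, CLIP_FLOOR_MGDL)
            threshold = float(np.mean(fasting))
            thresholds[week] = threshold
            params = ParticipantParams(
                participant_id=pid, week=week, baseline=baseline,
                circadian_amplitude=config.circadian_amplitude,
                meal_amplitude=amp, threshold=threshold,
                start=start, n_days=config.days_per_assessment)
            n_grid = int(config.days_per_assessment * 86400.0
                         / (config.cadence_minutes * 60.0))
            noise = ar1_noise(config, n_grid, rng)
            food = simulate_meals(config, params, prop, rng, noise=noise)
            trace = simulate_trace(config, params, noise=noise)
            cgm_frames.append(trace.to_frame())
            food_frames.append(food)
            anthro_rows.append({
                "participant_id": pid, "week": week, "weight_kg": weight,
                "fasting1_mg_dl": float(fasting[0]),
                "fasting2_mg_dl": float(fasting[1]),
            })
        truth_rows.append({
            "participant_id": pid, "baseline_mg_dl": baseline,
            "propensity_week0": p0, "propensity_week16": p16,
            "gv_level_week0": amp0, "gv_level_week16": amp16,
            "threshold_week0": thresholds[0], "threshold_week16": thresholds[16],
            "weight_week0": weight0, "weight_week16": weight16,
        })
    return SyntheticCohort(
        config=config,
        cgm=pd.concat(cgm_frames, ignore_index=True),
        food_logs=pd.concat(food_frames, ignore_index=True),
        anthropometrics=pd.DataFrame(anthro_rows),
        truth=pd.DataFrame(truth_rows),
    )
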