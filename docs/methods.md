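# Methods

## Overview

The package operationalizes a two-timepoint observational analysis: for each
participant at weeks 0 and 16 it scores low-glucose eating (LGE) from
timestamped food logs merged with CGM, computes a battery of glycemic-
variability (GV) metrics and glucotype time fractions from the CGM trace,
forms week-16 − week-0 change scores, and estimates the association between
ΔLGE and each ΔGV with and without adjustment for concurrent weight change.

## Event scoring and inclusion rules

* **Consolidation.** Food-log records are chain-merged when successive
  records are < 15 min apart (energy and macros summed, earliest timestamp
  kept); merged events < 25 kcal are dropped. The chain rule means A, B, C
  merge when A–B and B–C are each < 15 min even if A–C is not; it is
  deterministic and order-independent. The kcal filter runs *after* merging,
  so two small items eaten together can jointly qualify as one event.
* **Preprandial matching.** The raw trace is linearly interpolated onto a
  5-min grid (never across raw gaps > 60 min); each event takes the nearest
  grid value within ±5 min, preferring the reading at or before the meal on
  ties (preprandial semantics). Unmatched events are excluded from both the
  LGE numerator and denominator.
* **Thresholds.** The personalized threshold is the unrounded mean of exactly
  two positive morning fasting draws; classification is inclusive
  (G ≤ threshold). By default the week-0 threshold carries forward to week 16
  (`threshold_mode="per_assessment"` uses each week's draws instead).
* **Plausibility and inclusion.** A trace is plausible when > 95% (strict) of
  readings are ≥ 70 mg/dL (reading counts proxy wear time at even cadence).
  A calendar day (local midnight bounds, single-timezone data) is valid when
  it has ≥ 2 matched events on a plausible trace; a participant is included
  when both weeks have ≥ 3 valid days.

## GV metric battery

Canonical internal unit: mg/dL; K = 18.016 mg/dL per mmol/L. All metrics run
on the trace at native cadence (interpolation is used only for meal matching
and windowing). Per metric:

| Metric | Definition | Units / conventions |
|---|---|---|
| mean, SD | arithmetic mean; sample SD (N−1) | mg/dL |
| CONGA | sample SD of G_t − G_{t−lag}, lag 60 min, pair tolerance ½ cadence | mmol/L |
| LI | Σ (ΔG_mmol)²/Δt_h over a 60-min grid, ÷ days of observation (span/24 h, floored at 1) | (mmol/L)²/h per day |
| J-index | 0.001 × (mean + SD)², mg/dL inputs | unitless |
| LBGI/HBGI | f(G) = 1.509[(ln G)^1.084 − 5.381]; r = 10f²; means of the low/high sides | unitless |
| ADRR | mean over days of (max low risk + max high risk); days with < 12 readings excluded | unitless |
| GRADE | mean of min(50, 425[log₁₀(log₁₀ G_mmol) + 0.16]²); readings ≤ 1 mmol/L excluded | unitless |
| MAGE | mean amplitude of excursions between alternating three-point turning points (plateaus collapsed) exceeding the whole-trace sample SD, both directions; 0 + flag when none qualify | mmol/L |
| MODD | mean \|G_t − G_{t+24h}\| over pairs 24 h apart (± ½ cadence) | mmol/L |
| M-value | mean \|10 log₁₀(G/120)\|³; no sparse-sampling range correction | unitless |

Notes. CONGA uses the original sample-SD definition; published software
variants differ, so cross-tool numerical identity is not claimed. The LI
day-normalization makes multi-day assessments comparable. MAGE has many
published variants; the turning-point rule above is fixed, documented and
oracle-tested rather than claimed identical to any specific tool. The M-value
range/20 correction targets sparse self-monitoring profiles and is omitted
for dense CGM series. Every metric is validated to 1e-9 relative against an
independent naive-loop implementation on 200 random traces, plus closed-form
fixed points (e.g. LBGI = HBGI = 0 at ~112.5 mg/dL, GRADE minimum at
4.918 mmol/L, J-index(100, 10) = 12.1).

## Glucotyping

Regular-grid traces are cut into overlapping 150-min windows at a 30-min
step (the 2.5-h window follows the glucotype literature); windows overlapping
gaps are dropped. Each window is reduced to four features — mean, SD, range,
max |rate| per hour. Spread features are log1p-compressed (they are strongly
right-skewed), all features standardized, and features whose spread is
negligible relative to their magnitude are left unscaled (standardizing by a
float-noise spread would amplify noise to unit variance). Spectral clustering
(RBF affinity with bandwidth = median pairwise distance, k = 3, seeded) is
fit on the pooled windows of the run — subsampled to ≤ 1200 windows to keep
the dense affinity matrix tractable — and clusters are labeled low/moderate/
severe by ascending centroid window-SD. All windows are then assigned to the
nearest centroid and each assessment is summarized by its class fractions.
The model is self-trained per run; its fractions are a parameterized
reconstruction, not numerically identical to any external tool's reference
clusters.

## Change scores and association

ΔLGE is in percentage points, Δweight in kg; GV changes are analyzed as
percent change 100 × (post − pre)/pre (undefined and flagged when pre = 0;
absolute changes are carried alongside). Per GV measure: Pearson's r with a
t-based two-sided p (n − 2 df), and OLS of ΔGV% on ΔLGE and Δweight with
intercept; adjusted R² = 1 − (1 − R²)(n − 1)/(n − 3); the per-10-pp effect
is 10 × the LGE coefficient. A constant weight column collapses the model to
the simple regression (whose coefficient p equals the Pearson p); collinear
designs raise. No multiple-testing correction is applied to the primary
p-values (exploratory design); Benjamini–Hochberg columns are emitted
alongside.

## Synthetic cohort generator

Each trace is `baseline + circadian + Σ meal responses + AR(1) noise`,
clipped at the 40 mg/dL sensor floor, on a 15-min grid:

* **Circadian**: sinusoid with amplitude 10 mg/dL, zero-crossings 09:00 and
  21:00, trough ~03:00 — so morning fasting glucose tracks the baseline
  (dawn-normalized).
* **Meal response**: linear rise over 30 min to an amplitude drawn around the
  participant's level (40–80 mg/dL band), exponential decay (τ = 60 min) —
  the simplest shape giving realistic postprandial excursions.
* **Noise**: stationary AR(1) (φ = 0.6, marginal SD 5 mg/dL) matching CGM
  autocorrelation qualitatively. The same fluctuation series drives meal
  scheduling and the emitted trace: the simulated eater responds to their
  actual glucose state, which is also what the sensor records.

Meals (2–6/day intended) are placed chronologically on daytime slots
(06:00–22:00, ≥ 30 min apart) so a later placement never perturbs an earlier
meal's preprandial value. With probability equal to the participant's LGE
propensity a meal goes to the eligible slot with lowest current glucose,
and only if that glucose is at or below the threshold (otherwise the intended
low-glucose meal is skipped — high-propensity eaters eat somewhat less
often); other meals land on random slots. Sub-25-kcal snack records (no
glucose excursion) are interleaved at a configurable rate (default 10%) to
exercise the energy filter. Fasting draws are baseline plus lab-assay noise
(SD 2 mg/dL).

Across assessments, week-16 propensity = week-0 propensity + U(−0.4, 0.4)
(clipped to [0, 1]); week-16 meal amplitude = week-0 amplitude +
`effect_size` × Δpropensity + N(0, 5) drift, planting a negative ΔLGE↔ΔGV
association at the default `effect_size = −40` mg/dL per unit propensity.
Defaults (17 participants, 7 days/assessment, baseline 97 ± 8 mg/dL, weight
92.5 ± 18.5 kg with −6.9 ± 4.2 kg change independent of LGE, propensities
0.05–0.6) emulate the target cohort's scale: simulated week-0 LGE ~30% and
thresholds in the 85–110 mg/dL band. The truth table records planted
propensities and amplitudes for parameter-recovery tests.

**What the simulator does not emulate**: glucose–insulin physiology,
meal-composition effects, sensor dropout beyond interpolation-gap handling,
circadian phase differences between participants, or the empirical joint
distribution of real CGM features. Passing recovery tests therefore shows the
*measurement and inference chain* is sound — not that effect sizes on real
cohorts would match. Simulated absolute metric levels (e.g. overall CGM mean
~106 mg/dL, since meal excursions ride on a 97 mg/dL baseline chosen to keep
fasting thresholds in the stated band) are order-of-magnitude realistic, not
calibrated to any particular cohort's printed values.

## Numerical and design choices

* Lag/grid pair matching uses a tolerance of half the cadence; distances on
  regular grids are exact multiples of the cadence, so ties cannot straddle
  the tolerance.
* Duplicate CGM timestamps keep the first occurrence (logged); unparseable
  or non-positive rows are dropped and counted.
* Monte-Carlo problem sizes: sign recovery uses 100 seeds × 40 participants ×
  4-day assessments with the J-index readout; slope recovery uses directly
  generated change scores at n = 200. Single-cohort demonstrations use the
  default 17 × 7-day configuration.
* Determinism: every stochastic component (simulator, spectral clustering,
  subsampling) is seeded; identical configurations produce byte-identical
  output files.

## Known limitations

* CONGA/LI/MAGE values are tool-variant-specific; comparisons across software
  should be qualitative.
* The glucotype model is pool-dependent (self-trained): fractions are
  comparable within a run, not across runs with different pools.
* The percent-change outcome scale makes measures with near-zero baselines
  (e.g. a severe-pattern fraction of 0) undefined for some participants;
  those rows are flagged and excluded from that measure's association.
* With very high LGE propensity the placement rule can yield assessments with
  few or (rarely) no usable events; such assessments are excluded by the same
  rules that govern real data.
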