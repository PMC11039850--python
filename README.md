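# lge-gv

Analysis pipeline linking changes in **low-glucose eating** (LGE) to changes
in **glycemic variability** (GV) measured by continuous glucose monitoring
(CGM), for two-timepoint cohort designs (e.g. pre/post a 16-week dietary
intervention in postmenopausal women without diabetes).

Low-glucose eating is a timed-eating behavior: eating when preprandial
glucose is at or below a personalized threshold derived from morning fasting
glucose. A participant's LGE score is

```
LGE% = 100 × (# included eating events with preprandial G ≤ threshold)
             / (# included eating events)
```

where the threshold is the mean of two morning fasting draws, eating events
come from timestamped food logs (records < 15 min apart are merged onto the
earliest timestamp, merged events < 25 kcal dropped), and each event's
preprandial glucose is the nearest CGM reading within ±5 min on a 5-min
interpolated grid. High within-day glucose fluctuation is an emerging risk
marker even without diabetes, and the package quantifies it with the classic
CGM battery — mean, SD, CONGA, LI, J-index, LBGI/HBGI, ADRR, GRADE, MAGE,
MODD, M-value — plus spectral-clustering *glucotypes* (fractions of time in
low/moderate/severe variability patterns). The analysis then asks whether
participants who increased LGE also reduced GV: Pearson correlations of
ΔLGE (percentage points) with ΔGV (% change), and OLS of ΔGV% on ΔLGE and
Δweight to show the association is independent of concurrent weight change.

A synthetic cohort generator (`lge_gv.synthetic_data`) produces CGM traces,
food logs and anthropometrics with a *planted* negative LGE→GV effect, so the
entire pipeline is testable end to end without participant data.

## Worked example

```python
from lge_gv import SimConfig, simulate_cohort, run_cohort

cfg = SimConfig(n_participants=17, days_per_assessment=7, seed=42)
cohort = simulate_cohort(cfg)
res = run_cohort(cohort.cgm, cohort.food_logs, cohort.anthropometrics,
                 glucotype_seed=42)

print("included:", int(res.inclusion["included"].sum()), "of", len(res.inclusion))
wk0 = res.measures[res.measures.week == 0]
print(f"week-0 LGE%  mean (SD): {wk0.lge_percent.mean():.1f} ({wk0.lge_percent.std():.1f})")
print(f"week-0 CGM mean mg/dL : {wk0.mean_mg_dl.mean():.1f}")
cols = ["pearson_r", "r_p_value", "effect_per_10pp", "adjusted_r2"]
print(res.associations.loc[["mean_mg_dl", "j_index", "lbgi", "frac_severe"], cols].round(3))
```

prints

```
included: 14 of 17
week-0 LGE%  mean (SD): 34.9 (18.9)
week-0 CGM mean mg/dL : 106.9
             pearson_r  r_p_value  effect_per_10pp  adjusted_r2
measure
mean_mg_dl      -0.636      0.015           -0.528        0.366
j_index         -0.718      0.004           -2.607        0.471
lbgi             0.129      0.660            0.556       -0.158
frac_severe     -0.687      0.014          -18.669        0.355
```

Three of 17 simulated participants fail the inclusion rule (≥ 3 valid days —
days with ≥ 2 matched eating events on plausible CGM — at both weeks).
Among the included, week-0 LGE averages ~35% of eating events. The change
scores show the planted pattern: participants who increased LGE lowered
their mean glucose, J-index and severe-glucotype time (negative Pearson r,
p < 0.05), with, e.g., a 2.6% J-index decrease modeled per 10-percentage-
point LGE increase after adjusting for weight change (`effect_per_10pp`).

The same pipeline runs from the shell:

```bash
lge-gv simulate --out sim/ --n-participants 17 --days 7 --seed 42
lge-gv run --cgm sim/cgm.csv --meals sim/meals.csv --anthro sim/anthro.csv --out results/
```

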