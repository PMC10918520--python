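# hydrascore

Diagnostic-accuracy analysis of the **WUT Venn diagram** — the
weight / urine colour / thirst composite used in sports science to screen
for dehydration in the field — against urinary and blood laboratory
reference standards, together with a synthetic-cohort generator that
reproduces the repeated-measures spot-sample study design the analysis
expects.

## The problem and the method

Athletes, soldiers and occupational workers need a cheap, equipment-free
way to judge hydration status. The WUT composite counts how many of three
self-assessable markers cross a dehydration threshold at a visit:

| marker | criterion |
|---|---|
| **W** — body-mass loss | BML > 1 % of the euhydrated baseline (strict) |
| **U** — urine colour | ≥ 5 on the eight-point colour chart |
| **T** — thirst | ≥ 5 on the nine-point Likert scale |

with BML = (baseline − BM) / baseline × 100 (loss-positive) and the
baseline the mean of a subject's three euhydrated first-morning body
masses. Two markers met reads as *likely dehydrated*, all three as *very
likely dehydrated*.

The composite is validated against three laboratory standards — urine
specific gravity (USG ≥ 1.020), urine osmolality (U_OSM > 700 mOsm/kg)
and plasma osmolality (P_OSM > 290 mOsm/kg). For each reference marker,
each threshold k ∈ {1, 2, 3} (test-positive: WUT count ≥ k) and each
timepoint/condition stratum the package builds the 2×2 contingency table
(positive class = reference-dehydrated) and computes

- sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV, NPV,
  with explicit `NA (reason)` handling of empty denominators,
- ROC operating points (1 − specificity, sensitivity) for the three
  thresholds with (0,0)/(1,1) anchors,
- a cut-off determination value: Youden J = sens + spec − 1 (maximised,
  default) or distance to the ideal corner (0,1) (minimised),
- practical-significance flags (metric above both the cut-off value and
  0.800).

High sensitivity means a negative composite rules dehydration **out**
(SnNout); high specificity means a positive composite rules it **in**
(SpPin).

Because subject-level data for such studies are rarely released, the
package ships a first-class synthetic cohort generator: 24 subjects
(half men, half women) × 2 conditions (free-living, then enforced
euhydration verified by a spot USG < 1.020) × 3 consecutive days ×
2 timepoints (first-morning fasted, mid-afternoon) = 288 visits, with a
latent per-visit dehydration state that drives all six markers
monotonically, and a stratified plasma-sample knockout
(6 + 4 + 4 + 3 = 17 visits) leaving 271 plasma-analysable records.

## Worked example

```python
from hydrascore import SimConfig, WUTAccuracy, simulate

visits = simulate(SimConfig(rng_seed=7))   # 288 visits, 271 with plasma
results = WUTAccuracy(visits).fit()
m = results.metrics
morning = m[(m.timepoint == "morning") & (m.condition == "both")]
print(morning[["marker", "k", "sensitivity", "specificity",
               "ppv", "npv", "cutoff_value"]].round(3).to_string(index=False))
```

prints

```
marker  k  sensitivity  specificity   ppv   npv  cutoff_value
   USG  1        0.957        0.678 0.361 0.988         0.770
   USG  2        0.870        0.901 0.625 0.973         0.770
   USG  3        0.696        0.942 0.696 0.942         0.770
  UOSM  1        0.933        0.711 0.459 0.976         0.644
  UOSM  2        0.700        0.904 0.656 0.920         0.644
  UOSM  3        0.633        0.965 0.826 0.909         0.644
  POSM  1        0.839        0.670 0.433 0.932         0.580
  POSM  2        0.677        0.903 0.677 0.903         0.580
  POSM  3        0.516        0.942 0.727 0.866         0.580
```

Read per row: of the morning visits that USG calls dehydrated, 95.7 %
meet at least one WUT marker (k = 1, high sensitivity — a WUT0 visit
rules dehydration out), while 90.1 % / 94.2 % of USG-euhydrated visits
stay below two / three markers (k = 2, 3, high specificity — WUT2/WUT3
rules dehydration in). The cut-off determination value (0.770 for USG,
Youden criterion) is the best sens + spec − 1 over the three thresholds,
attained at k = 2. `results.summary()` renders the full stratified
report, `results.category_table` the WUT0–WUT3 visit counts, and
`results.roc` the ROC points. In the enforced-euhydration strata USG has
no reference-positive visits, so its sensitivity is reported as
`NA (no reference-positive visits)` rather than a number.

The same pipeline is scriptable from the shell:

```bash
hydrascore simulate --seed 7 --out visits.csv
hydrascore score    --in visits.csv --out wut.csv
hydrascore classify --in visits.csv --out ref.csv
hydrascore evaluate --in visits.csv --out metrics.csv --roc roc.csv
hydrascore report   --in visits.csv
```

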