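# Methods

This note documents the models, parameter choices and numerical
conventions behind `hydrascore`, and what the synthetic cohort does and
does not emulate.

## The WUT composite and its comparators

Each visit is scored on three markers; a marker contributes 1 to the
WUT count when its threshold is crossed:

| marker | comparator | default | scale |
|---|---|---|---|
| body-mass loss (BML) | strictly `>` | 1.0 % | percent of baseline |
| urine colour | `>=` | 5 | 1–8 chart |
| thirst | `>=` | 5 | 1–9 Likert |

The comparator mix is deliberate and is asserted in the tests: colour 5
and thirst 5 are met, a BML of exactly 1.0 % is not.

**BML sign convention.** BML is reported *loss-positive*:
`(baseline − BM) / baseline × 100`. The conventional change formula
`(BM − baseline) / baseline × 100` yields negative numbers for losses,
which cannot be compared against a "> 1 %" loss criterion; we therefore
negate it and document the convention here and in the docstrings. A
negative `bml_loss_pct` means mass was gained.

**Baseline.** One baseline per subject: the arithmetic mean of the
euhydrated first-morning body masses (three in the reference design).
Fewer than three available visits produces a `low_n` quality flag rather
than an error, so free-living-only datasets remain scorable with an
externally supplied baseline. The baseline applies unchanged to
afternoon visits; afternoon body mass is confounded by food and fluid
intake, which is a known limitation of the W marker in afternoon
settings and is not corrected here.

## Reference standards

Dehydration calls: USG `>=` 1.020, urine osmolality `>` 700 mOsm/kg,
plasma osmolality `>` 290 mOsm/kg. The USG comparator is exposed in
`ReferenceThresholds.usg_comparator` because both the inclusive and the
strict convention circulate in the literature; the inclusive default is
consistent with the euhydration screen (USG < 1.020) used to verify the
enforced-euhydration condition, so the two rules partition the USG
range. Osmolality thresholds are interpreted as mOsm/kg, the unit an
osmometer reports. A missing plasma measurement propagates to a missing
call — reference values are never imputed.

## Diagnostic accuracy

Orientation: positive class = reference-dehydrated, test-positive =
`wut_count >= k` for k ∈ {1, 2, 3}. A visit whose reference call is
missing is excluded *for that marker only* (listwise per marker), so the
urinary tables keep full totals while plasma tables shrink by the number
of missed samples.

Sensitivity, specificity, PPV and NPV are simple count ratios; a zero
denominator yields an explicit undefined value with a reason (e.g. an
enforced-euhydration stratum has no USG-positive visit, so sensitivity
is undefined there), never a silent 0 or NaN. Undefined metrics are
surfaced in every output.

The three thresholds form a monotone ROC family — sensitivity
non-increasing and specificity non-decreasing in k, since the
test-positive sets are nested — with anchors (0,0) and (1,1). The
**cut-off determination value** summarises the family by one of two
standard rules, chosen per run and always echoed in the output:

- `youden` (default): maximise J = sensitivity + specificity − 1;
- `closest_to_01`: minimise the Euclidean distance to the corner (0,1).

Ties break toward the larger k, i.e. the more specific call. The
practical-significance flag marks a sensitivity or specificity that
exceeds both the stratum's cut-off value and 0.800 (configurable). The
flag rule compares the metric directly to the cut-off value as printed
reports in this field do; under the distance criterion the comparison is
less natural (small distances are good) and the flag should then be read
with care.

Default strata are the cells such studies report: each timepoint pooled
over conditions, each timepoint × condition, and the overall pool. Pooled
counts equal the sum of the constituent strata (tested).

## Synthetic cohort

The generator reproduces the *design geometry* of a repeated-measures
spot-sample study — 24 subjects (half men, half women), free-living then
enforced-euhydration conditions, three consecutive days each, morning
and afternoon visits, 288 in total — and a latent-state mechanism that
induces the cross-marker correlation the analysis assumes:

1. Per subject, a baseline body mass is drawn from the sex-specific
   normal (men 81.0 ± 15.9 kg, women 68.8 ± 15.2 kg; floored at 40 kg).
2. Per visit, a binary dehydration state `D` is drawn with probability
   `p_dehydrated[condition][timepoint]` (defaults 0.45/0.55 free-living
   morning/afternoon, 0.10/0.15 euhydrated — dehydration is rarer under
   enforced euhydration and rarest in euhydrated mornings).
3. A latent deficit `z = latent_deficit_scale · D + N(0, latent_noise_sd)`
   drives every marker linearly, `anchor + slope · z` plus Gaussian
   marker noise; body mass is `baseline × (1 − bml/100)` plus a 0.1 kg
   scale-measurement noise. Markers are then discretised to their
   instrument scales: colour and thirst to integers on 1–8 / 1–9, USG to
   3 decimals on [1.000, 1.040], osmolalities to integers.
4. Enforced-euhydration visits are rejection-sampled (state and panel
   redrawn) until the spot USG passes the euhydration screen
   (< 1.020), emulating the screen structurally rather than by shifting
   distributions.
5. Plasma osmolality is knocked out for a fixed count of visits per
   (condition, timepoint) stratum — defaults 6/4/4/3, i.e. 17 of 288 —
   chosen uniformly within stratum on a seed-derived RNG stream.

Anchors (euhydrated means) and slopes (shift per unit deficit) default
to conventional physiological values: USG 1.010 + 0.012·z, urine
osmolality 400 + 450·z mOsm/kg, plasma osmolality 285 + 8·z mOsm/kg,
colour 3 + 3·z, thirst 3 + 3·z, BML 0 + 1.8·z %. With the default scale
of 1, a dehydrated visit sits just past every dehydration threshold and
the default noise SDs (0.35 % BML, 0.004 USG, 120/3 mOsm/kg, 1 colour
step, 1.2 thirst steps) make the markers overlap realistically.
`strong_signal_config()` tightens the noise so every marker separates by
at least two SDs; the parameter-recovery tests use it to show the
pipeline recovers the expected pattern — WUT2/WUT3 highly specific
against all three references, WUT1 highly sensitive against the urinary
ones — from data where it is true by construction.

**What the generator does not emulate.** No physiological fluid-balance
dynamics (sweat rate, renal response), no within-day or within-subject
autocorrelation beyond the shared baseline mass, no food/fluid-log
behaviour, no menstrual-cycle effects, and marker panels are calibrated
to conventional values rather than to any observed cohort. Passing
tests therefore demonstrate correctness of the *pipeline* — counting,
thresholding, table-building, metric arithmetic — under a controlled
data-generating process, not field validity of the WUT tool itself.

## Numerical choices and degenerate inputs

- Determinism: all randomness flows from `rng_seed` through
  `numpy.random.default_rng`; the missingness knockout uses a stream
  derived from the same seed so generation and knockout are individually
  reproducible. Identical seed + config gives byte-identical CSV and
  report output.
- Rejection sampling is capped (10^5 draws per visit) and aborts with a
  clear error if the USG parameters make the euhydration screen
  unreachable.
- Empty strata produce zero tables with a warning, not an error;
  all-undefined ROC families give an undefined cut-off with a reason.
- Display rounding is 3 decimals in rendered reports only; CSV output
  keeps full precision. `usg` is written with 3 decimals and
  osmolalities as integers so round-trips are byte-stable.
- CSV is RFC 4180 UTF-8 with '.' decimals; missing plasma is an empty
  field.

## Problem sizes

The test suite and acceptance script run on the reference design (288
visits), a 576-visit strong-coupling cohort, a 1008-visit cohort for the
marker-monotonicity check, and batches of 25–110 randomised small
fixtures (3–60 visits) for the brute-force oracle comparisons; the whole
suite completes in well under a minute.

## Known limitations

- The W marker inherits the afternoon body-mass confound by design.
- The "WUT1 (combined with 0)" operating point is the k = 1 threshold of
  the nested family; the alternative {0,1}-vs-{2,3} dichotomy is the
  k = 2 threshold and is reported alongside, so both readings are
  available.
- The practical-significance flag's comparison of a proportion to a
  Youden-scale value is inherited from field reporting practice, not a
  statistical test; no confidence intervals or paired tests are
  provided.
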