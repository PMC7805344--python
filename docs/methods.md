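# Methods

## Decision problem

A single-site newborn screening program must decide whether to fund
metabolic gestational-age (GA) estimation — blood-spot analytes plus
clinical variables — over a basic algorithm using clinical variables alone,
for two outcomes: identifying preterm infants (ultrasound GA < 37 weeks)
and identifying small-for-gestational-age (SGA) infants (birthweight below
the 10th percentile at GA). Outcomes are counted, not converted into QALYs
or DALYs; the perspective is governmental, and patient or research costs
are excluded. Results are expressed per program year at the reference
volume of 1323 infants tested.

## Cohort representation and annualization

Every published annual count of the reference deployment is an exact
multiple of one third (55.3 = 166/3, 17.3 = 52/3, 249.3 = 748/3, ...). The
package therefore stores the cohort as an integer *pool* of raw event
counts equal to 3× the annual values, with `annualization_factor = 1/3`;
classifying the pool and scaling recovers every annual figure without
rounding error. The pool is organized in 100 g birthweight strata matching
the sequential analysis: fifteen bins from 2500 to 4000 g whose
preterm/correct counts come from differencing the published cumulative
window counts, plus open-ended low (`[1500, 2500)`) and high
(`[4000, 5000)`) bins holding the remainder (all out-of-window preterm
infants are below 2500 g; all are correctly identified by the basic
algorithm, 140 of 150 by the metabolic one).

Quantities the tables do not pin down are fixed once, by rule:

- **Suitable samples per bin** (3045 raw of 3969): apportioned
  proportionally to infants tested, largest-remainder rounding, as are the
  heel-prick/cord-blood labels (975:2070 among suitable samples).
- **True-SGA per bin** (748 raw): a stylized allocation concentrated at low
  birthweight — 250 below 2500 g, declining from 120 to 10 across
  2500–3300 g — as expected when SGA is a weight-percentile condition.
  Per-bin concordant counts are apportioned proportionally to true-SGA
  counts. Only the totals affect the deterministic results; the split
  affects bootstrap variance mildly.
- **Joint correctness** of the two algorithms within an infant is not
  published. The default assumes maximal overlap (the smaller correct set
  nested in the larger); `minimal` and `independent` are available, and the
  sensitivity of PSA intervals to this setting is exercised in the tests.
- **The low/high open bins** split the 681 remaining tested infants 600:81.

The fixture realizes strata as records with predicted GAs placed at
bin-interior values (preterm truth at 36.0 weeks, correct predictions at
36.5, incorrect at 38.5; SGA truth at 42.0 weeks with discordant
predictions at 32.0; plain term infants at 37.0) — only the side of each
threshold matters, and the builder verifies the placements against the
percentile table before emitting records. Two builds of the same spec are
byte-identical.

The 10th-percentile curve is a *synthetic*, stylized monotone table over
32–44 weeks (growth standards for SGA apply only above 32 weeks). It is not
a published fetal-growth standard — the analysis needs only a strictly
increasing boundary that separates the fixture's placement GAs, and any
real standard can be substituted via `PercentileTable`.

## Effectiveness rules

Preterm correctness requires ultrasound GA strictly below 37 weeks and a
predicted GA of *no more than* 38 weeks; the 38-week bound is inclusive by
default (`predicted_inclusive=False` gives the strict reading — the
packaged fixture is insensitive to the choice). SGA correctness is
concordance of predicted-GA and ultrasound-GA classifications, reported
with the true-SGA denominator (179.3 of 249.3 → 71.9%). Counts include
suitable samples only; missing predictions are not-evaluable rather than
wrong.

The sequential analysis anchors on a no-algorithm baseline of 142/3 ≈ 47.3
correctly identified preterm infants per annum — a model input, not derived
from the cohort (it is *not* the basic algorithm's full-cohort count of
55.3). A window strategy adds the in-window metabolic-minus-basic
increment; the all-infants strategy adds the increment accumulated at and
above 2500 g (`ALL_INFANTS_INCREMENT_FLOOR_G`), the convention under which
the published all-infants effect (59.3) and its ICER versus baseline
($8,336 = $100,031/12) are mutually consistent: below 2500 g low
birthweight alone flags the infant and the basic algorithm is the better
preterm classifier, so its classification is retained there.

## Cost model

Three tiers, all USD: one-time setup ($9,396 site + $11,069 central =
$20,465), volume-independent annual ongoing costs ($36,259; 63% site), and
a per-sample cost. The published per-sample mean ($48.19) is rounded and
does not reproduce the published annual totals (36,259 + 1323 × 48.19 =
100,014 ≠ 100,031); the default *exact-total* profile back-derives
per-sample = (100,031 − 36,259)/1323 ≈ $48.2034 so the totals are exact,
with the rounded figure available as the `printed` profile (totals then
agree to 0.5%, the tolerance used for window-cost comparisons). The
variable term scales with infants *tested* (back-calculation of the window
costs supports this over suitable samples). CAD→USD rates (0.75483 / 
0.77006 / 0.77178 for 2016–2018) are shipped for re-deriving components
from source ledgers, never applied on top of the USD means.

## Probabilistic sensitivity analysis

Clinical uncertainty: each of 5000 replicates draws one simulated program
year — `round(pool × annualization_factor)` = 1323 infants, with
replacement, from the per-infant pool — and counts the per-annum
metabolic-minus-basic differences directly on the resample. Resampling at
the annual scale (rather than resampling the full 3-year pool and
rescaling) is what gives effect intervals the width of one year's worth of
information; the pool-scale alternative understates the variance of an
annual count by a factor of 3 and is available via `resample_size`.
Unsuitable-sample infants are part of the pool, so the usable-sample count
varies across replicates.

Cost uncertainty: ongoing, per-sample and setup components are drawn
independently per replicate from gamma distributions moment-matched to
mean and SE = 10% of mean (shape = 100, scale = mean/100). Incremental
cost is `ongoing + 1323 × per_sample` (+ setup when included) — gamma
draws keep it strictly positive.

One seeded `numpy` generator drives everything; the three cost vectors are
drawn first, then bootstrap index rows in replicate order, so a fixed seed
reproduces the run exactly.

Intervals are bias-corrected (BC) percentile bootstrap:
z₀ = Φ⁻¹(fraction of draws below the point estimate), bounds at empirical
quantiles Φ(2z₀ ± z₀.₉₇₅). No acceleration term is used. Degenerate draw
sets collapse to a zero-width interval; tail fractions are clipped to
(1/2n, 1 − 1/2n) before the normal quantile.

Acceptability curves report `P(λ·ΔE − ΔC > 0)` on a willingness-to-pay
grid. Reported curves include setup costs by default (`include_setup`
switches the basis): with setup included the preterm curve crosses ~56% at
λ = $15,000, matching the published figure.

## Dominance and the frontier

Strict dominance: another strategy costs no more and achieves at least as
much, one inequality strict; exact cost-and-effect ties retain the narrower
window. Extended dominance: iterative removal of any interior strategy
whose incremental ICER exceeds the next one's — equivalently the
nondominated set is the lower convex hull of (effect, cost); excluded
strategies are reported against the final frontier members bracketing their
effect. Sequential ICERs between consecutive frontier members are strictly
increasing by construction. The implementation is verified against an
exhaustive hull-membership oracle on random instances.

## Problem sizes and numerical choices

The packaged analyses run at the study's own scale: a 3969-record pool,
5000 PSA replicates, strategy families of ≤ 30 windows. The full suite and
the acceptance script complete in seconds. Windowed cost comparisons carry
a ±0.5% tolerance (per-sample rounding, above); effect comparisons are
exact to the printed precision. ICERs with zero incremental effect are
undefined and returned as NaN rather than ±inf.

## Known limitations

- The fixture reproduces *marginal* counts; within-stratum structure
  (SGA×preterm co-occurrence, per-bin SGA allocation, algorithm-correctness
  overlap) is stylized where unpublished, and PSA interval widths inherit
  those choices. The spread across overlap settings is about one infant on
  the preterm CI bounds.
- The percentile table is synthetic; absolute SGA rates are meaningful only
  relative to it.
- Costs are single-site and volume-linear; no discounting, inflation
  adjustment, or patient/societal costs.
- The two algorithms' GA estimation itself is out of scope: predicted GAs
  enter only through their threshold classifications.
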