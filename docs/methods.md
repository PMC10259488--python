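# Methods

This note documents the models, definitions, parameters and numerical
choices behind `bottlechoice`, and what the synthetic data do and do not
establish.

## Behavioral metrics

The experiment is a continuous-access two-bottle choice task: a mouse lives
with two bottles, one holding vehicle (2% saccharine) and one holding
nicotine plus vehicle, with the nicotine concentration stepped up every
four days (10, 50, 100, 200 µg/ml after a 4-day water/water habituation)
and the drug bottle swapped to the other physical side every other day to
control for side preference. An automated system records the cumulative
volume drunk from each bottle every minute.

From the minute-resolution logs the package computes, per mouse and day:

* **drug / vehicle volume** — the increment of each bottle's cumulative
  volume over the calendar day (minutes `[1440·(d−1), 1440·d)`; a
  `day_offset_minutes` option shifts the boundary, default 0). Missing
  minutes mean "no drinking recorded"; a day with no samples at all is
  flagged missing and excluded from averages rather than imputed.
* **nicotine intake** (mg/kg/day) = `vol_drug_ml × conc_µg_per_ml /
  weight_g`. Weights are recorded every other day and carried forward (the
  first weight is carried backward); weights are stable enough over two
  days that a step rule is preferable to interpolation.
* **percent nicotine consumption** = `100 × vol_drug / (vol_drug +
  vol_vehicle)`, undefined (never 0 or 50) when nothing was drunk.

Condition summaries are unweighted means over the non-missing days of each
maximal run of equal concentration. The side-resolved components `%c1`
(drug on the left) and `%c2` (drug on the right) average only the days the
drug bottle sat on that side. Habituation days are assigned a *virtual*
drug side following the same alternation pattern (anchored to the first
drug day's side) so that water-vs-water points are well defined and side
relabeling remains an exact symmetry of every metric.

## Pseudo-ternary choice representation

For each mouse × condition, `a = min(%c1, %c2)` and `b = max(%c1, %c2)`
give a consumption index `x = (a+b)/2` and a side-bias index `y = b − a`.
A mouse avoiding the drug on both sides sits at (0, 0); one tracking it on
both sides at (100, 0); one drinking a single physical side has `b ≈ 100,
a ≈ 0` and sits at the top. Before computing Euclidean apex distances the
side-bias axis is multiplied by √3/2 so the three apices form an
equilateral triangle with side 100 and the three distances are on a common
scale. Whether to scale the axis before measuring distances is a free
choice; it is exposed (`side_scale`, default √3/2, alternative 1.0) and the
default is used everywhere in this package. Distances are plain Euclidean —
the minimal reading of "distance from the apices" — and two of them already
determine the point, which the tests exploit as a reconstruction oracle.

## Phenotype classification

"Avoider" and "non-avoider" are operationalized with four explicit
parameters (all config-exposed):

| parameter | default | role |
|---|---|---|
| `low_intake_ceiling` | 2 mg/kg/day | max daily intake below this ⇒ avoider (`low_intake`) |
| `noise_band` | 0.5 mg/kg/day | day-to-day changes within this band are noise |
| `quit_level` | 0.2 | post-drop intake must stay below this fraction of the pre-drop mean |
| `avoid_pct` | 20 % | a condition with mean percent consumption below this counts as avoided |

The ceiling is stated by the behavioral definition; the other three are
this package's choices to make a narrative definition reproducible. The
abrupt-drop rule requires (i) a consecutive-day decrease larger than
`noise_band` landing at, or within one day after, a concentration
increase — "abrupt" is anchored to transitions because that is where
aversion is triggered — and (ii) durability: every subsequent condition's
mean intake (over the post-drop days) stays below `quit_level` × the
pre-drop mean. Durability is evaluated on condition means rather than
single days so that one residual bout in an otherwise quit mouse cannot
flip the label. Low intake is checked before the abrupt rule, so a mouse
that both stays low and drops is labelled `low_intake` (rule precedence is
a package choice; the original narrative does not specify it). Non-avoiders
are `plateau` when the last two condition means agree within `noise_band`
(or when only non-durable drops occurred), else `monotone_increase`.

The aversion threshold of an avoider is the lowest concentration from which
every condition's mean percent consumption stays below `avoid_pct`.

Mice with a habituation side preference strictly below 20% or above 80%
(fraction of habituation fluid from one side) are excluded before
classification; the boundaries themselves are kept, per the printed strict
inequalities.

## Evoked-response quantification

**Puff-evoked currents** (voltage clamp at −60 mV, 30 µM / 200 ms local
puff): baseline is the median current over the 1 s before the puff;
the response is the minimum of the box-smoothed current (5 ms) within 3 s
after the puff; amplitude = baseline − minimum, reported as a positive
magnitude (the "−pA" convention for inward currents). The window and
smoothing are this package's defaults, chosen from the transients' time
scale (50 ms rise, 500 ms decay), and are config-exposed. Smoothing
prevents single-sample noise extremes from inflating the peak; the
significance gate compares the amplitude against 3× the *raw* baseline SD,
which keeps a flat noisy trace at amplitude 0. Adding a constant offset to
a trace provably leaves the result unchanged.

**Peri-injection firing-rate changes** (in vivo, 5 min baseline before an
i.v. injection): baseline rate = count/300 s; the post-injection rate is
binned at 10 s over 180 s and smoothed with a 3-bin moving average, and the
response is the smoothed extreme deviating most from baseline, expressed as
% of variation from baseline. Direction (activated/inhibited) is asserted
only beyond 2 SD of the (equally smoothed) baseline bins. The smoothing is
load-bearing: the raw extreme of skewed Poisson count bins is biased upward
by several percent even for a perfectly stable train, while the smoothed
estimator is centered on zero (tested at 5 Hz over 200 replicates). The
flip side is mild attenuation and extreme-statistic inflation for genuine
transient responses (a programmed doubling reads back as ≈ +100 to +115%);
estimates should be compared between groups quantified identically, which
is how they are used. A silent baseline leaves the percent change
undefined and flagged.

**Covariate regression** is ordinary least squares of a response on a
covariate (optionally log10-transformed, as for the dose–current relation),
computed per mouse — neuron-level values are averaged within mouse first,
and shuffling neurons within a mouse leaves the result unchanged. The
output satisfies `F = R²/(1−R²)·(n−2)` and
`adj R² = 1 − (1−R²)(n−1)/(n−2)` exactly. A published value of
F(1,12) = 12.45 with R² = 0.47 at n = 14 is internally consistent only if
the printed R² is the *adjusted* one (the raw value would be
F/(F+12) ≈ 0.509); the package computes and reports both and does not guess
the original convention.

## Statistical toolkit

All tests are two-sided. The Mann-Whitney U test uses the exact null
distribution (count recursion) for tie-free samples with n₁·n₂ ≤ 400, else
a normal approximation with tie and continuity corrections. The "paired
Mann-Whitney" of the behavioral literature is implemented as the Wilcoxon
signed-rank test (zero differences dropped; exact for n ≤ 25 without tied
|differences|). The Friedman statistic uses the chi-squared approximation
with tie correction (df = k−1, no missing cells allowed). Holm-Bonferroni
is the step-down adjustment with monotonicity enforcement, applied within
declared test families. The 2×2 chi-squared applies the Yates continuity
correction floored at zero so near-balanced tables cannot be
over-corrected. Enumeration and scipy serve as independent oracles in the
tests; the implementations themselves are self-contained.

Applying the floored-Yates formula to the avoider-proportion table
((17, 18) vs (0, 13)) gives χ² ≈ 7.77, p ≈ 0.0053. The published value for
this comparison is p = 0.04, which the standard formula does not reproduce;
the package reports its own computed value and flags the discrepancy
instead of matching the printed number.

## Synthetic cohort generator

Each bottle is an independent marked point process: bout onsets Poisson
within each day, bout volumes gamma. Defaults: 180 bouts/day across both
bottles, mean bout 5/180 ml (gamma shape 8, so a mouse drinks ≈ 5 ml/day
with a day-to-day coefficient of variation of ~3% in total volume and ~11%
per bottle), body weight ≈ 25 g (SD 0.8 g across mice) drifting as a slow
random walk and recorded every other day. Archetypes:

* **tracker** — 62% of bouts follow the drug bottle; volume is
  concentration-independent, so intake scales with concentration
  (≈ 24.8 mg/kg/day at 200 µg/ml).
* **side_biased** — 95% of bouts on one physical side (4.5 ml/day), so the
  drug is consumed passively on the days it sits there (condition mean
  ≈ 18 mg/kg/day at 200). Habituation bias is kept at 68% so these mice
  pass the <20%/>80% screen, as the included side-biased animals did.
* **plateau** — a titrator: above a per-mouse knee (≈ 90 ± 8 µg/ml) the
  drug-side bout rate scales as `(knee/conc)^e` (e = 1), pinning the dose
  near `0.55 × 5 × knee/25 ≈ 10 mg/kg/day`.
* **avoider_abrupt** — tracker-like (p = 0.55, 4.6 ml/day) until the
  concentration reaches a per-mouse threshold; from the next day the
  drug-side bout rate and bout size collapse (×0.015, 8 µl bouts) and stay
  collapsed, with drinking re-routed to the vehicle bottle.
* **avoider_low** — constitutively tiny drug-side drinking
  (≈ 0.09 ml/day ⇒ intake never approaches 2 mg/kg/day).
* **minipump archetypes** — for the single-step (habituation → 100 µg/ml)
  protocol after chronic subcutaneous pretreatment: per-day drug-bottle
  preference profiles (saline-pretreated: 35→22→18→17%, abrupt avoidance;
  nicotine-pretreated: 50→44→38→33%, gradual decline).

The reference cohort fixes the mixture at 6 trackers + 5 side-biased +
7 plateau (18 non-avoiders) and 13 abrupt avoiders (8 triggered at the
100→200 step, 2 at 100, 2 at 50, 1 at 10 µg/ml) + 4 low avoiders
(17 avoiders). Calibration is by analytic moment matching of condition
means to the published group values (avoiders ≈ 2.6 and non-avoiders
≈ 16.9 mg/kg/day at 200 µg/ml; population intake ≈ 10 mg/kg/day; minipump
cohorts ≈ 23.0% and ≈ 41.2% at 100 µg/ml) — the raw per-animal
distributions are not available, so no fitting is involved. All randomness
flows from one seeded generator (documented default seed 20230530 for the
reference cohort), and equal seeds give byte-identical cohorts.

Synthetic electrophysiology: puff currents are double-exponential
transients (50 ms rise, 500 ms decay) on a −20 pA holding level with 5 pA
Gaussian noise; per-neuron peak amplitudes are lognormal with the group
mean set to the published value (e.g. 254.64 pA for the avoider group,
401 pA for saline-minipump animals) and an across-neuron SD of 80 pA. The
published sem × √n would imply a much wider spread (CV ≈ 1), under which a
group of a few dozen neurons cannot pin its own mean; the narrower spread
is a deliberate generator property so that group-mean recovery at the
published group sizes is a meaningful closed-loop test of the extraction
code. Spike trains are inhomogeneous Poisson (thinning) with an
alpha-shaped post-injection excursion peaking 40 s after the injection.

### What the synthetic data do not show

The generator reproduces the *structure* the analysis assumes — bout-level
drinking, archetypal strategies, transition-anchored collapse, calibrated
group means — not the full richness of real behavior. Known gaps: no
circadian structure within the day; day-to-day intake is conditionally
independent given the archetype state (no autocorrelated motivation), so
real non-avoiders' strictly-positive consecutive-day minimum differences
are only approximated here (side-biased mice swing with every bottle swap
and noisy trackers dip below zero; the classifier therefore leans on
transition anchoring and durability, not on the sign of the minimum alone);
avoiders and non-avoiders separate slightly earlier (at 10–50 µg/ml) than
the published groups, whose intakes were statistically indistinguishable at
low concentrations; and the quinine control is representable only as
another schedule, not as a distinct taste model. Passing the closed-loop
tests shows the pipeline recovers known ground truth under these
assumptions; it does not validate the assumptions against real mice.

## Problem sizes and runtimes

The test suite simulates the 35-mouse reference cohort once per session
plus ~400 small single-mouse cohorts for the recovery study, and runs in
well under a minute on one CPU; the acceptance script generates the
reference cohort and one 25-mouse minipump cohort and finishes in a few
seconds. These sizes match the published cohorts; nothing is scaled up
beyond them.
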