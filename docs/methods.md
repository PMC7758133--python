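# Methods

## Grading model

Each eye receives an ICDR severity grade (`none < mild < moderate < severe
NPDR < PDR`) and a DME grade (absent/present); grading is all-or-none per
eye, so an ungradable photograph yields neither. Patient-level labels:

- **Category** — if either eye has DME the patient is `dme`; otherwise the
  worse eye's severity maps to the `*_no_dme` categories. The six gradable
  categories partition gradable patients.
- **STDR** — severe NPDR, PDR or DME (i.e. the categories `severe_no_dme`,
  `pdr_no_dme`, `dme`). Moderate NPDR is *not* referable.
- **Ungradability** — both eyes ungradable, or one eye ungradable *and* the
  fellow eye not STDR on its own. The second clause is a conjunction by
  design: a unilateral ungradable photograph cannot hide absence of disease,
  but an STDR fellow eye settles the patient label regardless, so such
  patients remain gradable. Missing photographs are encoded as ungradable
  eyes; both are exclusion paths and nothing downstream distinguishes them.
- A gradable-severity/ungradable-DME mix within one eye is rejected at
  construction. Real data may contain such eyes; a caller must resolve them
  (for example to a fully ungradable eye) before analysis.

These rules make patient STDR provably equivalent to "some gradable eye is
STDR", which the test suite checks by exhaustive enumeration over all
11 × 11 eye-state pairs.

## Two-round simulation

The study design: all includable patients (graded by the reference standard,
DL and HG, none of them finding the patient ungradable) are screened by an
arm's modality; screen positives are overread by retina specialists; exactly
the *confirmed* STDR cases (the true positives) are referred out. False
positives remain in the program. The follow-up cohort removes the referred
set and dropouts, then the second screening repeats the first.

Dropout is an attribute of the data, not a stochastic process, in the
analysis path (the generator owns the stochastic version). A non-referred
patient drops before round 2 if:

1. they have no round-2 data at all;
2. either modality's round-2 data is missing — this removes the patient
   from **both** arms (the program cannot follow a patient one modality
   failed to photograph);
3. the round-2 reference assessment is ungradable (both arms); or
4. the round-2 assessment by the arm's own modality is ungradable (that
   arm only — the other arm keeps screening the patient).

The hybrid of shared (1–3) and per-arm (4) rules is forced by the published
aggregates: with a fully shared dropout set, the difference between the
arms' surviving false negatives is fixed at 35 by the dropout counts
(921/956) but at 78 by the round-2 STDR counts (211/289) — a contradiction.
Rule 4 is the per-round application of the study's entry criterion
("excluded if the reference standard or either grader found the images
ungradable") and resolves it.

Invariants asserted on every run: round-2 cohort + referred + dropout equals
the round-1 cohort, and (on synthetic data, where truth is logged) round-2
reference STDR equals surviving round-1 false negatives plus incident STDR
among survivors.

## Statistical conventions

- **Confidence intervals**: Wald (normal-approximation) binomial intervals,
  z = Φ⁻¹(0.975) for the default 95% level, clipped to [0, 100]%. Chosen
  because they reproduce all twenty published interval bounds to two
  decimals (e.g. 669/704 → 93.42–96.63); Wilson or exact intervals do not.
- **Between-round tests**: Pearson chi-squared on the metric's 2×2
  (numerator vs complement, round 1 vs round 2), one degree of freedom,
  **no** continuity correction — this reproduces the published p = 0.008
  for the DL sensitivity comparison and every "< 0.001" entry. Caveat 1:
  the rounds are treated as independent samples although the round-2 cohort
  is a subset of round 1; this mirrors the reference analysis and slightly
  misstates the variance of the difference. Caveat 2: the reference
  report's *non-significant* p-values (e.g. 0.742, 0.318) differ from
  Pearson-no-correction in the second decimal (we obtain 0.723, 0.339);
  no standard variant we tried reproduces them, so only the headline values
  are pinned by tests.
- **Rounding**: estimates are computed unrounded; two-decimal, half-up
  formatting happens only in the rendering layer, and comparisons always
  use unrounded values.
- **Stratified incidence**: denominators are patients non-STDR at round 1
  per the reference standard with a gradable reference assessment at round
  2, binned by baseline reference severity. The `detection_source` argument
  selects *whose round-2 STDR call* is counted in the numerator (reference
  standard, DL, or HG); patients without a usable grade from that source
  count as not detected. The detected counts for DL/HG can exceed the
  reference count because they include round-2 false positives, and can
  include patients outside that arm's analysed cohort (e.g. dropped for the
  *other* modality's missing data).
- **Sample size**: n = ⌈z²·p(1−p)/(m·p)²⌉ for estimating a prevalence p to
  a *relative* margin m (default 10%) at α = 0.05. At p = 6.5% this gives
  5,526. The reference design states "no less than 5,530" and also names a
  type-2 error, which has no role in a pure precision calculation; the
  implementation keeps the closed form and does not force 5,530.

## Synthetic cohort generator

Per patient: a baseline category from `baseline_probs`; a latent difficulty
u ~ Uniform(0, 1), constant across rounds and shared by both modalities
(difficulty is a property of the case, not the grader — required for the
arms to show correlated enrichment); a round-2 true category from the
transition row of the baseline category (no regression to milder disease:
non-referred patients are untreated); demographics drawn to match the
reference cohort's moments (age 57.27 ± 10.44 y, 68.8% female, 67.9%
hypertension, FBS 151.26 ± 52.83 mg/dL — cosmetic, uncorrelated with
disease).

Detection model, per modality and round: a true-STDR patient is called
positive with probability `base_sens(subtype) − difficulty_weight · d`,
clipped to [0, 1], where d = u for prevalent STDR and
`d = min(1, u + incident_difficulty_boost)` for STDR that is incident at
round 2 — new-onset disease is subtler than established disease, which is
the second half of the spectrum-shift mechanism. With the calibrated
defaults the spec's literal constant-difficulty model would predict a
round-2 sensitivity drop of well under one percentage point for a
high-sensitivity screener, an order of magnitude below what repeat
screenings actually show; the boost term closes that gap while vanishing
exactly when `difficulty_weight = 0` (the null case: errors independent of
the case, no enrichment, no drop). A non-STDR patient is called positive
with probability `(1 − base_spec) × fp_moderate_boost` if moderate NPDR,
`(1 − base_spec)` otherwise.

Eye-level grades are derived *after* the patient-level draw: the worse eye
carries the category, the fellow eye shares the STDR finding with
probability `eye_concordance` (default 0.25 — most STDR presents
asymmetrically; uncalibrated, as the reference data publish no eye-level
concordance). A detected patient's modality grades mirror the true STDR
eyes; a missed STDR patient reads as moderate NPDR; an over-called patient
reads as DME. This guarantees patient-level calibration (what the study
reports) and makes eye-level sensitivity equal the patient-level detection
probability.

Ungradability is drawn independently per modality per round
(`ungradable_rate`, default 0.005 — the round-1 rate is a free parameter:
the reference cohort is defined *after* baseline exclusions, so nothing
calibrates it); `dropout_rate` (default 0.17) removes both modalities'
round-2 data, giving expected per-arm attrition
1 − (1−0.17)(1−0.005)² ≈ 0.18, matching the observed 921/5,069.

Calibrated defaults (`paper_default_config`): baseline mix equal to the
reference round-1 severity margins (72.36% no DR … 11.35% DME; expected
prevalence 12.27%); transition rows with STDR mass 0.0172 / 0.0856 / 0.2526
from none / mild / moderate and incident subtype split 91% DME, 6% PDR, 3%
severe; DL `base_sens = 1.0`, `difficulty_weight = 0.10` (mean sensitivity
0.95), `base_spec = 0.992`, `fp_moderate_boost = 27.5` (expected
specificity ≈ 0.980, ~63% of false positives moderate); HG
`base_sens = 0.98`, `difficulty_weight = 0.48` (mean 0.74),
`base_spec = 0.988`, `fp_moderate_boost = 4` (≈ 0.986, ~20% moderate). All
operating points were set analytically from the closed-form expectations in
`synthcohort` (also exposed as `expected_round1_*`, the oracles the
parameter-recovery tests check against).

Reproducibility: every random variable has its own named child stream of
the seed and patient *i* consumes element *i*, so a cohort is bit-identical
for a fixed (config, seed) and growing `n_patients` never reshuffles
earlier patients.

What the generator does **not** emulate: image content and camera effects;
correlation of demographics with progression; regression under treatment;
new diabetics entering the program between rounds (~5% in practice);
eye-level severity discordance structure beyond the single concordance
probability; grader-specific category confusions (errors are generated at
the STDR/non-STDR level). Passing tests therefore demonstrate the
referral/enrichment mechanism and the pipeline's correctness, not
image-level realism.

## Benchmark cohort

`retscreen.benchmark` builds a deterministic 5,738-patient cohort by direct
integer bookkeeping from the published flow, contingency, severity-margin
and progression counts; individual rows are synthetic and only the margins
are constrained. Joint distributions the publication does not determine
(e.g. which HG false negatives were DL true positives, or the overlap of
round-1 and round-2 false positives) are fixed by simple conventions noted
in the builder. The seed affects only demographics and row order.

## Numerical and degenerate-input choices

Zero-denominator metrics raise (`UndefinedMetricError`) rather than return
0; chi-squared with a zero margin raises; Wald bounds are clipped; interval
level and probability parameters are validated at construction; transition
rows must be row-stochastic to 1e-12 before any draw. Ties in the severity
order cannot occur (the scale is a total order).

## Problem sizes

The test suite and acceptance script use the study's own scale: the
5,738-patient benchmark; 50 replicates of 5,738 patients for the
spectrum-shift experiment; 100,000 patients for parameter recovery; 200,000
for the transition-rate check; 1,000 random tables for the chi-squared
oracle. These sizes put Monte-Carlo standard errors well below every margin
being tested while keeping a full run in tens of seconds.

## Known limitations

- The between-round chi-squared inherits the reference analysis's
  independence approximation (see above).
- The reference report states 11 DL false negatives at the second screening
  in its narrative but 21 in its contingency table; this package follows
  the table, so the narrative's companion figure (64% of those FNs being
  DME) is not reproducible from it.
- Only two rounds are calibrated and exercised end-to-end, although the
  round loop itself is generic.
- The generator's round-1 ungradability rate and eye concordance are
  uncalibrated free parameters.
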