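# Methods

`pdcgrowth` implements a growth-monitoring decision-support algorithm for
paediatric development clinics (PDCs) — follow-up programmes for high-risk
infants (preterm, low-birthweight, or with other perinatal complications) —
together with the evaluation machinery used to audit how well clinic nurses
record and interpret growth assessments, and to estimate the effect of a
workflow intervention on those outcomes with a difference-in-difference
design.  This note documents the models, rules, parameters and design
choices; everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`, not asserted from memory.

## 1. The LMS reference engine

Growth standards are stored as LMS tables: for each value of an index
(age in days, or length/height in cm for weight-for-length), a Box-Cox
power `L`, a median `M` (kg or cm) and a coefficient of variation `S`.
A measurement `y` maps to a z-score by

    z = ((y/M)^L - 1) / (L*S)      (L != 0)
    z = ln(y/M) / S                (L == 0)

and back by `y = M*(1 + L*S*z)^(1/L)` (or `M*exp(S*z)`).  The engine:

* interpolates `(L, M, S)` **linearly** between adjacent table rows and is
  exact at the knots — the convention of the standard WHO analysis macros;
  no spline fitting;
* applies the **restricted adjustment** to weight-based indicators
  (weight-for-age, weight-for-length/height) only: beyond |z| = 3 the score
  is extended linearly in measurement units between the 2-SD and 3-SD
  curves, `z* = 3 + (y - SD3)/(SD3 - SD2)` above and the mirror image
  below.  Length/height-for-age always uses the raw transform;
* round-trips `zscore(inverse_zscore(z))` to better than 1e-9 over
  `z ∈ [-6, 6]` and the parameter ranges of real growth tables (the
  acceptance script reports the worst observed error, ~1e-14).

Reference files are plain delimited text (tab or comma), columns
`sex | index | L | M | S`, sex coded `1/2` or `m/f`; the loader is agnostic
to table granularity (daily or monthly rows).  The package bundles a
**synthetic** reference set — smooth invented curves with realistic
magnitudes (birth weight ≈ 3.4 kg, birth length ≈ 49.9 cm) — so the whole
pipeline runs self-contained; real WHO 2006 files are drop-in
replacements.  The synthetic curves are labelled as such everywhere and are
not a substitute for the WHO standards in any clinical sense.

Units: weights are grams in files and record objects (as EMRs store them)
and kilograms inside the reference layer; lengths are cm; ages are days.
One month = 30.4375 days wherever month-valued thresholds or target ages
must be converted.

## 2. The clinical assessment layer

**Corrected age.** Chronological age minus the days born early, where days
born early = `round(7 * (40 - GA))` for documented gestational age
GA < 37 weeks.  Corrected age may be negative (a very preterm infant seen
before term-equivalent age).  A child is *preterm* if GA < 37 weeks or GA
is missing but the child was referred as preterm; in the latter case
corrected age falls back to chronological age and carries a
`correction_unavailable` flag.  Such children still count in the
corrected-age completeness denominator.  Ages are kept in days throughout;
no rounding to completed weeks.

**Risk flags.** Low birthweight: birthweight < 2500 g.  Small-for-
gestational-age: birthweight below the 10th percentile for gestational age
and sex, via a user-supplied percentile table (the interface interpolates
linearly in GA); the bundled table is synthetic and test-only.  Missing
inputs propagate as missing.

**Interval growth.** `(weight_now - weight_prev) / days_between` in g/day,
signed, where the previous weight is the child's most recent *earlier*
visit with a recorded weight (not necessarily the previous visit row).

**Classification rules** (the decision layer the tool automates, with
traffic-light colours green/yellow/red):

| indicator | normal | moderate | severe | not applicable |
|---|---|---|---|---|
| L/HFA z | ≥ −2 | < −2 and ≥ −3 | < −3 | corrected age < 0 d, or length < 42 cm |
| WFL/H z | ≥ −2 | < −2 and ≥ −3 | < −3 | length < 45 cm, corrected age < 0 d, or weight < 1.6 kg |
| WFA z | ≥ −2 | < −2 and ≥ −3 | < −3 | corrected age < 0 d, or weight < 1.4 kg |

Interval growth is *adequate* at ≥ 20 g/day under 3 months corrected age,
then ≥ 15 (3–6 mo), ≥ 10 (6–8 mo), ≥ 6 (8–12 mo), ≥ 5 (12–16 mo) and
≥ 4 g/day (16–24 mo); *not applicable* at ≥ 24 months, below 0 days
(the bands are undefined there), or when the prior weight is missing.

Numerical conventions: the not-applicable conditions are checked before
the z value; boundaries are closed below (z = −2 is normal, z = −3
moderate; a rate exactly at a band threshold is adequate; corrected age
exactly 24 months is not applicable).  The bands partition [0, 24) months
with half-open intervals.  When no NA condition holds and the z-score
cannot be computed (missing measurement, index outside the reference
span), the classification is undefined rather than coerced — downstream
audits treat that as "insufficient data".

**Implausibility.** A visit measurement is implausible when its raw
(unrestricted) z-score lies beyond ±5; flags are kept per indicator.  The
ingest layer logs such rows as probable data-entry errors but never drops
them — the audit and outcome rules decide their fate.

## 3. Completeness and concordance audits

Visits are cross-classified into four exposure groups (control vs
intervention arm × pre vs post calendar period).  The study calendar
defaults to pre = 2017-08-01..2018-01-31 and post = 2018-08-01..2019-01-31;
both windows are configurable.  Cohort filters drop orphan visits, visits
outside the calendar and *contaminated* visits — post-window visits of
children who enrolled in the pre period, whose treatment simply continued.

**Completeness** is the share of visits where the nurse recorded each item:
weight, length, corrected age (denominator: preterm-child visits only),
the three categorised z-scores, and interval growth (complete whether
recorded as a category or as a continuous g/day rate).  "Not applicable"
entries count as complete.  Percentages are half-up-rounded to integers,
the presentation convention of clinical audit tables.

**Concordance** compares each nurse-recorded category with the
gold-standard classification recomputed from the raw measurements.  The
denominator per metric is the set of nurse-assessed visits.  A record is
discordant when (1) the category does not match the recomputed one, (2)
the raw data needed to validate it are missing or out of reference range
("insufficient data" — operationalised as: the gold classification is
undefined), or (3) for z-score metrics, the raw measurements are
implausible (±5 SD, evaluated on the unrestricted z) — rule 3 fires even
when the recorded category happens to agree.  A nurse "not applicable"
matches exactly when the gold NA condition holds.  A continuous interval-
growth entry matches when classifying *that number* against the child's
age band yields the gold category; no numeric tolerance is applied.
Each child's first visit is excluded from interval-growth concordance only
(no prior weight exists in the record system).

An optional config flag restricts the L/HFA metric to standard
growth-assessment visits from a cutover date onwards (a recording-practice
change); it is off by default.

## 4. Child-level outcomes at 2 and 6 months

For children enrolled before 2 months corrected age, the visit closest to
the target corrected age (2 or 6 months; months of 30.4375 days) within
±1 month qualifies; ties between equidistant visits go to the earlier
visit date, making selection order-independent.  Stunting, wasting and
underweight are L/HFA, WFL/H and WFA z < −2 at that visit; inadequate
interval growth is the band rule.  Children with no qualifying visit, an
undefined or not-applicable classification, or implausible measurements
are missing for that indicator and leave its denominator.

The outcome analysis keeps visits dated *between* the windows: the record
system is continuous, and a pre-window enrollee reaches 6 months corrected
age during the gap.  A child's exposure group is their arm crossed with
the care regime they enrolled under — "pre" for enrollment up to the end
of the pre window, "post" afterwards (the rollout happens right after the
pre window closes, so gap enrollees are followed under the new regime and
reach their target ages during the post window).  Contamination filtering
already removed pre-enrollees' post-window visits.

## 5. Difference-in-difference estimation

Binary outcomes are fit by OLS (a linear probability model) so
coefficients read as percentage-point effects:

    E[y] = b0 + b1*intervention + b2*post + b3*(intervention × post)

`b3` is the DiD estimate; in the saturated model it equals the four-cell
closed form `(p_I,post − p_I,pre) − (p_C,post − p_C,pre)` exactly (checked
to 1e-10).  Standard errors are cluster-robust over facilities with the
CR1 small-sample factor `G/(G−1) · (n−1)/(n−k)`; two-sided p-values use a
t reference with `G−1` degrees of freedom — the convention of Stata's
`cluster` option, pinned explicitly in our code rather than inherited from
library defaults (the statsmodels sandwich is cross-checked against a
hand-rolled CR1 oracle in the tests).  A facility-type (hospital vs health
centre) adjustment is available as a sensitivity analysis.  Fits require
at least two clusters and all four design cells non-empty; constant
outcomes yield an undefined p-value rather than a spurious zero.  The test
suite documents (not fixes) the usual LPM/cluster small-sample behaviour:
under a true null with facility random intercepts and 20 clusters, the
nominal 5% test rejects at roughly 3–9% over 1000 replicates.

## 6. The synthetic EMR generator

The generator produces children/visits tables in exactly the dialect the
ingest layer reads, plus a truth table carrying the generating labels.
It emulates:

* **Enrollment**: four cells of `n_children_per_cell` (default 220, ~880
  children and ~2100 in-window visits — the scale of a two-district PDC
  programme over two 6-month windows).  "Pre" children enrol during the
  pre window; "post" children enrol anywhere from the end of the pre
  window to the end of the post window, because children enrolling between
  the windows are exactly those who reach their target ages during the
  post window.
* **Case mix**: 57% preterm; gestational age truncated-normal (33 ± 2.5
  weeks preterm, 39 ± 1 term, charted to 0.1 weeks); birthweight normal
  with mean `3300 − 170·(40 − GA)` g, SD 350 g; 6% of records missing GA.
* **Visit process**: the standard PDC schedule (1, 2, 3 weeks; 1, 2, 4, 6,
  9, 12 months), laid out on *corrected* age for preterm infants (high-risk
  follow-up is scheduled on corrected age; this also makes target-age
  visits attainable for them), ±3 days of calendar jitter, attendance
  probability 0.65, 8% urgent-care ("other") visits.  Late visits of
  pre-window enrollees spill into the post window, generating the
  contaminated visits the filters must drop.
* **Latent growth**: per-child L/HFA and WFA z intercepts ~
  Normal(−2.0, 1.1) and Normal(−1.8, 1.1) — roughly 50% stunting/45%
  underweight at baseline, the malnourished case mix of such programmes —
  with AR(1) visit-to-visit noise (ρ = 0.7, marginal SD 0.35, growth
  "tracking").  True measurements come from inverting the LMS reference at
  the visit's corrected age; recorded values add measurement noise (30 g,
  0.4 cm).  A per-cell z shift (default +0.45 in intervention-post, −0.2
  in control-post, applied to visits dated in the post window) builds in a
  nutrition improvement with the lag such interventions show.
  Weight-for-length is *implied* by the simulated weight and length rather
  than drawn separately, so its marginal distribution is narrower than
  field data (simulated wasting prevalence runs below typical field
  levels); audits are unaffected because they compare nurse entries with
  classifications recomputed from the same recorded measurements.
* **Nurse behaviour**: per-cell, per-metric completion probabilities
  (defaults span 0.06–1.0, patchiest for corrected age) and
  misclassification probabilities (0.10–0.36); misclassified entries draw
  uniformly from the wrong categories.  30% of recorded interval-growth
  entries are continuous (uncategorised) rates; a misclassified continuous
  entry is reflected across the band threshold.  Implausible data-entry
  errors (weight × 4) occur with probability 0.003.  These defaults are
  chosen once for realism — completion and agreement in the 60–90% range,
  improving in the intervention-post cell — and are emulation targets,
  not authoritative reproductions of any particular programme's figures.

Determinism: one `SeedSequence` per run is spawned into per-child streams
in a fixed order, so output is byte-identical for a fixed seed and
insensitive to nothing but the seed and config.

What passing tests on synthetic data do and do not show: they demonstrate
that the audit and DiD machinery recover known generating parameters
(completion, misclassification, interaction effects) under the stated
models — independent Bernoulli recording, AR(1) Gaussian growth, additive
facility effects.  Real EMR data have feature the generator omits:
correlated missingness across fields, transcription-error structure beyond
the ±5 SD screen, secular trends, and true WHO reference curvature.

## 7. The DiD scenario generator

For statistical calibration work a separate, simpler generator produces
child-level binary outcomes from four cell probabilities (base 0.4 plus
additive arm/period/interaction effects) with facility-level normal
intercepts (SD 0.05, 10 facilities per arm).  Deterministic cell
probabilities outside [0, 1] are a configuration error; the stochastic
facility effect is clipped at the probability boundary.

## 8. Problem sizes

Defaults were chosen so every stage runs comfortably on a laptop core:
the full default cohort (880 children) simulates and assesses in a few
seconds; the parameter-recovery suite uses ~2100 children / ~5200 audited
visits; DiD recovery uses 4000 children across 20 facilities; the null-
calibration study runs 1000 replicates of 400 children.  The acceptance
script completes in well under a minute.

## 9. Known limitations

* The bundled reference curves are synthetic; clinical use requires real
  WHO 2006 LMS files (drop-in) and a real birthweight-percentile standard
  for SGA.
* Corrected-age banding uses days, not completed weeks; deployed tools
  sometimes round first.  The difference only matters within ~3 days of a
  band edge.
* Concordance compares continuous interval-growth entries with exact band
  arithmetic; no numeric tolerance.
* The exposure-group assignment for child-level outcomes (enrollment
  regime) is one defensible reading of a pre/post design with a rollout
  gap; grouping by assessed-visit calendar period instead would shrink the
  pre-period cells to the first enrollment weeks.
* No multiple-testing adjustment across outcomes, and no GEE/logistic
  alternatives to the linear probability model — raw agreement and LPM
  percentage points are the reporting conventions of this literature.
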