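# Methods

## The phenotyping model

`aghdstrat` implements a deterministic, rule-based computable phenotype for
adult growth hormone deficiency (AGHD) over longitudinal claims data. The
unit of analysis is the person; the evidence is the person's full stream of
coded claim lines — ICD-9-CM/ICD-10-CM diagnoses, CPT procedures, ATC
pharmacy dispensations. The model makes three structural assumptions:

1. **Claims are evidence of care, not of outcomes.** A procedure code says a
   test was billed, not what it showed; this is why test-based evidence can
   only ever reach the *moderate* tier.
2. **Code hierarchies carry meaning.** ICD and ATC are prefix-hierarchical,
   so list entries match by prefix by default (e.g. `H01AC` covers all
   somatropin-type agents); CPT is flat, so CPT entries default to exact
   match.
3. **Deficiency is an axis-level concept.** "≥ 3 pituitary hormone
   deficiencies besides GH" counts distinct hormonal axes (thyroid, adrenal,
   gonadal, prolactin, posterior), never repeat claims on one axis, and
   never the GH axis itself. The same counting rule is reused for the
   hormone-replacement and axis-test criteria, which keeps the three
   "≥ 3 of something besides GH" rules mutually consistent.

### Cohort eligibility

A person is in scope when, at the index date (default 2017-12-31): index-year
age ≥ `adult_age` (default 18; age is `index_year − birth_year` because
claims extracts carry year-granular birth information); the enrollment span
clipped at the index date covers ≥ `min_enrollment_days` (default 183,
i.e. ~6 months, computed on the enrollment interval as the standard
claims-data denominator, closed on both ends); and any recorded death falls
strictly after the index date. Dead or ineligible persons are reported with
the first failed criterion and never classified.

The "≥ 6 months of data" requirement is interpreted as continuous
enrollment rather than total claims span; enrollment is what claims
databases actually guarantee observability for.

### Tier assignment

The five high-likelihood paths are evaluated in fixed precedence
(`GROUP_A → GROUP_B → PIT_DEF_3 → GH_RX → HRT_3`); the reported reason is
the first satisfied path, but precedence can never change the tier (any
satisfied path suffices for *high*). Design choices where the flowchart
admitted more than one reading:

- **Exclusion lists veto only the two prescription paths.** The exclusion
  clause is attached to GH therapy and multi-replacement therapy — contexts
  where another indication (Turner syndrome, chronic kidney disease, HIV
  wasting, constitutional short stature) explains the drugs. Diagnosis-based
  paths ignore the exclusion lists entirely.
- **Both exclusion lists apply as a union to both prescription paths**, and
  exclusion diagnoses are searched over the person's whole record with no
  temporal relation to the prescription (no window is clinically implied:
  the explaining condition may be coded years before the therapy).
- **A vetoed GH user bypasses the moderate tier and lands in low.**
  GH-treated adults are structurally barred from the moderate tier; the
  behaviour sits behind `gh_veto_bypasses_moderate` (default `True`) because
  it is the single most consequential flowchart reading. A veto of *only*
  the multi-replacement path does **not** bypass moderate — the structural
  bar is stated for GH treatment specifically.
- **"Within the same year" means the same calendar year** for the
  three-replacement-classes rule (`ReplacementWindow.CALENDAR_YEAR`; the
  enum leaves room for a rolling-365-day variant, which is not implemented).
- **Age at an event is service-year minus birth-year**, matching the
  year-granular cohort age rule.

### Descriptive statistics

- *Tier/reason proportions* are exact rational counts over the eligible
  cohort; they sum to 1 to ≤ 1e-12.
- *Age × sex table*: bands (18,30], (30,40], … (80,∞) on index-date age;
  every cell is a percentage of the **whole** cohort, so the three tier
  columns sum row-wise to the cohort column and the cohort column sums
  to 100.
- *Comorbidity incidence*: per tier, the fraction of persons with ≥ 1
  matching diagnosis within the closed 365-day window ending at
  `min(enroll_end, index_date)` — the last year of observation, anchored per
  person. Each person counts once per comorbidity.
- *Standardized difference*: the standard pooled form for a binary
  covariate, `d = (p2 − p1)/sqrt((p1(1−p1)+p2(1−p2))/2)`, returning 0 when
  both group variances vanish with equal proportions, with |d| ≤ 0.1 flagged
  negligible. The formula is stated explicitly (and treated as a documented
  choice) because published balance tables frequently omit theirs and
  printed values cannot always be reproduced from printed proportions;
  this package never asserts agreement with any externally printed
  standardized-difference value.
- *Diagnostic-test usage*: per-sublabel (IGF-I serum, GH serum, and the
  arginine/levodopa, glucagon and insulin-tolerance stimulation panels)
  fraction of the high and moderate tiers over full observation; the low
  tier is omitted by reporting convention.

## Code lists

The algorithm is entirely list-driven, and validated lists are deployment
configuration, not package code. The shipped
`data/default_codelists.yaml` is an **approximate placeholder** set built
from clinical anchors: GH therapy = ATC `H01AC`; replacement classes = sex
hormones `G03`, systemic glucocorticoids `H02AB`, thyroid preparations
`H03AA`; GHD tests = CPT 84305 (IGF-I), 83003 (GH serum), 80428, 80422,
80435 (stimulation panels); axis tests = TSH/fT4, cortisol/ACTH,
testosterone/estradiol/FSH/LH, prolactin, vasopressin; plus plausible
sellar/structural diagnosis lists. Vasopressin *replacement* is deliberately
absent from the replacement list (central diabetes insipidus treatment was
not an input to the algorithm design). Every output is stamped with the
code-list version string so nothing computed under the defaults can be
mistaken for results under a validated set.

## The synthetic generator

The generator emulates what the pipeline needs from a claims extract: a
persons table, a multi-year event stream, and known ground truth. Six
archetypes plant one population per classifier branch (see the module
docstring for the table). Salient design decisions:

- **Constructive tier planting.** Archetype counts come from
  largest-remainder apportionment of the configured weights, so planted tier
  counts are exact integers and classifier-recovery tests can demand zero
  mismatches rather than statistical agreement.
- **Stochastic comorbidity planting.** Comorbidity flags are Bernoulli draws
  at configured prevalences (defaults graded by tier at levels typical of a
  stratified adult claims cohort, ~0.3 % to ~33 %), placed as dated
  diagnoses in the person's final observation year; they feed statistical
  recovery tests with 3σ binomial bounds.
- **Per-person streams.** Each person's randomness comes from
  `numpy.random.default_rng((seed, person_index))`, so output is
  byte-identical for a fixed (seed, config) and stable under any future
  parallelisation of the generation loop.
- **Enrollment ends at the index date** for every generated person, so the
  last observation year is the calendar index year and planted comorbidities
  are guaranteed to fall inside the incidence window. Demographics default
  to a female excess in the high/moderate tiers (59.3 / 71.6 / 50.4 %
  female) and an older age mix in those tiers.

What the generator does **not** emulate: claim reversals and billing noise,
enrollment gaps and insurance switching, code-version drift, correlations
between comorbidities, and any association between demographics and the
planted clinical events. Passing tests therefore demonstrate the logical
correctness and statistical calibration of the pipeline on clean data; they
do not demonstrate robustness to real-world claims messiness, which is
exactly the part that deployment-specific validated code lists and data
quality work must cover.

## Numerical and degenerate-input choices

- Dates are whole days; all intervals are closed. The 365-day incidence
  window is `[last − 364 d, last]`.
- The standardized difference returns exactly 0 for `p1 = p2 ∈ {0, 1}`
  (degenerate denominator) and raises on inputs outside `[0, 1]`.
- Code normalization (uppercase; dots/whitespace stripped for ICD) is
  idempotent; empty-after-normalization codes are configuration errors.
- Empty cohorts raise an explicit error for proportions (no silent NaNs);
  empty *tiers* in incidence/test tables produce zero rows.
- Malformed input rows become rejection records with reasons; accepted plus
  rejected rows always account for every input row.
- Duplicate person ids are an input-data error (the person is the unit of
  analysis); events referencing unknown persons are ignored with a warning.

## Problem sizes used by the test suite and acceptance script

Exhaustive rule-engine verification uses all 2⁸ = 256 predicate
combinations realized as minimal synthetic persons. Planted-structure
recovery uses n = 10,000 with weights chosen to produce a
0.5 / 6.0 / 93.5 % tier split (50 / 600 / 9,350 persons). Invariant fuzzing
uses 200 random cohorts of 12 persons drawing events from every configured
list. Statistical recovery uses 2,000 persons per tier over 20 seeds (10 in
the acceptance script) — at these sizes the 3σ binomial bound is ~3
percentage points for a 30 % prevalence and the whole suite completes in
well under a minute on one core.

## Known limitations

- The default code lists are approximate; results under them characterize
  the *software*, not any clinical population.
- Year-granular ages misclassify people near birthdays relative to exact
  dates; this mirrors the data the method is designed for.
- The rule engine is intentionally non-probabilistic: no scoring, no
  diagnosis sequencing beyond the stated age and calendar-year rules, no
  interpretation of test results.
- Whether a vetoed multi-replacement-only person should also bypass the
  moderate tier is genuinely open; the implemented reading (no bypass) is
  flagged in the classifier documentation and controlled by the same
  exclusion machinery, so revisiting it is a one-line change.
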