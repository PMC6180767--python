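# Methods

## The staging model

Pediatric Kaposi sarcoma (KS) in HHV-8-endemic Africa presents differently
from adult HIV-related KS: lymphadenopathic disease is common, woody edema
marks an indolent but chemo-refractory course, and disseminated skin/oral
disease carries very high mortality even without visceral involvement. The
Lilongwe pediatric staging classification encodes this in four stages
assigned by deterministic rules over a structured clinical record:

| stage | label | defining rule |
|---|---|---|
| 1 | Mild | only hyperpigmented skin / flat oral / subcutaneous nodule lesions, < 10 total |
| 2 | Lymphadenopathic | lymph nodes, nodular oral, facial edema, conjunctival, exophytic mass, or 10–19 hyperpigmented skin/oral lesions; residual class |
| 3 | Woody edema | woody edema, ± stage-1/2 features; 3A < 10% BSA, 3B ≥ 10% |
| 4 | Visceral / disseminated | pulmonary or abdominal visceral disease, and/or ≥ 20 hyperpigmented skin/oral lesions in a widespread distribution; dominates all |

Precedence is 4 → 3 → 1 → 2, which follows directly from the "with or
without features of the other stages" clauses; stage 2 is implemented as
the residual class. The classifier is total and deterministic: every valid
record receives exactly one stage, with the list of fired rules attached.

Rule details that required a decision:

* **Cluster counting.** Coalescing/confluent hyperpigmented skin lesions
  localized to one anatomic region count as one lesion per cluster. A
  cluster label spanning two regions is rejected. Collapsing applies to
  hyperpigmented skin lesions; oral lesions are counted individually.
* **Hyperpigmented skin/oral tally.** Counts hyperpigmented skin plus flat
  and nodular oral lesions; flesh-colored subcutaneous nodules are the
  sole stated exclusion and are excluded.
* **"Widespread distribution"** has no published quantitative definition.
  It is operationalized as cluster-collapsed hyperpigmented skin/oral
  lesions occupying ≥ 3 of the 11 anatomic regions (configurable), with a
  per-record boolean override so a clinician's adjudication wins.
* **The 10% BSA boundary.** "Less than 10%" (3A) versus "more than 10%"
  (3B) leaves exactly 10% unassigned; it is assigned to 3B so the
  boundary falls with the more extensive-disease group.
* **Facial edema** triggers stage 2 and is kept distinct from the woody
  edema that defines stage 3.
* **Induction failure** is the inability to achieve > 90% reduction in
  size of *all* lesions after four induction cycles of bleomycin–
  vincristine: success requires every lesion strictly above 90% reduction,
  and a lesion at exactly 90% is a failure.

## BSA estimation

Woody-edema extent uses the adult Wallace Rule of 9s (head/neck 9%, each
arm 9%, each leg 18%, anterior and posterior trunk 18% each, perineum 1%):
the estimate is Σ weight(region) × fraction(region), linear and monotone,
bounded in [0, 100]. The weight table is a package constant that can be
swapped for a pediatric (e.g. Lund–Browder-style) chart; the adult table
is the default because the classification names the Wallace rule without
pediatric modification.

## ACTG T comparison

The ACTG TIS system's tumor axis is re-implemented for the head-to-head
comparison: T1 for tumor-associated edema, extensive oral KS
(operationalized as any nodular oral lesion), or visceral disease; T0
otherwise. Ulceration, a T1 criterion in the published guidelines, is not
a schema field and is omitted. The I and S axes are out of scope. The
instructive divergence: every Lilongwe stage-3 record is T1, while
skin-disseminated stage-4 records without viscera are T0 despite ~88%
mortality in that stage.

## Survival analysis

Event-free survival (EFS: induction failure, progression/relapse, or
death) and overall survival (OS) are estimated per stage with the
Kaplan–Meier product-limit estimator (via `lifelines` behind the package's
`km_fit` surface) and compared with the asymptotic k-group log-rank test;
an optional label-permutation p-value (with the +1 correction) is
available for small groups. Ties between events and censorings at one
time follow the events-first convention. The "2-year" horizon defaults to
24 months. Point estimates only — no Greenwood confidence bands. The test
suite checks `km_fit` against a hand-written risk-set recomputation on
exhaustive small inputs, and the log-rank p-value against a hand-written
two-group permutation null.

## The synthetic cohort generator

No line-level data for the 68-patient retrospective cohort are deposited,
so the package ships a generator whose defaults *are* the published cohort
structure, making every stage of the pipeline testable end-to-end:

* **Stage mix** 0 / 37 / 14 / 17 (stages 1–4), n = 68.
* **Covariates.** Stage-2 cART-at-diagnosis (19/37) and moderate-severe
  cytopenias among stage-2 patients not on cART (13/18) are realized as
  exact counts, randomly placed, so the printed proportions hold for any
  seed. Ages are drawn per stage from normal distributions and recentred
  so the realized stage mean equals the configured mean exactly (stage 3:
  12.6 years; stage 2 youngest at 6.0; stage 4 at 8.5 — the last two are
  stated only ordinally in the source and are config defaults, not
  calibration surfaces). CD4 means (450/380/120 for stages 2/3/4) respect
  the stage-4-lowest ordering; lymphadenopathy is enriched in stage 2 and
  oral involvement in stage 4. Values the source reports only ordinally
  are deliberately *not* treated as reproduction targets.
* **Lesion inventories** are generated per latent stage to satisfy that
  stage's defining rule and no higher-precedence rule (e.g. stage-2
  tallies capped at 19; stage-4 disseminated patients get ≥ 20 lesions
  over ≥ 4 regions so the widespread rule holds with margin, and no woody
  edema or nodular oral lesions so their ACTG stage reads T0). Some
  records carry confluent clusters to exercise cluster collapsing. Every
  record is re-classified at generation time and a latent/assigned
  mismatch is a hard error, so round-trip stage recovery is exact by
  construction.
* **Outcomes** come from frozen per-patient tables, not parametric draws:
  with 14–37 patients per stage, only explicit event/censor tables can
  reproduce the printed product-limit values exactly. The tables satisfy,
  simultaneously: stage-2 24-month EFS = 27/37 (73%) and OS = 27/36 (75%,
  with exactly one patient lost to follow-up before the first death);
  stage-3 EFS = 4/14 (28.6%) and OS = 11/14 (78.6%, three of four deaths
  before month 24); stage-4 EFS = 0% and OS = 2/17 (11.8%); deaths
  10/4/15 by stage with causes 4 KS + 6 non-KS / 4 non-KS / 15 KS; the 12
  stage-4 deaths before doxorubicin availability with median 3 months and
  maximum 7; the three ABV-treated deaths at 4, 9 and 12 months; two
  ABV-treated stage-4 survivors alive at 17 and 27 months; and survivor
  follow-up within 15–50 months with median 28. `validate_outcome_tables`
  re-checks the full constraint set with `km_fit` every time the default
  tables are built. The tables are one admissible configuration: the real
  per-patient censoring pattern cannot be recovered from published
  aggregates, so quantities *not* pinned by a printed number (exact death
  dates within a stage, which patient is censored when) are choices.
* **Stage-3 substages.** The four complete-remission patients all had
  < 10% BSA involvement; the generator makes them substage 3A and defaults
  to a 5/9 3A/3B split (one admissible split; only the pooled stage-3
  count is a published number).
* **Seeding.** All randomness flows from one `numpy` Generator seeded from
  the single config seed. The same config is byte-identical across runs;
  the reference cohort is regenerated on demand (`reference_cohort()`)
  rather than shipped as a static file — the determinism test guarantees
  the regeneration is byte-identical, which is the property a shipped
  fixture would provide. Because calibrated quantities are exact counts,
  frozen tables, or recentred means, every published aggregate is
  invariant to the seed; the seed only permutes which patient carries
  which draw.
* **Exponential mode** (`outcome_mode="exponential"`) draws outcome times
  from per-stage hazards for power/sample-size exploration. It is *not*
  calibrated to the printed survival values.

### What the generator does not emulate

No HHV-8 or treatment-response biology, no correlation between covariates
and outcomes within a stage (CD4 and age are independent of death times
given the stage), no immune reconstitution under cART, and no measurement
error in lesion counts or BSA fractions. Passing tests therefore
demonstrate that the classifier, estimator and reporting are correct and
that the published aggregates are internally consistent — not that the
generator's records are clinically realistic at the individual level.

## Reporting

The Table-1-style report gives per-stage rows (3A and 3B separately plus
a pooled stage-3 subtotal): n, percent of cohort, mean age, mean CD4,
lymph-node / oral-involvement / cART percentages, induction-failure
percentage, deaths, and 24-month EFS/OS. Induction failure has no
per-patient schema field, so the report counts an EFS event within the
first 8 months (four 3-week BV cycles plus assessment) as an induction
failure. Every number in the report is recomputable from the staged
records alone.

## Known limitations

* The widespread-distribution rule (≥ 3 regions) is this package's
  operationalization, not the authors' definition; use the per-record
  override where clinical adjudication exists.
* The ACTG T axis omits ulceration (not recorded in the schema) and uses
  the nodular-oral surrogate for "extensive oral disease".
* Visceral involvement enters as upstream boolean adjudications; the
  package does not implement the clinical working definitions used to
  call visceral disease without endoscopy/bronchoscopy.
* The frozen outcome tables are one admissible configuration; analyses
  sensitive to the censoring pattern (anything beyond the pinned
  aggregates) should not treat them as data.
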