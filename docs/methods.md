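# Methods

## The validation problem

A case-ascertainment algorithm is a deterministic rule over coded
administrative records that classifies each person as a disease case or
not. Its value for surveillance depends on four operating characteristics
measured against a reference standard: sensitivity (cases found among true
cases), specificity, PPV (true cases among flags) and NPV. For pediatric
celiac disease the reference standard is histological — a duodenal biopsy
graded Marsh IIIa or above — so the reference positive cohort is assembled
by chart review at the single regional pediatric endoscopy provider, and
the negative cohort is *population-based*: every other child resident in
the region. A population-based negative cohort matters because predictive
values depend on prevalence; computing PPV in an enriched clinic sample
would inflate it. For the same reason the package reports PPV/NPV directly
from the validation cohort with no prevalence adjustment.

## The algorithm family

Every rule has two components: an endoscopy and a set of celiac-coded
clinical contacts. The endoscopy can come from two channels with different
coding behaviour:

- **Fee-claim channel** (`ohip_any_indication`): the outpatient billing
  claim for the procedure, matched on fee code only. Physicians bill at
  procedure time, before histology is available, and the claim format
  allows a single diagnostic code — so the claim is treated as an endoscopy
  *for any indication*.
- **Procedure-record channel** (`sds_cd_coded`): the same-day-surgery
  record, which carries up to 20 diagnostic codes and is completed by
  hospital coders who may see the biopsy result; the rule requires the
  record itself to carry a celiac code.

Contacts are outpatient claims with a celiac diagnostic code billed by an
adult or pediatric gastroenterologist (family-physician and pediatrician
visits never qualify), optionally extended with celiac-coded hospital
discharges. The 13 rule variants per channel vary the number of contacts
(1 or 2), the window (1–5 years) and the ordering (contacts strictly after
the scope or anywhere).

Interpretive choices the rule descriptions leave open, fixed here and
configurable:

- *Window anchoring*: "2 or more contacts in k years" anchors the half-open
  k-year window at the scope date, `[scope, scope + k years)`, matching the
  clinical investigation sequence. The alternative reading (k-year span
  measured between the contacts themselves) is implemented behind
  `window_anchor="span"`.
- *Unwindowed rows* (1 and 7): contacts may precede the scope. This is
  forced internally — the "after scope" variant (row 13) would otherwise be
  identical to row 1, yet the two are defined as distinct rules.
- *"After scope" is strict*: a same-day contact does not qualify.
- *Index date*: the earliest scope participating in a qualifying pattern,
  since biopsy defines the diagnosis. A person is counted once regardless
  of how many patterns qualify.
- *Deduplication*: identical claims (person, physician, date, code) count
  as one contact.
- *Code matching* is by prefix ("579" matches "579", "579.0", "5790"),
  reconciling 3-character outpatient claim codes with the 4-digit ICD-9
  celiac code; exact matching is available. Endoscopy fee/intervention code
  sets are configuration lists with documented placeholder defaults, since
  jurisdictional fee schedules vary.

The evaluator is vectorized over pandas merges; an independent brute-force
enumerator over all (scope, contact-subset) combinations backs it in the
test suite, along with the four family-monotonicity properties (threshold,
window length, event types, ordering).

## Confidence intervals for proportions

Operating characteristics use the Wilson score interval with Newcombe's
continuity correction. The correction keeps coverage honest at the extreme
proportions typical here (specificity and NPV near 1). z is fixed at 1.96
for the 95% level, the conventional reporting value; the difference from
the exact normal quantile (1.959964) is far below the 2-dp reporting
precision. Reported percentages round half-up (Python's default banker's
rounding would turn 0.625 into 0.62). Degenerate cells are reported as
not-applicable rather than zero: PPV is undefined when nothing is flagged.

Known edge: for 82/89 the continuity-corrected lower bound is 83.946%,
which prints as 83.95 at 2 dp; published tabulations sometimes truncate
rather than round here, so cross-checks against external tables are done at
1 dp (83.9), where both conventions agree.

## Weighted kappa

Duplicate chart review on the ordinal Marsh scale is summarized by
κ_w = 1 − Σw·o / Σw·e with disagreement weights |i−j| (linear) or (i−j)²
(quadratic, the default for ordinal grades), observed proportions o and
chance-expected proportions e from the marginals. κ is undefined (an error,
not 0 or 1) when both raters use a single category. The implementation is
tested against a hand-worked 3×3 table and an independent library
implementation.

## Standardized incidence

Annual incidence is directly standardized over age-band × sex strata
(default bands 0–4, 5–9, 10–14; the banding is configurable since finer
schemes are equally defensible). Person-years are exact: each person
contributes the eligible fraction of each calendar year, attributed to
their completed age on January 1 of that year (age 0 for in-year births);
case counts use the same attribution so numerators and denominators can
never disagree about a stratum.

The 95% CI uses the Fay–Feuer gamma method. With DSR y = Σwᵢdᵢ/nᵢ and
variance v = Σwᵢ²dᵢ/nᵢ², the lower bound is the α/2 quantile of a gamma
distribution with shape y²/v and scale v/y; the upper bound augments both
moments by the largest stratum weight per person-year w_M = max wᵢ/nᵢ
(shape (y+w_M)²/(v+w_M²), scale (v+w_M²)/(y+w_M)). In the single-stratum
limit this reduces exactly to the Poisson chi-square interval
[χ²_{2d}(α/2)/2n, χ²_{2d+2}(1−α/2)/2n], which the test suite checks to
relative 1e-9; simulated coverage sits in the conservative 93–99% band.

## Poisson trend

Stratum event counts with log person-years offset, covariates calendar year
(integer, centered at the first study year so the intercept is
interpretable), a male indicator, and age (band midpoint in years);
optional year×age interaction and quadratic-year term for the linearity
check. Fitting is maximum likelihood via iteratively reweighted least
squares; an independent generic optimizer on the same likelihood agrees to
1e-6 in the tests. APC = (exp(β_year) − 1)·100; rate ratios exponentiate
the *unrounded* coefficients with Wald intervals (matching symmetric
printed intervals; note that exponentiating a coefficient already rounded
to 2 dp can disagree with a printed RR in the last digit).

## The synthetic cohort generator

The generator emulates the statistical structure the validation assumes,
not any real data set. Default parameters describe a mid-size metropolitan
pediatric cohort: 235,320 children observed 2005–2011, true incidence of
biopsy-proven disease 7/100,000 person-years (within the 2–54 range
reported across western populations, and yielding on the order of a hundred
incident cases), 51% male, uniform ages. The cohort is open and roughly
stationary: each child's age is drawn at a uniformly chosen reference time
inside the window, so births spread over the preceding 15 years and the
window itself and every age stratum is populated in every calendar year.

Event streams follow the investigation sequence. A true case has a
celiac-coded screening visit (primary care) at onset; undergoes endoscopy
with probability `p_biopsy_if_cd` (default 0.90 — families sometimes
decline biopsy after positive serology, and only biopsied cases enter the
positive reference standard, exactly as a biopsy-based chart review would
find them); the endoscopy generates a fee claim with probability
`p_ohip_endoscopy_billed` (0.95) and always a procedure record, which
carries the celiac code with probability `p_sds_record_cd_coded` (0.80,
the coder-saw-the-histology channel); with probability
`p_outpatient_cd_visit_post_dx` (0.85) the case enters gastroenterology
follow-up — at least one celiac-coded GI visit, plus extra visits at 0.5
per remaining eligibility-year — and with probability 0.05 has a
celiac-coded hospitalization. Because the channels are independent, the
measured sensitivity of each benchmark algorithm is the product of its
stage probabilities, which the parameter-recovery tests verify to ±0.02.

False positives arise from a celiac-suspected-without-confirmation channel:
with probability `background_cd_code_noise` (4 per 10,000) a non-case
(e.g. non-celiac gluten sensitivity, which has no code of its own) acquires
celiac-coded GI visits and is usually scoped; the fee claim looks identical
to a true case's, while the procedure record is celiac-coded only with
probability 0.10 since the coder usually sees negative histology. This
reproduces the qualitative signature of the two channels — similar
sensitivity, sharply different PPV. Background endoscopy for unrelated
indications runs at 150/100,000 person-years; coverage gaps of 1–6 months
occur with probability 0.03.

What the generator does **not** emulate: real fee-schedule code
distributions, regional referral patterns, secular drift in coding
practice, migration, family clustering, or the chart-review identification
funnel. Passing tests therefore demonstrate correctness of the estimators
and the algorithm logic under a faithful generative structure — not that
any particular real jurisdiction's data would yield the same operating
characteristics.

## Exact-count fixtures

The benchmark 2×2 tables are uniquely recoverable from the validation
cohort sizes (115 positives, 235,320 negatives) plus published sensitivity
and PPV: TP = round(0.7043·115) = 81 and flagged = round(81/0.5329) = 152
give (81, 71, 34, 235249) for the fee-claim benchmark, and TP = 82,
flagged = 89 give (82, 7, 33, 235313) for the procedure-record benchmark.
Before use, the reconstruction is cross-checked by re-deriving all four
published statistics from the counts. `build_validation_fixture`
constructs a bundle attaining any requested table exactly: flagged persons
receive a scope followed by monthly contacts (qualifying under every grid
variant), labeled-positive misses have no administrative footprint, and
negatives are event-free registry rows.

## Reporting conventions

Displayed counts of 1–5 are suppressed as "<6"; counts outside the union of
identified cases are rounded to the nearest 10. Suppression applies only at
the rendering layer — internal statistics always use raw counts. Pipeline
runs log the seed, a config hash and per-stage record counts, so a run is
reproducible from its log alone. The default generator seed is 20110629
and every CLI run accepts `--seed`.

## Problem sizes

Simulation-based tests use cohorts of 15,000–200,000 children (full-scale
235,320 for the default-parameter checks), 500 replicates for gamma-CI
coverage, 20 seeds for the noise-monotonicity property, and 100 random toy
bundles for the algorithm-family monotonicity suite; these sizes give
binomial/Poisson standard errors comfortably inside the asserted
tolerances.

## Known limitations

- Subgroup re-validation needs an age for negatives, who have no diagnosis
  date; the study-window midpoint is used (configurable). Children born
  after the midpoint get a negative age and fall below any cutoff.
- The exact fee/intervention code sets of any real jurisdiction, and its
  physician-specialty coding scheme, must be supplied via configuration;
  the defaults are placeholders.
- Eligibility intervals are half-open day-granular; sub-day timing and
  retroactive coverage corrections are out of scope.
- Whether procedure-record diagnostic codes in a given era are ICD-9 or
  ICD-10-CA is absorbed into the configurable code sets; no general
  cross-revision mapping is provided.
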