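# celiaclaims

Validation of code-based case-ascertainment algorithms for **biopsy-proven
pediatric celiac disease** in linked health-administrative data, with
downstream standardized-incidence and trend estimation — exercised entirely
on synthetic linked-claims cohorts with known ground truth.

Administrative claims (physician billing, same-day-surgery records, hospital
discharges) are an attractive substrate for population surveillance of
chronic disease, but a diagnostic code is not a diagnosis. Before a
code-based algorithm can be used to count incident cases, its operating
characteristics must be measured against a reference standard in which true
disease status is known. This package implements that whole workflow for the
pediatric celiac setting, where the reference standard is duodenal biopsy
(Marsh grade IIIa or above) and the candidate algorithms combine an
endoscopy record with celiac-coded gastroenterologist contacts. It is aimed
at epidemiologists and health-services researchers who build or audit
claims-phenotyping algorithms.

## What it computes

**Case-ascertainment algorithms.** A 26-variant grid of declarative rules:
an endoscopy from one of two recording channels — an outpatient *fee-code
claim* (billed at procedure time, any indication, single diagnostic code) or
a *same-day-surgery procedure record* (coded later, up to 20 diagnostic
codes, must itself carry the celiac code) — combined with 1 or 2
gastroenterologist celiac-coded visits and/or celiac-coded hospitalizations,
optionally within a k-year window anchored at the endoscopy or strictly
after it. The differential coding accuracy of the two endoscopy channels is
the scientific crux: the fee-claim channel is sensitive but unspecific, the
procedure-record channel specific but incomplete.

**Diagnostic accuracy.** Sensitivity, specificity, PPV and NPV as binomial
proportions x/n with 95% CIs by the efficient-score (Wilson) method with
continuity correction,

    lower = [2np + z² − 1 − z·√(z² − 2 − 1/n + 4p(n(1−p)+1))] / [2(n+z²)]
    upper = [2np + z² + 1 + z·√(z² + 2 − 1/n + 4p(n(1−p)−1))] / [2(n+z²)]

with z = 1.96, p = x/n; plus weighted kappa for duplicate chart-review
agreement on the ordinal Marsh grade.

**Incidence and trends.** Directly age–sex standardized rates per 100,000
person-years, DSR = Σᵢ wᵢ·dᵢ/nᵢ, with Fay–Feuer gamma CIs (exact Poisson
behaviour at low counts), and a log-linear Poisson model on stratum counts
with person-years offset giving the annual percent change
APC = (exp(β_year) − 1)·100, adjusted for age and sex, with optional
year×age interaction and quadratic-year linearity check.

**Synthetic cohorts.** A generator that draws a whole linked pediatric
cohort (registry with coverage intervals, claims, procedure records,
hospitalizations, physician specialties, reference labels) following the
clinical sequence screening → endoscopy → follow-up, with the two endoscopy
recording channels modelled independently; and a constructive fixture
builder that produces a bundle on which a chosen algorithm attains an exact
requested confusion table.

## Worked example

The benchmark fee-claim-based algorithm ("scope + ≥1 gastroenterologist
celiac visit after the scope") validated against a population reference of
115 biopsy-proven positives and 235,320 negatives:

```python
import datetime as dt
import celiaclaims as cc

win = (dt.date(2005, 1, 1), dt.date(2011, 12, 31))
spec = cc.get_algorithm("13-OHIP")
bundle, truth = cc.build_validation_fixture(81, 71, 34, 235249, spec, seed=20110629)
result = cc.apply_algorithm(bundle, spec, win)
ct = cc.confusion_table(result, bundle.labels)
oc = cc.operating_characteristics(ct, algorithm_id="13-OHIP")
print("flagged:", result.n_cases)
print("confusion:", ct.as_tuple())
print("sensitivity:", oc.sensitivity.format())
print("specificity:", oc.specificity.format())
print("ppv:", oc.ppv.format())
print("npv:", oc.npv.format())
```

prints

```
flagged: 152
confusion: (81, 71, 34, 235249)
sensitivity: 70.43 (61.09–78.39)
specificity: 99.97 (99.96–99.98)
ppv: 53.29 (45.05–61.36)
npv: 99.99 (99.98–99.99)
```

The algorithm flags 152 children; 81 are true biopsy-proven cases, so
sensitivity is 81/115 = 70.43% and PPV 81/152 = 53.29% — the algorithm
misses 3 in 10 true cases and nearly half its flags are false, which is why
a validation step like this must precede any claims-based incidence
estimate.

A full simulated pipeline (simulate → ascertain → validate → incidence →
trends → report) runs from the shell:

```sh
celiaclaims run-all --seed 7 --out pipeline_out
celiaclaims simulate --out cohort --seed 7 --n-children 50000 --incidence 60
celiaclaims validate --bundle cohort --algorithms 13-OHIP,1-SDS --out table1.csv
```

## Layout

- `src/celiaclaims/data_model.py` — linked-table schema, CSV readers/writers,
  code-set configuration, age and eligibility operations
- `src/celiaclaims/algorithms.py` — the declarative rule grid and its
  vectorized evaluator
- `src/celiaclaims/accuracy.py` — confusion tables, score-CC intervals,
  subgroup re-validation, weighted kappa
- `src/celiaclaims/incidence.py` — person-years, direct standardization with
  gamma CIs, Poisson trend fits
- `src/celiaclaims/synthetic.py` — cohort simulator and exact-count fixture
  builder
- `src/celiaclaims/reporting.py`, `cli.py` — pipeline orchestration, cell
  suppression, report rendering, command-line interface

See `docs/methods.md` for the statistical methods, generator assumptions and
design decisions.
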