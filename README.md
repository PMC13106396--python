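# fairprov

Provenance-based fairness auditing for clinical risk prediction models.

Clinical AI governance needs more than a point-in-time fairness metric: an
auditor has to be able to trace *why* a model flagged one patient and not
another, and to trust that the audit trail has not been edited after the
fact. `fairprov` is a simulation-backed toolkit for that problem, aimed at
methodologists and auditors of clinical decision-support models. It

- simulates 30-day readmission cohorts with a **known injected gender bias**,
  giving audits a ground truth to recover;
- fits two audited model families — L2 logistic regression and a random
  forest — that log the **mechanism of every prediction** (per-feature logit
  contributions; per-tree decision paths and votes; impurity importances);
- computes group-fairness statistics with permutation significance,
  counterfactual gender-flip analysis, a gender-exclusion ablation and a
  bias-magnitude sensitivity sweep;
- packages everything into a hash-chained, schema-validated
  **AI Fairness Provenance Record (AFPR)** with a rendered audit report.

## The model and the statistics

Cohorts of n patients (age, BMI, comorbidity, gender) get outcomes from a
logistic data-generating process on standardized features:

```
P(Y = 1 | x) = σ(β₀ + β_age·age_z + β_bmi·bmi_z + β_com·com + β_g·male)
```

with defaults β₀ = −1.0, β_age = +0.50, β_bmi = +0.40, β_com = +1.00 and the
injected disparity β_g = −0.30 (male patients get lower readmission odds than
otherwise-identical female patients).

The audit computes, on a held-out 30% outcome-stratified test split at
threshold 0.5, with group means written female − male:

- **DPD** (demographic parity difference) = selection_rate(F) − selection_rate(M)
- **EOD** (equal opportunity difference) = TPR(F) − TPR(M)
- a permutation test of |EOD| under gender exchangeability, with the add-one
  p-value `p = (k + 1)/(N + 1)` over N = 1,000 permutations;
- 5-fold stratified cross-validation of accuracy, ROC-AUC, DPD and EOD with
  95% confidence intervals `mean ± t(0.975, df = 4)·SD/√5`;
- the fraction of decision-boundary cases (|p̂ − 0.5| ≤ 0.15) whose class
  flips when the gender bit is inverted.

## Worked example

```
$ fairprov audit --n 1000 --seed 42 --no-tune --no-sweep --out out/
audit complete; artifacts in out/
$ fairprov afpr verify out/afpr.json
valid; chain of 50 entries verified
```

`out/report.md` then contains (excerpt):

```
### logistic

| group | n | selection rate | TPR | FPR |
|---|---|---|---|---|
| female | 149 | 0.282 | 0.519 | 0.155 |
| male | 151 | 0.179 | 0.289 | 0.132 |

DPD = 0.103 (moderate), EOD = 0.230 (high), permutation p = 0.0170*
```

Read: the logistic model flags 28.2% of female vs 17.9% of male test
patients (DPD = +0.103), and among truly readmitted patients it catches
51.9% of women but only 28.9% of men (EOD = +0.230) — a disparity the
permutation test rates unlikely under gender exchangeability (p ≈ 0.017).
The forest, audited in the same report, spreads gender across many shallow
tree paths and shows a smaller, non-significant disparity. `out/afpr.json`
holds the full AFPR: cohort provenance, the development log, hash-chained
per-prediction records, and every audit block; `fairprov afpr verify`
detects any post-hoc edit to a logged decision.

Other subcommands: `simulate` (write a cohort CSV), `cv`, `sweep`,
`afpr report`. Add `-v` for stage-by-stage progress on stderr.

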