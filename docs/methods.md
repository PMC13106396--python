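# Methods

This note documents the models, procedures and design choices behind
`fairprov`, in the order the audit pipeline runs them.

## Cohort simulation

Each cohort is a table of n patients with four clinical features and a
binary 30-day readmission outcome:

| feature | distribution | default |
|---|---|---|
| age (years) | continuous uniform on [20, 85] | — |
| BMI (kg/m²) | Normal(27, 5), clipped to [16, 45] | — |
| comorbidity | Bernoulli | prevalence 0.35 |
| gender (male = 1) | Bernoulli | male fraction 0.5 |

Age and BMI are z-scored over the full generated cohort (sample SD,
ddof = 1); BMI is standardized *after* clipping. The outcome is a Bernoulli
draw at `sigmoid(lp)` with

`lp = −1.0 + 0.50·age_z + 0.40·bmi_z + 1.00·comorbidity + β_g·male`,

β_g = −0.30 by default. The coefficients are log-odds per SD (continuous) or
per unit (binary). A uniform age distribution is the simplest choice
consistent with a stated range; Bernoulli outcome draws (rather than
deterministic thresholding) keep labels stochastic, which is what makes
moderate, realistic accuracies attainable at all. Standardization is
computed once, globally, before outcome generation, and models are fit on
the same standardized columns; this makes the generating coefficients
exactly the large-n maximum-likelihood targets. The leakage introduced by
global (rather than per-fold) standardization is negligible at these n and
is accepted in exchange for that self-consistency.

Under this process the default cohort has outcome prevalence ≈ 0.31, and a
correctly specified logistic fit at n = 50,000 recovers every coefficient
within ±0.1 (tested).

**Seed discipline.** One master seed; every stochastic component (feature
draws, outcome draws, splitting, CV folds, permutations, per-sweep-point
cohorts, replicate seeds) draws from its own named 31-bit substream obtained
by hashing `"<master>:<name>"` with SHA-256. Adding a component or a sweep
grid point never perturbs the draws of another.

**Splitting.** The 70/30 train/test split is outcome-stratified with
largest-remainder rounding: the total test size is `round(0.3·n)` and each
outcome stratum contributes `floor(0.3·n_c)` plus leftovers by largest
fractional remainder. This pins the arithmetic exactly (1,000 patients split
700/300; 10 patients with 3 positives put exactly 1 positive in a 30% test
side). Strata with fewer than 2 members refuse to split.

## Audited models

**Logistic.** L2-penalized maximum likelihood: ridge strength 1/(2C) with
C = 1.0 against the *summed* negative log-likelihood, intercept unpenalized,
lbfgs, max 1,000 iterations, tolerance 1e−4. Non-convergence is recorded as
a provenance warning, not an error. The fitted model is stored as explicit
weights, and the per-prediction logit is *computed* as
`w₀ + Σ w_j·x_j` from the logged contributions `c_j = w_j·x_j`, so the
contribution-sum identity is algebraic, not a tolerance check.

**Random forest.** 100 trees, Gini impurity, bootstrap on, `sqrt(p)`
features per split, unlimited depth, `min_samples_split = 2`; leaf
probability = positive-class proportion at the leaf; ensemble probability =
mean of per-tree leaf proportions (not majority-vote fraction); a tree's
"vote" for the path logs is its class at 0.5. Fitted trees are flattened
into plain arrays (split feature, threshold, children, leaf proportions), so
archived models replay without the fitting backend; the replay is tested to
reproduce the backend's probabilities exactly.

**Classification.** Class 1 iff probability ≥ 0.5, uniformly (ties go
positive).

**Tuning.** Exhaustive grid search over n_estimators ∈ {50, 100, 200} ×
max_depth ∈ {unlimited, 10, 20} × min_samples_split ∈ {2, 5} (18
candidates), 3-fold outcome-stratified CV, ROC-AUC criterion. Ties break to
the first candidate in row-major grid order; a held-out fold with one class
is skipped with a warning and the candidate scored on the remaining folds.
"Unlimited" depth is serialized as an explicit sentinel string in configs.

**Model versions** are SHA-256 hashes of the canonicalized training config
plus a fingerprint of the training arrays — stable across re-runs, different
when either changes.

## Fairness statistics

Gender is coded 0 = female, 1 = male; both disparities are **female minus
male** (DPD from selection rates, EOD from TPRs), the convention used
throughout reports, tables and AFPR blocks. Rates are kept at full
precision; 3-decimal rounding happens only at render time. A group with no
true positives has an *undefined* TPR — an explicit error state, never a
silent zero.

**Permutation test.** |EOD| under N = 1,000 uniform random permutations of
the gender vector (whole-test-set permutation, not within outcome strata),
add-one p-value (k+1)/(N+1). Permuted replicates where a group draws no true
positives are counted as exceedances — the conservative direction.
Significance bands use strict inequalities: `***` p < 0.001, `**` p < 0.01,
`*` p < 0.05, else `ns`. Under a null generator and a gender-blind model the
rejection rate at α = 0.05 stays within the binomial band (tested over 200
audits).

**Cross-validation.** 5-fold, outcome-stratified, folds shuffled once with a
dedicated substream. Per-fold accuracy, ROC-AUC, DPD, EOD; summaries are
mean ± sample SD with 95% CIs from `t(0.975, df = k−1)` (2.776 at df = 4,
computed at runtime from the t distribution). Folds where a fairness metric
is undefined are flagged and dropped from that metric's summary, with df
adjusting.

**Counterfactual flips.** Boundary cases are test patients with predicted
probability in [0.35, 0.65] (inclusive; implemented as endpoint comparisons
because binary floating point makes |0.35 − 0.5| > 0.15). Every boundary
case is flipped — both female→male and male→female — with all other features
untouched. A flipped logistic case changes class iff the ±|w_gender| logit
shift crosses zero, which the tests verify case by case. Models refit
without gender are refused (no gender pathway exists to flip).

**Sensitivity sweep.** β_g ∈ {−0.10, −0.20, −0.30, −0.50, −0.80}; one fresh
cohort per grid point (per-index substreams), same split/fit/audit protocol.
Detection rule: `detected := (EOD ≥ 0.05) and (fitted gender weight < 0)`.
The permutation p is reported alongside but deliberately excluded from the
flag: small injected effects produce real, correctly-signed disparities that
need not reach p < 0.05 at n = 1,000. Across replicate seeds the fitted
gender weight tracks the injected β nearly linearly (correlation > 0.9;
tested); EOD is *not* monotone in |β| — at strong bias the male stratum's
predictions saturate below threshold and EOD stops growing — so only its
positive sign is asserted.

## The AFPR document

JSON, validated against a published schema (`docs/afpr.schema.json`,
generated from the pydantic models). Five parts: data provenance (cohort
spec, seed, feature descriptions, demographic composition, limitations),
model-development log, hash-chained inference log, audit results, chain
head.

Hash chain: SHA-256; genesis `prev_hash` is 64 zero hex characters;
canonical serialization is UTF-8 JSON with lexicographically sorted keys, no
insignificant whitespace, shortest round-trip floats. An entry's hash covers
the previous hash plus all of its own fields, so any mutation, reordering or
deletion fails verification at the earliest inconsistent sequence number.
Patient references are salted SHA-256 hashes of patient ids; the salt stays
outside the document. Timestamps come through an injectable clock so tests
are deterministic. Digital signatures, access control and storage engines
are out of scope — the record's content and verifiability are the point, not
a security implementation.

Reports label disparity magnitudes low (< 0.1), moderate (0.1–0.2), high
(> 0.2).

## Replicate-mean evaluation and problem sizes

Subgroup statistics on a 300-patient test split are noisy (per-seed EOD SD ≈
0.10), so summary claims are made on replicate means: the full audit
repeated under 50 master seeds at n = 1,000, 1,000 permutations, 5 CV folds
— the study `scripts/acceptance.py` runs end to end. The acceptance-level
tests compare these replicate means against externally reported reference
values at fixed tolerance bands; several of those bands are not attained by
the generating process as specified here (its signal strength, and hence the
reachable accuracies and disparities, is set by the coefficients above, not
by the reference values), and the suite reports those as failures by design
rather than widening a band or re-dialling the generator. Calibration
checks use
200 null audits at n = 400 and a single n = 50,000 fit for coefficient
recovery. These sizes put every estimate's Monte-Carlo error well inside the
tolerance it is judged against while keeping a full study in the minutes
range on one CPU.

## What the simulation does and does not show

The generator provides what real clinical data cannot: a known injected
bias, so an audit's output can be checked against ground truth. It
deliberately omits missing data, measurement error, proxy correlations
(features are independent of gender by construction, so excluding gender
removes essentially the whole disparity — real data, where correlated
features act as proxies, will not behave this benignly), multi-site
heterogeneity, and temporal drift. Passing audits here demonstrates that the
machinery measures what it claims under controlled conditions; it does not
certify performance of any real clinical model.

Known limitations: a single binary protected attribute; fairness definitions
limited to selection-rate and TPR parity (no calibration or individual
fairness); ensemble provenance logs paths and votes but not a per-feature
decomposition of forest predictions; the full inference log is capped by
default (25 entries per model) because forest path payloads are bulky —
set `inference_log_limit=None` to log every prediction.
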