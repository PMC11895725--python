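# Methods

## Problem setting

Electronic health records show which medications were *prescribed*, not
which were *dispensed*. For a new psychotropic prescription in a pediatric
population, roughly a fifth of patients never fill it (primary
nonadherence), and treating prescriptions as receipt misclassifies exactly
those patients. Bridging the gap requires linking the EHR's e-prescribing
events, coded as RxNorm concept unique identifiers (RxCUIs), to pharmacy
dispensing records, coded as package-level National Drug Codes (NDCs),
where one RxCUI fans out to many NDCs and no shared key exists.

`rxlink` implements that linkage and the downstream analysis — new-user
cohort construction, covariate balance, a propensity model for filling, and
propensity-weighted time-to-event estimation of the association between
filling and returning to the prescribing provider — as a tested pipeline
exercised end to end on synthetic data with known ground truth.

## Record linkage

The crosswalk maps each RxCUI to its candidate NDCs, with drug-name
validation: names from both ontologies are lowercased, stripped of
punctuation, and compared on the first alphabetic token, which is the
active-ingredient word under both naming conventions. Full-string matching
would be brittle across ontologies; the ingredient token is the invariant
part. NDCs are normalized to the 11-digit 5-4-2 form by zero-padding the
short segment of 10-digit hyphenated codes. Malformed NDCs and unknown
RxCUIs are collected into diagnostics rather than aborting a run, since
real feeds contain unmappable codes.

Matching is greedy, earliest-prescription-first, one-to-one: prescriptions
are processed in ascending (date, id) order, and each takes the unassigned
same-patient dispensing with a compatible NDC and the smallest fill date on
or after the prescription date within a 365-day search horizon (ties broken
by dispensing id). Same-day fills count as day 0. One-to-one assignment
guarantees a dispensing never satisfies two prescriptions; on instances
small enough to enumerate, the greedy result equals the lexicographically
earliest feasible assignment, which the test suite verifies by brute force.

Fill *labelling* is a separate step: a prescription counts as filled when
its matched dispensing is within `cutoff_days` (default 30) of the
prescription. Matches beyond the cutoff keep their link but are labelled
unfilled. The cutoff is a configuration value; an empirical CDF of
days-to-fill is emitted so a user can inspect the inflection point rather
than rely on automated detection.

## Cohort

Cohort entry is the patient's earliest in-window psychotropic prescription,
subject to: (1) washout — no psychotropic prescription *or* dispensing in
the 365 days before the index date (half-open interval, the index day
itself exempt); (2) age under 18 at index, computed as whole 365-day years
from integer day offsets; (3) an outpatient index encounter; and
(4) completeness — at least one encounter of any type in the capture year,
because dispensing feeds only refresh when the patient returns to the
system. Filters run in that order and log a CONSORT-style attrition table.
One index event per patient.

## Covariates

Twenty-two contextual variables per member: age, sex, race/ethnicity, BMI
(kg/m², may be missing), Area Deprivation Index state rank (decile 1–10),
payer, provider type, prescriber specialty, clinic type, four diagnosis
flags recorded at the prescribing encounter (depression, anxiety, ADHD,
headache), SSRI vs other psychotropic class, PHQ-9 severity category
(0–4 nonminimal, 5–9 mild, 10–14 moderate, 15–19 moderately severe, 20–27
severe, from the most recent score in the inclusive 14-day window ending at
the index date, else "Not taken"), psychotropic prescription counts at the
index encounter and over the index calendar year (the index prescription
included), and five service-use flags (well-child prior/index year,
outpatient/inpatient/ED prior year). Missing BMI is retained as missing
here; imputation happens inside the propensity model.

## Balance statistics

Standardized mean differences, with 0.10 as the conventional imbalance
flag:

* continuous: |m₁ − m₂| / √((s₁² + s₂²)/2), displayed alongside
  median (IQR);
* binary, from counts: |p₁ − p₂| / √((p₁(1−p₁) + p₂(1−p₂))/2), with the
  degenerate 0/0 case resolved to 0;
* multicategory (Yang–Dalton Mahalanobis form): drop one category, take the
  K−1 vector T of proportion differences and the averaged multinomial
  covariance S (diagonal (p₁ₖ(1−p₁ₖ)+p₂ₖ(1−p₂ₖ))/2, off-diagonal
  −(p₁ₖp₁ₗ+p₂ₖp₂ₗ)/2), and return √(TᵀS⁻¹T), falling back to the
  pseudo-inverse when S is singular. For K=2 this reduces algebraically to
  the binary formula, which the tests confirm numerically.

Display rounding is 3 decimals.

## Propensity and outcome models

The fill-probability model is an L1-penalized logistic regression
(scikit-learn `LogisticRegressionCV`, liblinear): features standardized,
categoricals one-hot against declared reference levels, BMI median-imputed
with a missingness indicator; a stratified 9:1 train/test split; the
penalty chosen at minimum 5-fold cross-validated deviance on the training
split (not the 1-SE rule); discrimination reported as held-out AUROC
(Mann–Whitney form, ties ½). Predicted probabilities for all rows, clipped
to [0.01, 0.99], are the propensity scores; ATE weights are 1/PS for
fillers and 1/(1−PS) for non-fillers. Clipping bounds the weights at 100
and is configurable.

The outcome is days to the first encounter with the prescribing provider
strictly after the index date, administratively censored at 90 days. The
marginal hazard ratio comes from a single-covariate Cox partial-likelihood
fit (lifelines, Efron tie handling); with weights, a robust sandwich
variance supplies the confidence interval — the naive variance is invalid
under IPW. Kaplan-Meier curves (optionally weighted) use the product-limit
estimator.

## Synthetic data generator

The generator emulates the structure of the target study so that every
stage has a recoverable ground truth. Per patient: demographics drawn to
match the published cohort's marginals (two-thirds female, median age 14,
ADI median 3, payer 44/53/2% public/private/self-pay, ~86% SSRI index
prescriptions, half with a recent PHQ-9); one index prescription at an
outpatient encounter uniformly in the study year; a latent fill indicator
from a logistic model whose default coefficients encode the observed
directions of imbalance (anxiety, SSRI, prior well-child visit and
primary-care clinic raise the fill probability; public insurance/self-pay,
male sex, deprivation and BMI lower it), with the intercept calibrated at
generation time (Brent root-finding on the realized linear predictors) so
the marginal fill rate is exactly `1 − nonfill_rate_target` (default
0.778). The default effect sizes put the oracle (Bayes) AUROC of the latent
fill probability near 0.81, i.e. discrimination of the strength the study
context reports.

Fill delay is a point mass at day 0 (probability 0.812) plus a shifted
geometric tail, rate 0.104, calibrated so ~91.3% of fills land within
7 days. A single geometric cannot simultaneously reproduce that 7-day mass
and a several-percent beyond-30-days tail; the 7-day anchor was chosen and
the beyond-30-day mass is ~0.7%. Real delay distributions are
heavier-tailed, so cutoff-sensitivity behaviour near 30 days is milder here
than in real feeds.

Observation noise: a configurable fraction of true fills is never recorded
(`coverage_miss_rate`, default 0.03, emulating non-participating
pharmacies), and decoy dispensings with NDCs absent from the crosswalk are
injected (`decoy_dispensing_rate`, default 0.10) — linkage and washout
scanning must both ignore them. A `prior_use_rate` fraction (default 0.10)
of patients carries a psychotropic fill inside the washout window (placed
before the study window so it cannot itself become an index candidate), and
`missed_capture_rate` (default 0.10) lack a capture-year encounter; these
are the exclusions the cohort filters must detect, and the truth table
records the resulting eligibility.

Follow-up visits are exponential with hazard
`baseline · exp(log_hr · fill + covariate terms)`, censored at 90 days. The
default true hazard ratio is 1.5 with no covariate terms; a documented
confounded configuration shares anxiety, prior well-child visit and public
payer between the fill and follow-up models, giving inverse-probability
weighting genuine bias to remove. The baseline hazard default (0.007/day)
brackets the two groups' 90-day follow-up fractions; an exponential model
with HR 1.5 cannot match both published fractions simultaneously, and this
is a calibration anchor only.

Dates are integer day offsets from 2020-01-01 in memory; calendar parsing
and ISO-8601 formatting are confined to the readers and writers. Identical
configurations (including the seed) produce byte-identical tables.

## What the synthetic tests do and do not show

Passing recovery tests show the pipeline's *mechanics* are correct under
the generator's assumptions: exact truth recovery when observation noise is
off, unbiased hazard-ratio recovery without confounding, and IPW debiasing
when the propensity model is correctly specified (the generator's fill
model and the LASSO share functional form, so correct specification holds
by construction). They do not show robustness to misspecified propensity
models, informative censoring, heavier delay tails, duplicate or
conflicting dispensing rows, or multi-prescription patients — the generator
emits one index prescription per patient, and refills, dose changes and
claim adjudication are out of scope.

## Numerical and design choices

* Problem sizes: unit fixtures use hand-built tables; recovery tests use
  n = 400–1000 patients; replicate-based recovery and debiasing checks use
  20 replicates at n = 2000, sized so the whole suite runs in a few minutes
  on one core.
* Linkage ties: equal fill dates break by smallest dispensing id;
  prescriptions process in (date, id) order.
* The washout interval is [index − 365, index); the 30-day fill window is
  inclusive on both ends (0 ≤ days ≤ 30), forced by same-day fills counting
  as filled.
* Degenerate SMD inputs: zero pooled variance with equal proportions
  returns 0; with unequal proportions, infinity.
* Cox non-convergence raises; symmetric groups recover HR = 1 to machine
  precision.
* The propensity train/test split is stratified by label with a recorded
  seed; rerunning with the same seed reproduces coefficients exactly.
* The crosswalk shipped under `rxlink/data/` is a synthetic stand-in
  (21 psychotropic ingredients, two NDCs each, plus a drug-class table
  marking the six SSRIs); any real crosswalk with the same columns can be
  loaded in its place.
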