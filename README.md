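# rxlink

Link EHR prescribing data to pharmacy dispensing records and analyse
primary medication nonadherence.

EHR data record which medications were *prescribed*; pharmacy dispensing
feeds record which were actually *filled*. The two streams use different
ontologies — prescriptions carry RxNorm concept unique identifiers
(RxCUIs), dispensings carry package-level National Drug Codes (NDCs), with
one RxCUI mapping to many NDCs — and share no key. `rxlink` is for
pharmacoepidemiologists and health-services researchers who need to bridge
that gap: it matches each prescription to at most one dispensing by
crosswalk compatibility, drug-name validation and nearest-fill-after date,
labels fills against a day cutoff, builds a new-user cohort (washout, age
restriction, data-completeness filter), quantifies filler/non-filler
covariate imbalance, and estimates the association between filling and
follow-up care with a propensity model and weighted survival analysis.

## The statistics at the core

* **Balance**: standardized mean differences — |m₁−m₂|/√((s₁²+s₂²)/2) for
  continuous covariates, |p₁−p₂|/√((p₁(1−p₁)+p₂(1−p₂))/2) for binary ones
  from group counts, and the Mahalanobis-type form √(TᵀS⁻¹T) over K−1
  category-proportion differences for multicategory covariates; SMD > 0.10
  flags imbalance.
* **Propensity**: L1-penalized logistic regression for P(fill | covariates),
  penalty chosen by 5-fold cross-validated deviance on a 9:1 train/test
  split, discrimination reported as held-out AUROC; inverse-probability
  (ATE) weights 1/PS and 1/(1−PS) with PS clipped to [0.01, 0.99].
* **Outcomes**: Kaplan-Meier product-limit curves and marginal Cox hazard
  ratios (Efron ties) for days to a follow-up visit with the prescribing
  provider, censored at 90 days; weighted fits use a robust sandwich
  variance.

Because no patient-level data ship with the package, a synthetic-data
generator produces internally consistent patient / encounter /
prescription / dispensing / PHQ-9 / diagnosis tables with a ground-truth
table (latent fill probabilities, true delays, true follow-up times), so
the full pipeline is testable end to end. See `docs/methods.md` for the
models, their assumptions and calibration.

## Worked example

```python
from rxlink import PipelineConfig, SimConfig, run_pipeline
from rxlink.config import PropensityConfig

cfg = PipelineConfig(
    out_dir="demo_run",
    simulate=SimConfig(n_patients=2000, seed=11),
    propensity=PropensityConfig(seed=0),
)
report = run_pipeline(cfg)
print(report["results"].summary())
```

prints

```
Prescription-fill study analysis
================================
cohort size                 1643
filled within cutoff        1222 (74.4%)
covariates with SMD > 0.10  10: bmi, adi_state_rank, sex, dx_anxiety, ssri, wcv_prior_year, payer, prescriber_specialty, clinic_type, phq9_severity
propensity model AUROC      0.745
marginal HR (follow-up)     1.275 (95% CI 1.097-1.483)
IPW-weighted HR             1.270 (95% CI 1.039-1.552)
```

Reading the output: of 2000 simulated patients, 1643 survive the washout
and completeness filters; 74.4% of their prescriptions were matched to a
dispensing within 30 days (the generator's marginal fill rate is calibrated
to 0.778 before cohort selection). Ten covariates separate fillers from
non-fillers beyond the 0.10 SMD convention — the generator plants exactly
this kind of confounding — and the propensity model discriminates fill
status with held-out AUROC 0.745. Patients who filled returned to their
prescribing provider at ~1.3 times the hazard of those who did not; the
IPW-weighted estimate adjusts that association for the planted covariate
imbalance. The run directory holds every intermediate artifact: linkage
table, attrition log, covariate table, balance report, coefficients,
propensity scores and weights, KM curve points, `report.json` and
`summary.txt`.

The same pipeline runs from the shell:

```sh
rxlink simulate --n-patients 2000 --seed 11 --out tables/
rxlink run-all --config pipeline.yaml
```

with subcommands (`link`, `cohort`, `covariates`, `balance`) for individual
stages. Tables are plain CSV with ISO-8601 dates; a synthetic stand-in
RxCUI→NDC crosswalk covering 21 pediatric psychotropic ingredients ships
with the package and any crosswalk with columns `rxcui, ndc, drug_name`
can replace it.

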