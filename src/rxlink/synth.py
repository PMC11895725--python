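"""Synthetic EHR + pharmacy-dispensing study population.

The generator emits internally consistent event tables — patients,
encounters, prescriptions, dispensings, PHQ-9 scores, diagnoses — plus a
per-prescription truth table, so every downstream stage (linkage, cohort
construction, covariate assembly, balance, propensity/outcome modelling) can
be tested against known ground truth without any external data.

Structure emulated:

* one index psychotropic prescription per patient, written at an outpatient
  encounter in the study year, drug drawn from the bundled crosswalk;
* a latent fill indicator from a logistic model on patient covariates,
  marginal rate calibrated to ``1 - nonfill_rate_target``;
* fill delay = 0 with probability ``p_same_day``, otherwise a geometric
  number of days >= 1 — a point mass plus fast-decaying tail;
* recorded dispensings carry an NDC mapped from the prescription's RxCUI;
  a configurable fraction of real fills is never recorded (non-participating
  pharmacies), and decoy dispensings with unmappable NDCs are injected;
* a follow-up visit with the prescribing provider drawn from an exponential
  hazard ``baseline * exp(log_hr * fill + covariate terms)``, censored at
  ``censor_days``;
* a fraction of patients carries a prior psychotropic pharmacy fill inside
  the washout window, and a fraction has no capture-year encounter — the two
  conditions the cohort filters must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import io
from .config import ConfigurationError, SimConfig
from .dates import year_interval
from .vocabulary import MedicationVocabulary, bundled_vocabulary

__all__ = ["SimPopulation", "generate_population", "write_fixture", "read_fixture"]

RACE_LEVELS = ["Hispanic", "NH Asian", "NH Black", "NH White", "Other"]
RACE_PROBS = [0.109, 0.028, 0.193, 0.558, 0.112]
PAYER_LEVELS = ["Public", "Private", "Self-pay"]
PAYER_PROBS = [0.445, 0.534, 0.021]
SPECIALTY_LEVELS = ["Primary care", "Psychiatry", "Other", "Unknown"]
SPECIALTY_PROBS = [0.827, 0.045, 0.120, 0.008]
CLINIC_LEVELS = ["Primary care", "Behavioral health", "Other", "Unknown"]
CLINIC_PROBS = [0.728, 0.080, 0.111, 0.081]
PHQ9_LEVELS = ["Nonminimal", "Mild", "Moderate", "Moderately severe", "Severe"]
PHQ9_PROBS = [0.215, 0.204, 0.213, 0.202, 0.166]
PHQ9_SCORE_RANGES = {
    "Nonminimal": (0, 4),
    "Mild": (5, 9),
    "Moderate": (10, 14),
    "Moderately severe": (15, 19),
    "Severe": (20, 27),
}
AGES = np.arange(5, 18)
AGE_WEIGHTS = np.array([1, 1, 1, 2, 2, 3, 4, 5, 7, 8, 8, 7, 6], dtype=float)

TABLE_NAMES = ["patients", "encounters", "prescriptions", "dispensings", "phq9", "diagnoses", "truth"]


@dataclass
class SimPopulation:
    patients: pd.DataFrame
    encounters: pd.DataFrame
    prescriptions: pd.DataFrame
    dispensings: pd.DataFrame
    phq9: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}


def _design_matrix(truth: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature columns the fill / follow-up linear predictors may use.

    BMI enters median-imputed so that a missing BMI contributes the typical
    value rather than dropping the subject.
    """
    bmi = truth["bmi"].astype(float)
    bmi = bmi.fillna(bmi.median())
    d = pd.DataFrame(
        {
            "age": truth["age"].astype(float),
            "male": (truth["sex"] == "Male").astype(float),
            "female": (truth["sex"] == "Female").astype(float),
            "bmi": bmi,
            "adi_state_rank": truth["adi_state_rank"].astype(float),
            "payer_public": (truth["payer"] == "Public").astype(float),
            "payer_private": (truth["payer"] == "Private").astype(float),
            "payer_selfpay": (truth["payer"] == "Self-pay").astype(float),
            "provider_physician": (truth["provider_type"] == "Physician").astype(float),
            "specialty_primary_care": (truth["prescriber_specialty"] == "Primary care").astype(float),
            "clinic_primary_care": (truth["clinic_type"] == "Primary care").astype(float),
            "clinic_behavioral": (truth["clinic_type"] == "Behavioral health").astype(float),
            "depression": truth["dx_depression"].astype(float),
            "anxiety": truth["dx_anxiety"].astype(float),
            "adhd": truth["dx_adhd"].astype(float),
            "headache": truth["dx_headache"].astype(float),
            "ssri": truth["ssri"].astype(float),
            "phq9_taken": (truth["phq9_severity"] != "Not taken").astype(float),
            "wcv_prior_year": truth["wcv_prior_year"].astype(float),
            "wcv_index_year": truth["wcv_index_year"].astype(float),
            "outpatient_prior_year": truth["outpatient_prior_year"].astype(float),
            "inpatient_prior_year": truth["inpatient_prior_year"].astype(float),
            "ed_prior_year": truth["ed_prior_year"].astype(float),
        },
        index=truth.index,
    )
    return d


def _linear_predictor(design: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(design))
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        if name not in design.columns:
            raise ConfigurationError(f"fill_model_coefficients: unknown covariate {name!r}")
        eta += float(coef) * design[name].to_numpy()
    return eta


def _calibrate_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target_rate."""
    if target_rate >= 1.0 - 1e-12:
        return 40.0
    if target_rate <= 1e-12:
        return -40.0
    return brentq(lambda c: expit(c + eta).mean() - target_rate, -30.0, 30.0, xtol=1e-10)


def generate_population(
    config: SimConfig, vocab: MedicationVocabulary | None = None
) -> SimPopulation:
    """Generate a complete synthetic study population.

    Identical configs (including seed) yield identical tables.
    """
    config.validate()
    if vocab is None:
        vocab = bundled_vocabulary()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    win_start, win_end = year_interval(config.study_year)
    cap_start, cap_end = year_interval(config.capture_year)
    prior_start, prior_end = year_interval(config.study_year - 1)

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])

    # --- patient-level covariates -------------------------------------------------
    age = rng.choice(AGES, size=n, p=AGE_WEIGHTS / AGE_WEIGHTS.sum())
    sex = np.where(rng.random(n) < 0.668, "Female", "Male")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    bmi = np.clip(rng.normal(22.5, 4.5, size=n), 13.0, 45.0).round(1)
    bmi_missing = rng.random(n) < 0.04
    bmi = np.where(bmi_missing, np.nan, bmi)
    adi = rng.choice(
        np.arange(1, 11),
        size=n,
        p=np.array([0.14, 0.18, 0.18, 0.14, 0.11, 0.08, 0.06, 0.05, 0.03, 0.03]),
    )
    payer = rng.choice(PAYER_LEVELS, size=n, p=PAYER_PROBS)
    provider_type = np.where(rng.random(n) < 0.743, "Physician", "Other")
    specialty = rng.choice(SPECIALTY_LEVELS, size=n, p=np.array(SPECIALTY_PROBS) / sum(SPECIALTY_PROBS))
    clinic = rng.choice(CLINIC_LEVELS, size=n, p=np.array(CLINIC_PROBS) / sum(CLINIC_PROBS))
    dx_depression = rng.random(n) < 0.261
    dx_anxiety = rng.random(n) < 0.534
    dx_adhd = rng.random(n) < 0.140
    dx_headache = rng.random(n) < 0.148

    # index prescription drug: SSRIs carry ~85.6% of the mass collectively
    ssri_cuis = sorted(c for c, k in vocab.classes.items() if k == "SSRI")
    other_cuis = sorted(c for c in vocab.rxcuis if c not in set(ssri_cuis))
    drug_cuis = np.array(ssri_cuis + other_cuis)
    drug_p = np.concatenate(
        [
            np.full(len(ssri_cuis), 0.856 / len(ssri_cuis)),
            np.full(len(other_cuis), 0.144 / len(other_cuis)),
        ]
    )
    rx_cui = rng.choice(drug_cuis, size=n, p=drug_p / drug_p.sum())
    is_ssri = np.isin(rx_cui, ssri_cuis)

    phq9_taken = rng.random(n) < 0.494
    phq9_sev = rng.choice(PHQ9_LEVELS, size=n, p=np.array(PHQ9_PROBS) / sum(PHQ9_PROBS))
    lo = np.array([PHQ9_SCORE_RANGES[s][0] for s in phq9_sev])
    hi = np.array([PHQ9_SCORE_RANGES[s][1] for s in phq9_sev])
    phq9_score = lo + rng.integers(0, hi - lo + 1)
    phq9_offset = rng.integers(0, 14, size=n)  # days before index, inside window
    # some untested patients still have an old (out-of-window) score on file
    phq9_stale = (~phq9_taken) & (rng.random(n) < 0.3)
    phq9_stale_offset = rng.integers(15, 120, size=n)
    phq9_severity = np.where(phq9_taken, phq9_sev, "Not taken")

    wcv_prior = rng.random(n) < 0.431
    wcv_index = rng.random(n) < 0.578
    outp_prior = rng.random(n) < 0.766
    inp_prior = rng.random(n) < 0.008
    ed_prior = rng.random(n) < 0.044

    index_date = rng.integers(win_start, win_end + 1, size=n)
    # birth date chosen so that (index - birth) // 365 reproduces age exactly
    birth_date = index_date - (age * 365 + rng.integers(0, 365, size=n))

    prior_use = rng.random(n) < config.prior_use_rate
    has_capture_enc = rng.random(n) >= config.missed_capture_rate

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "rx_id": [f"RX{i:06d}" for i in range(n)],
            "index_date": index_date,
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "bmi": bmi,
            "adi_state_rank": adi,
            "payer": payer,
            "provider_type": provider_type,
            "prescriber_specialty": specialty,
            "clinic_type": clinic,
            "dx_depression": dx_depression,
            "dx_anxiety": dx_anxiety,
            "dx_adhd": dx_adhd,
            "dx_headache": dx_headache,
            "ssri": is_ssri,
            "phq9_severity": phq9_severity,
            "n_rx_at_index": 1,
            "n_rx_in_year": 1,
            "wcv_prior_year": wcv_prior,
            "wcv_index_year": wcv_index,
            "outpatient_prior_year": outp_prior,
            "inpatient_prior_year": inp_prior,
            "ed_prior_year": ed_prior,
            "prior_use": prior_use,
        }
    )

    # --- fill process -------------------------------------------------------------
    design = _design_matrix(truth)
    coeffs = dict(config.fill_model_coefficients)
    eta = _linear_predictor(design, coeffs)
    intercept = coeffs.get("intercept")
    if intercept is None:
        intercept = _calibrate_intercept(eta, 1.0 - config.nonfill_rate_target)
    p_fill = expit(float(intercept) + eta)
    true_fill = rng.random(n) < p_fill

    same_day = rng.random(n) < config.delay_mixture.p_same_day
    tail = rng.geometric(config.delay_mixture.tail_rate, size=n)
    delay = np.where(same_day, 0, tail)
    delay = np.where(true_fill, delay, -1)  # -1 marks "never fills"
    recorded = true_fill & (rng.random(n) >= config.coverage_miss_rate)

    # --- follow-up visit process --------------------------------------------------
    fu_eta = config.followup_log_hr * true_fill.astype(float)
    if config.followup_covariate_log_hrs:
        fu_eta = fu_eta + _linear_predictor(design, config.followup_covariate_log_hrs)
    rate = config.baseline_followup_hazard * np.exp(fu_eta)
    t_raw = rng.exponential(1.0 / rate)
    fu_day = np.ceil(t_raw).astype(int)
    fu_event = fu_day <= config.censor_days
    fu_time = np.where(fu_event, fu_day, config.censor_days)

    truth["intercept_used"] = float(intercept)
    truth["p_fill"] = p_fill
    truth["true_fill"] = true_fill
    truth["true_delay"] = pd.array(np.where(true_fill, delay, np.nan), dtype="Int64")
    truth["recorded"] = recorded
    truth["fill_within_30"] = recorded & true_fill & (delay >= 0) & (delay <= 30)
    truth["followup_time"] = fu_time
    truth["followup_event"] = fu_event

    # --- event tables -------------------------------------------------------------
    patients = truth[
        ["patient_id", "sex", "race_ethnicity", "bmi", "adi_state_rank"]
    ].copy()
    patients.insert(1, "birth_date", birth_date)

    rx_names = np.array([vocab.name_for(c, sorted(vocab.index[c])[0]) for c in rx_cui])
    enc_rows: list[dict] = []
    enc_counter = 0

    def _enc(pid, date, etype, provider_id="PRV-GEN", ptype="Physician", spec="Unknown", clin="Unknown", pay="Private"):
        nonlocal enc_counter
        row = {
            "encounter_id": f"E{enc_counter:07d}",
            "patient_id": pid,
            "date": int(date),
            "enc_type": etype,
            "provider_id": provider_id,
            "provider_type": ptype,
            "prescriber_specialty": spec,
            "clinic_type": clin,
            "payer": pay,
        }
        enc_counter += 1
        enc_rows.append(row)
        return row["encounter_id"]

    index_enc_ids = []
    provider_ids = [f"PRV{i:05d}" for i in range(n)]
    # history / capture encounter dates drawn up front, in bulk, for determinism
    hist_dates = {
        "wcv_prior": rng.integers(prior_start, prior_end + 1, size=n),
        "wcv_index": rng.integers(win_start, win_end + 1, size=n),
        "outp_prior": rng.integers(prior_start, prior_end + 1, size=n),
        "inp_prior": rng.integers(prior_start, prior_end + 1, size=n),
        "ed_prior": rng.integers(prior_start, prior_end + 1, size=n),
        "capture": rng.integers(cap_start, cap_end + 1, size=n),
    }
    for i in range(n):
        pid = patient_ids[i]
        index_enc_ids.append(
            _enc(
                pid,
                index_date[i],
                "outpatient",
                provider_id=provider_ids[i],
                ptype=provider_type[i],
                spec=specialty[i],
                clin=clinic[i],
                pay=payer[i],
            )
        )
        if wcv_prior[i]:
            _enc(pid, hist_dates["wcv_prior"][i], "wellchild")
        if wcv_index[i]:
            _enc(pid, hist_dates["wcv_index"][i], "wellchild")
        if outp_prior[i]:
            _enc(pid, hist_dates["outp_prior"][i], "outpatient")
        if inp_prior[i]:
            _enc(pid, hist_dates["inp_prior"][i], "inpatient")
        if ed_prior[i]:
            _enc(pid, hist_dates["ed_prior"][i], "ed")
        if has_capture_enc[i]:
            _enc(pid, hist_dates["capture"][i], "outpatient")
        if fu_event[i]:
            _enc(
                pid,
                int(index_date[i]) + int(fu_day[i]),
                "outpatient",
                provider_id=provider_ids[i],
                ptype=provider_type[i],
                spec=specialty[i],
                clin=clinic[i],
                pay=payer[i],
            )

    # capture may also happen through follow-up spillover into the capture year
    fu_abs = index_date + fu_time
    captured = has_capture_enc | (fu_event & (fu_abs >= cap_start) & (fu_abs <= cap_end))
    truth["captured"] = captured
    truth["eligible"] = (~prior_use) & captured

    encounters = pd.DataFrame(enc_rows)

    prescriptions = pd.DataFrame(
        {
            "rx_id": truth["rx_id"],
            "patient_id": patient_ids,
            "encounter_id": index_enc_ids,
            "rx_date": index_date,
            "rxcui": rx_cui,
            "drug_name": rx_names,
        }
    )

    # dispensings: recorded index fills, prior-use fills, decoys
    disp_rows: list[dict] = []
    disp_counter = 0

    def _disp(pid, ndc, date, name):
        nonlocal disp_counter
        disp_rows.append(
            {
                "disp_id": f"D{disp_counter:07d}",
                "patient_id": pid,
                "ndc": ndc,
                "fill_date": int(date),
                "drug_name": name,
            }
        )
        disp_counter += 1

    ndc_choice = rng.random(n)  # which of the drug's NDCs gets dispensed
    decoy_flag = rng.random(n) < config.decoy_dispensing_rate
    decoy_date = rng.integers(win_start, win_end + 1, size=n)
    decoy_serial = rng.integers(0, 10**6, size=n)
    prior_date_frac = rng.random(n)
    prior_cui_idx = rng.integers(0, len(drug_cuis), size=n)
    for i in range(n):
        pid = patient_ids[i]
        if recorded[i]:
            ndcs = sorted(vocab.index[rx_cui[i]])
            ndc = ndcs[int(ndc_choice[i] * len(ndcs)) % len(ndcs)]
            _disp(pid, ndc, int(index_date[i]) + int(delay[i]), vocab.name_for(rx_cui[i], ndc))
        if prior_use[i]:
            # a psychotropic fill strictly inside the washout window, before
            # the study window so it cannot itself become an index candidate
            lo_d = int(index_date[i]) - config.washout_days
            hi_d = win_start - 1
            d = lo_d + int(prior_date_frac[i] * max(hi_d - lo_d + 1, 1))
            cui = drug_cuis[prior_cui_idx[i]]
            ndcs = sorted(vocab.index[cui])
            _disp(pid, ndcs[0], d, vocab.name_for(cui, ndcs[0]))
        if decoy_flag[i]:
            # unmappable NDC absent from the crosswalk: linkage and washout
            # scanning must both ignore it
            _disp(pid, f"99999{decoy_serial[i]:06d}", decoy_date[i], "amoxicillin 250 MG oral capsule")
    dispensings = pd.DataFrame(
        disp_rows, columns=["disp_id", "patient_id", "ndc", "fill_date", "drug_name"]
    )

    phq_rows = []
    for i in range(n):
        if phq9_taken[i]:
            phq_rows.append(
                {
                    "patient_id": patient_ids[i],
                    "date": int(index_date[i]) - int(phq9_offset[i]),
                    "score": int(phq9_score[i]),
                }
            )
        elif phq9_stale[i]:
            phq_rows.append(
                {
                    "patient_id": patient_ids[i],
                    "date": int(index_date[i]) - int(phq9_stale_offset[i]),
                    "score": int(phq9_score[i]),
                }
            )
    phq9 = pd.DataFrame(phq_rows, columns=["patient_id", "date", "score"])

    dx_rows = []
    for i in range(n):
        for flag, dx in (
            (dx_depression[i], "depression"),
            (dx_anxiety[i], "anxiety"),
            (dx_adhd[i], "adhd"),
            (dx_headache[i], "headache"),
        ):
            if flag:
                dx_rows.append(
                    {
                        "patient_id": patient_ids[i],
                        "encounter_id": index_enc_ids[i],
                        "date": int(index_date[i]),
                        "dx": dx,
                    }
                )
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "encounter_id", "date", "dx"])

    return SimPopulation(
        patients=patients,
        encounters=encounters,
        prescriptions=prescriptions,
        dispensings=dispensings,
        phq9=phq9,
        diagnoses=diagnoses,
        truth=truth,
        config=config,
    )


def write_fixture(population: SimPopulation, destination: str | Path) -> dict[str, str]:
    """Write one delimited table per event stream plus the config echo.

    Returns the manifest (table name -> path); the tables round-trip
    losslessly through :func:`read_fixture`.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, df in population.tables().items():
        manifest[name] = str(io.write_table(df, name, destination))
    if population.config is not None:
        cfg_path = destination / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(population.config.to_dict(), fh, sort_keys=False)
        manifest["config"] = str(cfg_path)
    io.write_manifest(manifest, destination)
    return manifest


def read_fixture(directory: str | Path) -> SimPopulation:
    directory = Path(directory)
    tables = io.read_tables(directory, TABLE_NAMES)
    cfg = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            cfg = SimConfig.from_dict(yaml.safe_load(fh))
    return SimPopulation(config=cfg, **tables)
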