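"""Per-member contextual covariates.

Assembles the 22 contextual variables used to compare prescription fillers
with non-fillers: demographics (age, sex, race/ethnicity, BMI, ADI state
rank), index-encounter characteristics (payer, provider type, prescriber
specialty, clinic type), diagnoses recorded at the prescribing encounter,
SSRI vs other psychotropic class, PHQ-9 depression-severity category from
the most recent score in the two weeks before the index date, prescription
counts, and service-use history flags over the prior and index calendar
years.
"""

from __future__ import annotations

import pandas as pd

from .dates import year_interval
from .vocabulary import MedicationVocabulary

__all__ = ["PHQ9_CATEGORIES", "categorize_phq9", "build_covariate_table", "COVARIATE_COLUMNS"]

PHQ9_CATEGORIES = ["Nonminimal", "Mild", "Moderate", "Moderately severe", "Severe", "Not taken"]

COVARIATE_COLUMNS = [
    "age",
    "sex",
    "race_ethnicity",
    "bmi",
    "adi_state_rank",
    "payer",
    "provider_type",
    "prescriber_specialty",
    "clinic_type",
    "dx_depression",
    "dx_anxiety",
    "dx_adhd",
    "dx_headache",
    "ssri",
    "phq9_severity",
    "n_rx_at_index",
    "n_rx_in_year",
    "wcv_prior_year",
    "wcv_index_year",
    "outpatient_prior_year",
    "inpatient_prior_year",
    "ed_prior_year",
]


def categorize_phq9(score: int | None) -> str:
    """PHQ-9 severity bin: 0-4 nonminimal, 5-9 mild, 10-14 moderate,
    15-19 moderately severe, 20-27 severe; absent -> "Not taken"."""
    if score is None or pd.isna(score):
        return "Not taken"
    score = int(score)
    if not 0 <= score <= 27:
        raise ValueError(f"PHQ-9 score out of range [0, 27]: {score}")
    if score <= 4:
        return "Nonminimal"
    if score <= 9:
        return "Mild"
    if score <= 14:
        return "Moderate"
    if score <= 19:
        return "Moderately severe"
    return "Severe"


class ReferentialIntegrityError(ValueError):
    pass


def build_covariate_table(
    cohort: pd.DataFrame,
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    phq9: pd.DataFrame,
    prescriptions: pd.DataFrame,
    links: pd.DataFrame,
    vocab: MedicationVocabulary,
    index_year: int = 2021,
    phq9_lookback_days: int = 14,
) -> pd.DataFrame:
    """One row per cohort member with all 22 covariates plus fill_status.

    ``cohort`` needs columns patient_id, rx_id, index_date, age_at_index,
    encounter_id; ``links`` is the labelled linkage table providing
    fill_status = filled_within_cutoff.
    """
    prior_lo, prior_hi = year_interval(index_year - 1)
    index_lo, index_hi = year_interval(index_year)

    pat = patients.set_index(patients["patient_id"].astype(str))
    missing = set(cohort["patient_id"].astype(str)) - set(pat.index)
    if missing:
        raise ReferentialIntegrityError(f"cohort references unknown patient(s): {sorted(missing)[:5]}")

    enc = encounters.copy()
    enc["patient_id"] = enc["patient_id"].astype(str)
    enc_by_id = enc.set_index(enc["encounter_id"].astype(str))

    fill_map = dict(zip(links["rx_id"].astype(str), links["filled_within_cutoff"].astype(bool)))

    rx = prescriptions.copy()
    rx["patient_id"] = rx["patient_id"].astype(str)
    psych_rx = rx[rx["rxcui"].astype(str).isin(set(vocab.index))]
    rx_by_enc = psych_rx.groupby(psych_rx["encounter_id"].astype(str)).size()
    in_year = psych_rx[(psych_rx["rx_date"] >= index_lo) & (psych_rx["rx_date"] <= index_hi)]
    rx_by_patient_year = in_year.groupby("patient_id").size()

    dx = diagnoses.copy()
    if len(dx):
        dx["encounter_id"] = dx["encounter_id"].astype(str)
    phq = phq9.copy()
    if len(phq):
        phq["patient_id"] = phq["patient_id"].astype(str)

    ssri_cuis = {c for c, k in vocab.classes.items() if k == "SSRI"}
    rx_cui_map = dict(zip(rx["rx_id"].astype(str), rx["rxcui"].astype(str)))

    # pre-index (patient, encounter type) pairs per window for O(1) flag lookups
    def _window_pairs(lo: int, hi: int) -> set[tuple[str, str]]:
        sub = enc[(enc["date"] >= lo) & (enc["date"] <= hi)]
        return set(zip(sub["patient_id"], sub["enc_type"].astype(str)))

    prior_pairs = _window_pairs(prior_lo, prior_hi)
    index_pairs = _window_pairs(index_lo, index_hi)

    def service_flag(pid: str, etype: str, lo: int, hi: int) -> bool:
        pairs = prior_pairs if lo == prior_lo else index_pairs
        return (pid, etype) in pairs

    phq_by_patient: dict[str, pd.DataFrame] = {}
    if len(phq):
        phq_by_patient = {pid: g.sort_values("date") for pid, g in phq.groupby("patient_id")}
    dx_by_enc: dict[str, set[str]] = {}
    if len(dx):
        dx_by_enc = {eid: set(g["dx"].astype(str)) for eid, g in dx.groupby("encounter_id")}

    rows = []
    for member in cohort.itertuples(index=False):
        pid = str(member.patient_id)
        rx_id = str(member.rx_id)
        enc_id = str(member.encounter_id)
        index_date = int(member.index_date)
        if rx_id not in fill_map:
            raise ReferentialIntegrityError(f"no linkage row for rx_id {rx_id}")
        if enc_id not in enc_by_id.index:
            raise ReferentialIntegrityError(f"unknown index encounter {enc_id}")
        e = enc_by_id.loc[enc_id]
        p = pat.loc[pid]

        score = None
        g = phq_by_patient.get(pid)
        if g is not None:
            window = g[(g["date"] >= index_date - phq9_lookback_days) & (g["date"] <= index_date)]
            if len(window):
                score = int(window.iloc[-1]["score"])

        dx_at_index = dx_by_enc.get(enc_id, set())

        rows.append(
            {
                "patient_id": pid,
                "rx_id": rx_id,
                "fill_status": fill_map[rx_id],
                "age": int(member.age_at_index),
                "sex": str(p["sex"]),
                "race_ethnicity": str(p["race_ethnicity"]),
                "bmi": float(p["bmi"]) if pd.notna(p["bmi"]) else float("nan"),
                "adi_state_rank": int(p["adi_state_rank"]),
                "payer": str(e["payer"]),
                "provider_type": str(e["provider_type"]),
                "prescriber_specialty": str(e["prescriber_specialty"]),
                "clinic_type": str(e["clinic_type"]),
                "dx_depression": "depression" in dx_at_index,
                "dx_anxiety": "anxiety" in dx_at_index,
                "dx_adhd": "adhd" in dx_at_index,
                "dx_headache": "headache" in dx_at_index,
                "ssri": rx_cui_map.get(rx_id, "") in ssri_cuis,
                "phq9_severity": categorize_phq9(score),
                "n_rx_at_index": int(rx_by_enc.get(enc_id, 0)),
                "n_rx_in_year": int(rx_by_patient_year.get(pid, 0)),
                "wcv_prior_year": service_flag(pid, "wellchild", prior_lo, prior_hi),
                "wcv_index_year": service_flag(pid, "wellchild", index_lo, index_hi),
                "outpatient_prior_year": service_flag(pid, "outpatient", prior_lo, prior_hi),
                "inpatient_prior_year": service_flag(pid, "inpatient", prior_lo, prior_hi),
                "ed_prior_year": service_flag(pid, "ed", prior_lo, prior_hi),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "rx_id", "fill_status"] + COVARIATE_COLUMNS)
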