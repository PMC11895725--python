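"""New-user cohort construction.

Cohort entry is the patient's earliest in-window psychotropic prescription
(the index), subject to: a washout lookback free of any psychotropic
prescription or pharmacy fill, age under 18 at index, an outpatient index
encounter, and — because dispensing feeds only update when the patient
returns to the health system — a data-completeness filter requiring at
least one encounter of any type in the capture window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dates import age_years
from .vocabulary import MedicationVocabulary

__all__ = ["IndexEvent", "AttritionLog", "identify_new_users", "apply_completeness_filter", "build_cohort"]


class ReferentialIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    rx_id: str
    index_date: int
    age_at_index: int
    prescriber_id: str
    encounter_id: str


@dataclass
class AttritionLog:
    stages: list[tuple[str, int, int]]

    def record(self, stage: str, n_before: int, n_after: int) -> None:
        self.stages.append((stage, n_before, n_after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_before", "n_after"])


def _events_frame(events: list[IndexEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "rx_id": [e.rx_id for e in events],
            "index_date": [e.index_date for e in events],
            "age_at_index": [e.age_at_index for e in events],
            "prescriber_id": [e.prescriber_id for e in events],
            "encounter_id": [e.encounter_id for e in events],
        }
    )


def identify_new_users(
    prescriptions: pd.DataFrame,
    dispensings: pd.DataFrame,
    patients: pd.DataFrame,
    study_window: tuple[int, int],
    washout_days: int = 365,
    vocab: MedicationVocabulary | None = None,
    encounters: pd.DataFrame | None = None,
    attrition: AttritionLog | None = None,
) -> list[IndexEvent]:
    """One index event per patient: earliest in-window psychotropic
    prescription, washed out and age-restricted.

    A patient is excluded when any psychotropic prescription or dispensing
    falls in ``[index_date - washout_days, index_date)`` (the index date
    itself is exempt), or when age at index is 18 or older.  When ``vocab``
    is given, only RxCUIs/NDCs it knows count as psychotropic; otherwise
    every record in the tables does.  When ``encounters`` is given, the
    index encounter must be an outpatient visit.
    """
    if washout_days < 1:
        raise ValueError("washout_days must be >= 1")
    win_start, win_end = study_window
    birth = dict(zip(patients["patient_id"].astype(str), patients["birth_date"].astype(int)))

    rx = prescriptions.copy()
    rx["patient_id"] = rx["patient_id"].astype(str)
    missing = set(rx["patient_id"]) - set(birth)
    if missing:
        raise ReferentialIntegrityError(
            f"prescriptions reference unknown patient(s): {sorted(missing)[:5]}"
        )
    if vocab is not None:
        rx_psych = rx[rx["rxcui"].astype(str).isin(set(vocab.index))]
    else:
        rx_psych = rx
    disp = dispensings.copy()
    if len(disp):
        disp["patient_id"] = disp["patient_id"].astype(str)
        if vocab is not None:
            disp = disp[disp["ndc"].astype(str).isin(vocab.all_ndcs)]

    enc_type: dict[str, str] = {}
    if encounters is not None and len(encounters):
        enc_type = dict(
            zip(encounters["encounter_id"].astype(str), encounters["enc_type"].astype(str))
        )

    in_window = rx_psych[(rx_psych["rx_date"] >= win_start) & (rx_psych["rx_date"] <= win_end)]
    candidates = (
        in_window.sort_values(["rx_date", "rx_id"], kind="mergesort")
        .groupby("patient_id", sort=True)
        .head(1)
    )
    n0 = len(candidates)

    rx_dates = rx_psych.groupby("patient_id")["rx_date"]
    rx_hist = {pid: sorted(g) for pid, g in rx_dates}
    disp_hist: dict[str, list[int]] = {}
    if len(disp):
        disp_hist = {pid: sorted(g) for pid, g in disp.groupby("patient_id")["fill_date"]}

    def washed_out(pid: str, index_date: int) -> bool:
        lo = index_date - washout_days
        for dates in (rx_hist.get(pid, []), disp_hist.get(pid, [])):
            for d in dates:
                if lo <= d < index_date:
                    return True
        return False

    after_washout = [
        c for c in candidates.itertuples(index=False)
        if not washed_out(str(c.patient_id), int(c.rx_date))
    ]
    n1 = len(after_washout)

    events: list[IndexEvent] = []
    for c in after_washout:
        pid = str(c.patient_id)
        age = age_years(birth[pid], int(c.rx_date))
        if age >= 18:
            continue
        enc_id = str(getattr(c, "encounter_id", ""))
        if enc_type and enc_type.get(enc_id, "outpatient") != "outpatient":
            continue
        events.append(
            IndexEvent(
                patient_id=pid,
                rx_id=str(c.rx_id),
                index_date=int(c.rx_date),
                age_at_index=age,
                prescriber_id="",
                encounter_id=enc_id,
            )
        )
    if attrition is not None:
        attrition.record("washout", n0, n1)
        attrition.record("age_and_outpatient", n1, len(events))
    return events


def apply_completeness_filter(
    index_events: list[IndexEvent],
    encounters: pd.DataFrame,
    capture_window: tuple[int, int],
    attrition: AttritionLog | None = None,
) -> list[IndexEvent]:
    """Keep patients with >= 1 encounter of any type inside capture_window."""
    lo, hi = capture_window
    captured: set[str] = set()
    if len(encounters):
        mask = (encounters["date"] >= lo) & (encounters["date"] <= hi)
        captured = set(encounters.loc[mask, "patient_id"].astype(str))
    kept = [e for e in index_events if e.patient_id in captured]
    if attrition is not None:
        attrition.record("completeness", len(index_events), len(kept))
    return kept


def build_cohort(
    prescriptions: pd.DataFrame,
    dispensings: pd.DataFrame,
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    study_window: tuple[int, int],
    capture_window: tuple[int, int],
    washout_days: int = 365,
    vocab: MedicationVocabulary | None = None,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Full filter chain (washout -> age/outpatient -> completeness) with a
    CONSORT-style attrition log."""
    log = AttritionLog(stages=[])
    events = identify_new_users(
        prescriptions,
        dispensings,
        patients,
        study_window,
        washout_days=washout_days,
        vocab=vocab,
        encounters=encounters,
        attrition=log,
    )
    events = apply_completeness_filter(events, encounters, capture_window, attrition=log)
    # prescriber from the index encounter
    frame = _events_frame(events)
    if len(frame) and "provider_id" in encounters.columns:
        prov = dict(zip(encounters["encounter_id"].astype(str), encounters["provider_id"].astype(str)))
        frame["prescriber_id"] = frame["encounter_id"].map(prov).fillna("")
    return frame, log
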