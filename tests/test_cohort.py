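"""New-user cohort: washout, age restriction, completeness filter."""

import pandas as pd
import pytest

from rxlink.dates import year_interval
from rxlink.cohort import (
    AttritionLog,
    ReferentialIntegrityError,
    apply_completeness_filter,
    build_cohort,
    identify_new_users,
)

WINDOW = (366, 730)  # study window as day offsets
CAPTURE = (731, 1095)


def _patients(rows):
    return pd.DataFrame(rows, columns=["patient_id", "birth_date", "sex", "race_ethnicity", "bmi", "adi_state_rank"])


def _rx(rows):
    return pd.DataFrame(rows, columns=["rx_id", "patient_id", "encounter_id", "rx_date", "rxcui", "drug_name"])


def _disp(rows):
    return pd.DataFrame(rows, columns=["disp_id", "patient_id", "ndc", "fill_date", "drug_name"])


def _age_birth(age_years, index_date):
    return index_date - age_years * 365 - 100


def test_prior_fill_within_washout_excludes():
    patients = _patients([("p", _age_birth(14, 400), "Female", "Other", 20.0, 3)])
    rx = _rx([("r1", "p", "e1", 400, "A", "")])
    disp = _disp([("d1", "p", "00000000001", 100, "")])  # 300 days before index
    events = identify_new_users(rx, disp, patients, WINDOW, washout_days=365)
    assert events == []


def test_prior_prescription_within_washout_excludes():
    patients = _patients([("p", _age_birth(14, 500), "Female", "Other", 20.0, 3)])
    rx = _rx([("r0", "p", "e0", 200, "A", ""), ("r1", "p", "e1", 500, "A", "")])
    # r0 is out of window so r1 is the candidate index, but r0 violates washout
    events = identify_new_users(rx, _disp([]), patients, WINDOW, washout_days=365)
    assert events == []


def test_clean_single_rx_included():
    patients = _patients([("p", _age_birth(12, 400), "Male", "Other", 20.0, 3)])
    rx = _rx([("r1", "p", "e1", 400, "A", "")])
    (event,) = identify_new_users(rx, _disp([]), patients, WINDOW)
    assert (event.rx_id, event.index_date, event.age_at_index) == ("r1", 400, 12)


def test_age_18_at_index_excluded():
    patients = _patients(
        [
            ("adult", 400 - 18 * 365, "Female", "Other", 20.0, 3),
            ("teen", 400 - 18 * 365 + 1, "Female", "Other", 20.0, 3),
        ]
    )
    rx = _rx([("r1", "adult", "e1", 400, "A", ""), ("r2", "teen", "e2", 400, "A", "")])
    events = identify_new_users(rx, _disp([]), patients, WINDOW)
    assert [e.patient_id for e in events] == ["teen"]


def test_earliest_in_window_rx_is_index():
    patients = _patients([("p", _age_birth(10, 400), "Male", "Other", 20.0, 3)])
    rx = _rx([("r2", "p", "e2", 500, "A", ""), ("r1", "p", "e1", 420, "A", "")])
    events = identify_new_users(rx, _disp([]), patients, WINDOW, washout_days=10)
    assert [e.rx_id for e in events] == ["r1"]


def test_unknown_patient_is_referential_error():
    rx = _rx([("r1", "ghost", "e1", 400, "A", "")])
    with pytest.raises(ReferentialIntegrityError, match="ghost"):
        identify_new_users(rx, _disp([]), _patients([]), WINDOW)


def _enc(rows):
    return pd.DataFrame(
        rows,
        columns=["encounter_id", "patient_id", "date", "enc_type", "provider_id",
                 "provider_type", "prescriber_specialty", "clinic_type", "payer"],
    )


def _event(pid="p", rx="r1", date=400):
    from rxlink.cohort import IndexEvent

    return IndexEvent(pid, rx, date, 12, "", "e1")


def test_completeness_requires_capture_window_encounter():
    kept = apply_completeness_filter(
        [_event("a"), _event("b")],
        _enc(
            [
                ("x1", "a", 800, "inpatient", "q", "Physician", "Unknown", "Unknown", "Private"),
                ("x2", "b", 700, "outpatient", "q", "Physician", "Unknown", "Unknown", "Private"),
            ]
        ),
        CAPTURE,
    )
    # an inpatient encounter counts; b's visit predates the capture window
    assert [e.patient_id for e in kept] == ["a"]


def test_empty_encounters_empty_cohort():
    assert apply_completeness_filter([_event()], _enc([]), CAPTURE) == []


def test_attrition_counts_monotone(small_population, vocab):
    pop = small_population
    frame, log = build_cohort(
        pop.prescriptions,
        pop.dispensings,
        pop.patients,
        pop.encounters,
        year_interval(2021),
        year_interval(2022),
        vocab=vocab,
    )
    stages = log.to_frame()
    assert list(stages["stage"]) == ["washout", "age_and_outpatient", "completeness"]
    assert (stages["n_after"] <= stages["n_before"]).all()
    assert stages["n_after"].iloc[-1] == len(frame)
    assert frame["patient_id"].is_unique


def test_cohort_membership_matches_generator_truth(small_population, vocab):
    pop = small_population
    frame, _ = build_cohort(
        pop.prescriptions,
        pop.dispensings,
        pop.patients,
        pop.encounters,
        year_interval(2021),
        year_interval(2022),
        vocab=vocab,
    )
    expected = set(pop.truth.loc[pop.truth["eligible"], "patient_id"])
    assert set(frame["patient_id"]) == expected
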