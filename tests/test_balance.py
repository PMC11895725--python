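"""Standardized mean difference routines and the balance table."""

import numpy as np
import pandas as pd
import pytest

from rxlink.balance import (
    balance_table,
    smd_binary,
    smd_continuous,
    smd_multicategory,
)


def test_continuous_unit_and_zero_cases():
    assert smd_continuous(1, 1, 0, 1) == pytest.approx(1.0)
    assert smd_continuous(5, 2, 5, 3) == pytest.approx(0.0)


def test_continuous_backsolved_fixture():
    # means 21.62 vs 22.86 with equal SDs chosen so the pooled SD is 7.561
    assert round(smd_continuous(21.62, 7.561, 22.86, 7.561), 3) == 0.164


def test_continuous_rejects_bad_sd():
    with pytest.raises(ValueError):
        smd_continuous(1, 0, 2, 1)


def test_binary_zero_for_identical_groups():
    assert smd_binary(500, 1000, 500, 1000) == 0.0
    assert smd_binary(0, 10, 0, 10) == 0.0  # 0/0 resolved to 0


def test_binary_rejects_impossible_counts():
    with pytest.raises(ValueError):
        smd_binary(11, 10, 1, 10)


def test_multicategory_identical_is_zero():
    assert smd_multicategory([10, 20, 30], [1, 2, 3]) == pytest.approx(0.0)


def test_multicategory_k2_equals_binary():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n1, n2 = rng.integers(5, 200, size=2)
        x1 = rng.integers(1, n1)
        x2 = rng.integers(1, n2)
        a = smd_multicategory([x1, n1 - x1], [x2, n2 - x2])
        b = smd_binary(int(x1), int(n1), int(x2), int(n2))
        assert a == pytest.approx(b, rel=1e-9)


def test_multicategory_permutation_invariant():
    rng = np.random.default_rng(1)
    c1 = rng.integers(1, 100, size=4)
    c2 = rng.integers(1, 100, size=4)
    base = smd_multicategory(c1, c2)
    for _ in range(10):
        perm = rng.permutation(4)
        assert smd_multicategory(c1[perm], c2[perm]) == pytest.approx(base, rel=1e-9)


def test_multicategory_rejects_length_mismatch():
    with pytest.raises(ValueError):
        smd_multicategory([1, 2], [1, 2, 3])


def _covariate_frame(n, rng, shift_col=None):
    fill = np.concatenate([np.ones(n // 2, bool), np.zeros(n // 2, bool)])
    df = pd.DataFrame(
        {
            "fill_status": fill,
            "age": rng.integers(5, 18, size=n),
            "bmi": rng.normal(22, 4, size=n),
            "adi_state_rank": rng.integers(1, 11, size=n),
            "n_rx_at_index": 1,
            "n_rx_in_year": rng.integers(1, 4, size=n),
            "sex": rng.choice(["Female", "Male"], size=n),
            "race_ethnicity": rng.choice(["NH White", "NH Black", "Other"], size=n),
            "payer": rng.choice(["Public", "Private"], size=n),
            "provider_type": rng.choice(["Physician", "Other"], size=n),
            "prescriber_specialty": rng.choice(["Primary care", "Other"], size=n),
            "clinic_type": rng.choice(["Primary care", "Other"], size=n),
            "phq9_severity": rng.choice(["Not taken", "Mild"], size=n),
            "dx_depression": rng.random(n) < 0.3,
            "dx_anxiety": rng.random(n) < 0.5,
            "dx_adhd": rng.random(n) < 0.2,
            "dx_headache": rng.random(n) < 0.1,
            "ssri": rng.random(n) < 0.8,
            "wcv_prior_year": rng.random(n) < 0.4,
            "wcv_index_year": rng.random(n) < 0.5,
            "outpatient_prior_year": rng.random(n) < 0.7,
            "inpatient_prior_year": rng.random(n) < 0.05,
            "ed_prior_year": rng.random(n) < 0.05,
        }
    )
    if shift_col is not None:
        # force a large group difference in a single covariate
        df.loc[df["fill_status"], shift_col] = rng.random(n // 2) < 0.85
        df.loc[~df["fill_status"], shift_col] = rng.random(n - n // 2) < 0.35
    return df


def test_identical_groups_all_smds_zero():
    rng = np.random.default_rng(5)
    half = _covariate_frame(400, rng).drop(columns="fill_status")
    df = pd.concat([half, half], ignore_index=True)
    df["fill_status"] = [True] * 400 + [False] * 400
    report = balance_table(df)
    assert (report.to_frame()["smd"] == 0).all()
    assert report.flagged() == []


def test_forced_difference_is_flagged():
    rng = np.random.default_rng(6)
    df = _covariate_frame(4000, rng, shift_col="dx_anxiety")
    report = balance_table(df)
    assert "dx_anxiety" in report.flagged()
    frame = report.to_frame().set_index("covariate")
    # only the forced covariate shows a large imbalance
    others = frame.drop(index="dx_anxiety")
    assert frame.loc["dx_anxiety", "smd"] > 0.3
    assert (others["smd"] < 0.3).all()


def test_empty_group_rejected():
    rng = np.random.default_rng(7)
    df = _covariate_frame(100, rng)
    df["fill_status"] = True
    with pytest.raises(ValueError):
        balance_table(df)
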