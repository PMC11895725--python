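"""Linkage: nearest-after matching, one-to-one discipline, cutoff labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rxlink.linkage import apply_fill_cutoff, days_to_fill_ecdf, match_fills, time_to_fill_curve
from rxlink.vocabulary import MedicationVocabulary, CrosswalkEntry


def _vocab(mapping):
    """mapping: rxcui -> list of ndcs (names all share one ingredient)."""
    entries = [
        CrosswalkEntry(rxcui=c, ndc=n, drug_name="drugx 10 MG", normalized_name="drugx 10 mg")
        for c, ndcs in mapping.items()
        for n in ndcs
    ]
    return MedicationVocabulary(entries)


def _rx(rows):
    return pd.DataFrame(rows, columns=["rx_id", "patient_id", "encounter_id", "rx_date", "rxcui", "drug_name"])


def _disp(rows):
    return pd.DataFrame(rows, columns=["disp_id", "patient_id", "ndc", "fill_date", "drug_name"])


V = _vocab({"A": ["00000000001"], "B": ["00000000002"]})


def test_nearest_fill_after_prescription_wins():
    rx = _rx([("r1", "p", "e1", 0, "A", "drugx 10 MG")])
    disp = _disp(
        [("d1", "p", "00000000001", 40, "drugx 10 MG"), ("d2", "p", "00000000001", 2, "drugx 10 MG")]
    )
    res = match_fills(rx, disp, V, search_horizon_days=365)
    (link,) = res.links
    assert (link.disp_id, link.days_to_fill) == ("d2", 2)
    assert res.unmatched_dispensings == {"d1"}


def test_no_compatible_dispensing_leaves_rx_unmatched():
    rx = _rx([("r1", "p", "e1", 0, "A", "drugx 10 MG")])
    disp = _disp([("d1", "p", "00000000002", 2, "drugx 10 MG")])  # NDC of drug B
    (link,) = match_fills(rx, disp, V, 365).links
    assert link.disp_id is None and link.days_to_fill is None


def test_earlier_prescription_claims_shared_dispensing():
    rx = _rx(
        [("r2", "p", "e2", 10, "A", "drugx 10 MG"), ("r1", "p", "e1", 0, "A", "drugx 10 MG")]
    )
    disp = _disp([("d1", "p", "00000000001", 12, "drugx 10 MG")])
    res = match_fills(rx, disp, V, 365)
    by_id = {l.rx_id: l for l in res.links}
    assert by_id["r1"].days_to_fill == 12  # day-0 rx processed first
    assert by_id["r2"].disp_id is None  # dispensing already assigned


def test_duplicate_ids_rejected():
    rx = _rx([("r1", "p", "e", 0, "A", ""), ("r1", "p", "e", 1, "A", "")])
    with pytest.raises(ValueError, match="rx_id"):
        match_fills(rx, _disp([]), V, 365)


# --- exhaustive oracle -------------------------------------------------------


def _oracle_assignment(rx_df, disp_df, vocab, horizon):
    """Lexicographically earliest feasible one-to-one assignment, by brute
    force over all injective candidate selections, prescriptions taken in
    (rx_date, rx_id) order.  None ranks after any real candidate."""
    order = rx_df.sort_values(["rx_date", "rx_id"]).itertuples(index=False)
    rx_list = list(order)
    cand_lists = []
    for rx in rx_list:
        ndcs = vocab.ndcs_for_rxcui(str(rx.rxcui), rx.drug_name or "")
        cands = [
            (int(d.fill_date) - int(rx.rx_date), str(d.disp_id))
            for d in disp_df.itertuples(index=False)
            if str(d.patient_id) == str(rx.patient_id)
            and str(d.ndc) in ndcs
            and 0 <= int(d.fill_date) - int(rx.rx_date) <= horizon
        ]
        cand_lists.append(sorted(cands) + [None])
    best = None
    for combo in itertools.product(*cand_lists):
        used = [c[1] for c in combo if c is not None]
        if len(used) != len(set(used)):
            continue
        key = tuple((c if c is not None else (10**9, "~")) for c in combo)
        if best is None or key < best[0]:
            best = (key, combo)
    return {rx.rx_id: c for rx, c in zip(rx_list, best[1])}


def _random_instance(rng, n_rx, n_disp):
    cuis = ["A", "B"]
    rx = _rx(
        [
            (f"r{i}", f"p{rng.integers(0, 2)}", f"e{i}", int(rng.integers(0, 30)), rng.choice(cuis), "drugx 10 MG")
            for i in range(n_rx)
        ]
    )
    ndcs = {"A": "00000000001", "B": "00000000002"}
    disp = _disp(
        [
            (f"d{i}", f"p{rng.integers(0, 2)}", ndcs[rng.choice(cuis)], int(rng.integers(0, 40)), "drugx 10 MG")
            for i in range(n_disp)
        ]
    )
    return rx, disp


@pytest.mark.parametrize("seed", range(25))
def test_greedy_equals_exhaustive_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    rx, disp = _random_instance(rng, int(rng.integers(1, 7)), int(rng.integers(0, 7)))
    res = match_fills(rx, disp, V, search_horizon_days=15)
    expected = _oracle_assignment(rx, disp, V, 15)
    got = {
        l.rx_id: ((l.days_to_fill, l.disp_id) if l.disp_id is not None else None)
        for l in res.links
    }
    assert got == expected
    assigned = [l.disp_id for l in res.links if l.disp_id is not None]
    assert len(assigned) == len(set(assigned))  # one-to-one


def test_raising_cutoff_never_unfills():
    rng = np.random.default_rng(7)
    rx, disp = _random_instance(rng, 6, 6)
    res = match_fills(rx, disp, V, search_horizon_days=40)
    counts = [
        sum(l.filled_within_cutoff for l in apply_fill_cutoff(res, c).links)
        for c in range(1, 41)
    ]
    assert counts == sorted(counts)


@pytest.mark.parametrize(
    "days,filled", [(0, True), (30, True), (35, False), (None, False)]
)
def test_cutoff_labelling(days, filled):
    rx = _rx([("r1", "p", "e1", 0, "A", "drugx 10 MG")])
    disp = _disp([]) if days is None else _disp([("d1", "p", "00000000001", days, "drugx 10 MG")])
    res = apply_fill_cutoff(match_fills(rx, disp, V, 365), cutoff_days=30)
    assert res.links[0].filled_within_cutoff is filled


def test_time_to_fill_curve_closed_form():
    rx = _rx([(f"r{i}", "p", "e", 0, "A", "drugx 10 MG") for i in range(3)])
    disp = _disp(
        [
            ("d1", "p", "00000000001", 0, "drugx 10 MG"),
            ("d2", "p", "00000000001", 0, "drugx 10 MG"),
            ("d3", "p", "00000000001", 1, "drugx 10 MG"),
        ]
    )
    res = match_fills(rx, disp, V, 365)
    curve = time_to_fill_curve(res, observation_end_days=30)
    assert curve.survival_at(0) == pytest.approx(1 / 3)
    assert curve.survival_at(1) == pytest.approx(0.0)


def test_time_to_fill_all_censored():
    rx = _rx([("r1", "p", "e", 0, "A", "x"), ("r2", "p", "e2", 0, "A", "x")])
    curve = time_to_fill_curve(match_fills(rx, _disp([]), V, 365), observation_end_days=30)
    assert curve.survival_at(29) == 1.0


def test_ecdf_diagnostic_monotone(small_population, vocab):
    pop = small_population
    res = match_fills(pop.prescriptions, pop.dispensings, vocab, 365)
    ecdf = days_to_fill_ecdf(res)
    assert ecdf["cum_fraction"].is_monotonic_increasing
    assert ecdf["cum_fraction"].iloc[-1] == pytest.approx(1.0)
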