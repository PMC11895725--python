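"""Prescription-to-dispensing record linkage.

Prescriptions (RxCUI-coded) and pharmacy dispensings (NDC-coded) share no
key, so linkage proceeds by ontology compatibility plus temporal proximity:
a dispensing is a candidate for a prescription when it belongs to the same
patient, its NDC is among the crosswalk's name-validated NDCs for the
prescription's RxCUI, and its fill date falls on or after the prescription
date within a search horizon.  Each prescription takes the earliest such
candidate, and each dispensing is assigned to at most one prescription —
processing prescriptions in ascending date order — so the same fill can
never count for two prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .vocabulary import MedicationVocabulary

__all__ = [
    "LinkedFill",
    "LinkageResult",
    "match_fills",
    "apply_fill_cutoff",
    "time_to_fill_curve",
    "days_to_fill_ecdf",
]


@dataclass(frozen=True)
class LinkedFill:
    rx_id: str
    disp_id: str | None
    days_to_fill: int | None
    filled_within_cutoff: bool = False

    def __post_init__(self) -> None:
        if (self.disp_id is None) != (self.days_to_fill is None):
            raise ValueError("disp_id and days_to_fill must be present together")
        if self.days_to_fill is not None and self.days_to_fill < 0:
            raise ValueError("days_to_fill must be non-negative")


@dataclass
class LinkageResult:
    links: list[LinkedFill]
    unmatched_dispensings: set[str]
    cutoff_days: int | None = None
    diagnostics: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rx_id": [l.rx_id for l in self.links],
                "disp_id": [l.disp_id for l in self.links],
                "days_to_fill": pd.array(
                    [l.days_to_fill for l in self.links], dtype="Int64"
                ),
                "filled_within_cutoff": [l.filled_within_cutoff for l in self.links],
            }
        )


def _validate_unique(values: pd.Series, label: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {label}: {sorted(set(dup))[:5]}")


def match_fills(
    prescriptions: pd.DataFrame,
    dispensings: pd.DataFrame,
    vocab: MedicationVocabulary,
    search_horizon_days: int = 365,
) -> LinkageResult:
    """Greedy earliest-prescription-first, one-to-one nearest-fill matching.

    Prescriptions are processed in ascending (rx_date, rx_id) order.  For
    each, the unassigned same-patient dispensing with compatible NDC and the
    smallest fill_date >= rx_date within the horizon is assigned (ties broken
    by smallest disp_id); days_to_fill = fill_date - rx_date, so a same-day
    fill is day 0.
    """
    if search_horizon_days < 1:
        raise ValueError("search_horizon_days must be >= 1")
    _validate_unique(prescriptions["rx_id"], "rx_id")
    if len(dispensings):
        _validate_unique(dispensings["disp_id"], "disp_id")

    diagnostics = {"candidates_evaluated": 0, "name_validation_rejections": 0, "unknown_rxcuis": 0}

    disp_by_patient: dict[str, list[tuple[int, str, str]]] = {}
    for row in dispensings.itertuples(index=False):
        disp_by_patient.setdefault(str(row.patient_id), []).append(
            (int(row.fill_date), str(row.disp_id), str(row.ndc))
        )
    for lst in disp_by_patient.values():
        lst.sort()

    assigned: set[str] = set()
    links: list[LinkedFill] = []
    order = prescriptions.sort_values(["rx_date", "rx_id"], kind="mergesort")
    for rx in order.itertuples(index=False):
        rxcui = str(rx.rxcui)
        drug_name = getattr(rx, "drug_name", "")
        if pd.isna(drug_name):
            drug_name = ""
        if rxcui not in vocab.index:
            diagnostics["unknown_rxcuis"] += 1
            links.append(LinkedFill(str(rx.rx_id), None, None))
            continue
        valid_ndcs = vocab.ndcs_for_rxcui(rxcui, drug_name)
        all_ndcs = vocab.index[rxcui]
        rx_date = int(rx.rx_date)
        best: tuple[int, str] | None = None
        for fill_date, disp_id, ndc in disp_by_patient.get(str(rx.patient_id), []):
            if fill_date < rx_date:
                continue
            if fill_date - rx_date > search_horizon_days:
                break
            if disp_id in assigned:
                continue
            diagnostics["candidates_evaluated"] += 1
            if ndc not in valid_ndcs:
                if ndc in all_ndcs:
                    diagnostics["name_validation_rejections"] += 1
                continue
            best = (fill_date, disp_id)
            break  # list is date-sorted: first acceptable is the nearest
        if best is None:
            links.append(LinkedFill(str(rx.rx_id), None, None))
        else:
            assigned.add(best[1])
            links.append(LinkedFill(str(rx.rx_id), best[1], best[0] - rx_date))

    # restore input prescription order
    pos = {rid: i for i, rid in enumerate(prescriptions["rx_id"].astype(str))}
    links.sort(key=lambda l: pos[l.rx_id])
    unmatched = set(dispensings["disp_id"].astype(str)) - assigned if len(dispensings) else set()
    return LinkageResult(links=links, unmatched_dispensings=unmatched, diagnostics=diagnostics)


def apply_fill_cutoff(result: LinkageResult, cutoff_days: int = 30) -> LinkageResult:
    """Label each link as a valid fill iff days_to_fill <= cutoff_days.

    Matches beyond the cutoff keep their disp_id but are labelled not
    filled; unmatched prescriptions are not filled.
    """
    if cutoff_days < 1:
        raise ValueError("cutoff_days must be >= 1")
    links = [
        LinkedFill(
            l.rx_id,
            l.disp_id,
            l.days_to_fill,
            l.days_to_fill is not None and l.days_to_fill <= cutoff_days,
        )
        for l in result.links
    ]
    return LinkageResult(
        links=links,
        unmatched_dispensings=set(result.unmatched_dispensings),
        cutoff_days=cutoff_days,
        diagnostics=dict(result.diagnostics),
    )


def time_to_fill_curve(result: LinkageResult, observation_end_days: int = 365):
    """Kaplan-Meier curve of days from prescription to fill.

    Fill = event at days_to_fill; never-matched prescriptions are censored
    at ``observation_end_days``.
    """
    from .survival import km_estimator

    times, events = [], []
    for l in result.links:
        if l.days_to_fill is not None:
            if l.days_to_fill > observation_end_days:
                raise ValueError("observation_end_days below an observed days_to_fill")
            times.append(l.days_to_fill)
            events.append(True)
        else:
            times.append(observation_end_days)
            events.append(False)
    return km_estimator(times, events)


def days_to_fill_ecdf(result: LinkageResult) -> pd.DataFrame:
    """Empirical CDF of observed days_to_fill among matched prescriptions.

    Diagnostic for choosing the valid-fill cutoff by eye (the inflection
    point of the fill curve); no automated detection is attempted.
    """
    days = sorted(l.days_to_fill for l in result.links if l.days_to_fill is not None)
    if not days:
        return pd.DataFrame(columns=["days_to_fill", "cum_fraction"])
    s = pd.Series(days)
    ecdf = s.value_counts().sort_index().cumsum() / len(s)
    return pd.DataFrame({"days_to_fill": ecdf.index, "cum_fraction": ecdf.values})
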