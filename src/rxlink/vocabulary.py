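"""Medication crosswalk between the prescribing and dispensing ontologies.

EHR prescriptions carry RxNorm concept unique identifiers (RxCUIs), which
name a drug entity (ingredient + strength + dose form).  Pharmacy dispensing
records carry National Drug Codes (NDCs), which are package-level: one RxCUI
fans out to many NDCs across manufacturers and package sizes.  The
:class:`MedicationVocabulary` holds the RxCUI -> NDC crosswalk and performs
the drug-name validation used to reject spurious code-level matches.

A synthetic stand-in crosswalk covering 21 common pediatric psychotropic
ingredients ships with the package (``data/synthetic_crosswalk.csv``); any
crosswalk with columns ``rxcui, ndc, drug_name`` can be loaded in its place.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CrosswalkEntry",
    "MedicationVocabulary",
    "SchemaError",
    "load_crosswalk",
    "bundled_vocabulary",
    "normalize_ndc",
    "normalize_name",
    "ingredient_token",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


_NON_ALNUM = re.compile(r"[^a-z0-9. ]+")


def normalize_name(drug_name: str) -> str:
    """Lowercase and strip punctuation from a drug name. Idempotent."""
    s = str(drug_name).lower()
    s = _NON_ALNUM.sub(" ", s)
    return " ".join(s.split())


def ingredient_token(drug_name: str) -> str:
    """First purely alphabetic token of the normalized name.

    For names in either ontology ("Sertraline 25 MG tablet",
    "SERTRALINE HCL 25MG TAB") this is the active-ingredient word, which is
    the stable part across the RxCUI and NDC naming conventions.
    """
    for tok in normalize_name(drug_name).split():
        if tok.isalpha():
            return tok
    return ""


def normalize_ndc(ndc: str) -> str:
    """Normalize an NDC to the 11-digit 5-4-2 form.

    Hyphenated 10-digit codes (4-4-2, 5-3-2, 5-4-1) get their short segment
    zero-padded. Bare strings must already contain exactly 11 digits.

    Raises :class:`ValueError` for non-digit content or unnormalizable shapes.
    """
    s = str(ndc).strip()
    if "-" in s:
        parts = s.split("-")
        if len(parts) != 3:
            raise ValueError(f"NDC {ndc!r}: expected 3 hyphenated segments")
        widths = (5, 4, 2)
        out = []
        for part, w in zip(parts, widths):
            if not part.isdigit():
                raise ValueError(f"NDC {ndc!r}: non-digit segment {part!r}")
            if len(part) > w:
                raise ValueError(f"NDC {ndc!r}: segment {part!r} longer than {w}")
            out.append(part.zfill(w))
        return "".join(out)
    if not s.isdigit() or len(s) != 11:
        raise ValueError(f"NDC {ndc!r}: expected 11 digits or a hyphenated code")
    return s


@dataclass(frozen=True)
class CrosswalkEntry:
    rxcui: str
    ndc: str  # 11-digit normalized
    drug_name: str
    normalized_name: str


@dataclass
class MedicationVocabulary:
    """RxCUI -> NDC crosswalk with name-validated lookup."""

    entries: list[CrosswalkEntry]
    classes: dict[str, str] = field(default_factory=dict)  # rxcui -> drug class
    invalid_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.index: dict[str, set[str]] = {}
        self._names: dict[tuple[str, str], str] = {}
        for e in self.entries:
            self.index.setdefault(e.rxcui, set()).add(e.ndc)
            self._names[(e.rxcui, e.ndc)] = e.normalized_name

    @property
    def all_ndcs(self) -> set[str]:
        return {e.ndc for e in self.entries}

    @property
    def rxcuis(self) -> list[str]:
        return sorted(self.index)

    def ndcs_for_rxcui(self, rxcui: str, drug_name: str = "") -> set[str]:
        """NDCs for ``rxcui`` whose entry name shares the leading ingredient
        token with ``drug_name``; all NDCs when ``drug_name`` is empty;
        empty set for an unknown RxCUI."""
        rxcui = str(rxcui)
        candidates = self.index.get(rxcui, set())
        if not drug_name:
            return set(candidates)
        want = ingredient_token(drug_name)
        return {
            ndc
            for ndc in candidates
            if ingredient_token(self._names[(rxcui, ndc)]) == want
        }

    def name_for(self, rxcui: str, ndc: str) -> str:
        return self._names.get((str(rxcui), str(ndc)), "")

    def is_class(self, rxcui: str, drug_class: str) -> bool:
        return self.classes.get(str(rxcui)) == drug_class


def load_crosswalk(path: str | Path, classes_path: str | Path | None = None) -> MedicationVocabulary:
    """Load a delimited crosswalk (columns rxcui, ndc, drug_name).

    Duplicate (rxcui, ndc) rows collapse to one entry; NDCs are normalized
    to 11 digits. Rows with malformed NDCs are collected into
    ``vocab.invalid_rows`` rather than aborting the load: real dispensing
    feeds contain unmappable codes and a hard failure would be useless.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"rxcui", "ndc", "drug_name"} - set(df.columns)
    if missing:
        raise SchemaError(f"crosswalk missing column(s): {sorted(missing)}")
    entries: dict[tuple[str, str], CrosswalkEntry] = {}
    invalid: list[str] = []
    for row in df.itertuples(index=False):
        try:
            ndc = normalize_ndc(row.ndc)
        except ValueError as exc:
            invalid.append(str(exc))
            continue
        key = (str(row.rxcui), ndc)
        if key not in entries:
            entries[key] = CrosswalkEntry(
                rxcui=str(row.rxcui),
                ndc=ndc,
                drug_name=row.drug_name,
                normalized_name=normalize_name(row.drug_name),
            )
    classes: dict[str, str] = {}
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, dtype=str)
        if {"rxcui", "drug_class"} - set(cdf.columns):
            raise SchemaError("drug class table needs columns rxcui, drug_class")
        classes = dict(zip(cdf["rxcui"], cdf["drug_class"]))
    return MedicationVocabulary(list(entries.values()), classes=classes, invalid_rows=invalid)


def bundled_vocabulary() -> MedicationVocabulary:
    """The synthetic stand-in crosswalk shipped with the package."""
    data = resources.files("rxlink") / "data"
    return load_crosswalk(
        str(data / "synthetic_crosswalk.csv"),
        str(data / "synthetic_drug_classes.csv"),
    )
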