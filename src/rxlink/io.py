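"""Readers and writers for the delimited event tables.

Every table is comma-separated with a header row; date columns are ISO-8601
on disk and integer day offsets (see :mod:`rxlink.dates`) in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dates import iso_to_offsets, offsets_to_iso

# date-typed columns per table name
DATE_COLUMNS: dict[str, list[str]] = {
    "patients": ["birth_date"],
    "encounters": ["date"],
    "prescriptions": ["rx_date"],
    "dispensings": ["fill_date"],
    "phq9": ["date"],
    "diagnoses": ["date"],
    "truth": ["index_date"],
    "crosswalk": [],
    "links": [],
    "cohort": ["index_date"],
    "covariates": [],
}

_ID_PREFIXES = ("patient_id", "rx_id", "disp_id", "encounter_id", "provider_id", "rxcui", "ndc")


def write_table(df: pd.DataFrame, name: str, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in DATE_COLUMNS.get(name, []):
        if col in out.columns and len(out):
            mask = out[col].notna()
            formatted = pd.Series("", index=out.index, dtype=object)
            formatted.loc[mask] = offsets_to_iso(out.loc[mask, col])
            out[col] = formatted
    path = directory / f"{name}.csv"
    out.to_csv(path, index=False)
    return path


def read_table(path: str | Path, name: str | None = None) -> pd.DataFrame:
    path = Path(path)
    name = name or path.stem
    df = pd.read_csv(path, dtype={c: str for c in _ID_PREFIXES}, keep_default_na=True)
    for col in DATE_COLUMNS.get(name, []):
        if col in df.columns and len(df):
            mask = df[col].notna() & (df[col].astype(str) != "")
            offsets = pd.Series(pd.NA, index=df.index, dtype="Int64")
            if mask.any():
                offsets.loc[mask] = iso_to_offsets(df.loc[mask, col].astype(str)).values
            if offsets.notna().all():
                df[col] = offsets.astype("int64")
            else:
                df[col] = offsets
    return df


def read_tables(directory: str | Path, names: list[str]) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    return {n: read_table(directory / f"{n}.csv", n) for n in names}


def write_manifest(entries: dict[str, str], directory: str | Path) -> Path:
    path = Path(directory) / "manifest.txt"
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}: {value}\n")
    return path
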