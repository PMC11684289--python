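"""Reading and writing the linked three-table dataset as CSV.

Layout: a directory with ``patients.csv``, ``prescriptions.csv``,
``encounters.csv`` and (for simulated data) ``truth.csv`` holding the latent
status sequence. UTF-8, header row, ISO-8601 dates. Readers are tolerant of
extra columns but fail loudly on missing required ones.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple

import pandas as pd


class SchemaError(ValueError):
    """A required file or column is missing; message names both."""


DATE_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "patients": (
        "birth_date",
        "first_uc_code_date",
        "first_cd_code_date",
        "resection_date",
        "registration_date",
    ),
    "prescriptions": ("date",),
    "encounters": ("date",),
    "truth": (),
}

REQUIRED_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "patients": (
        "patient_id",
        "birth_date",
        "sex",
        "first_uc_code_date",
        "first_cd_code_date",
        "resection_date",
        "registration_date",
    ),
    "prescriptions": (
        "patient_id",
        "date",
        "drug_name",
        "drug_class",
        "molecule",
        "dose_value",
        "dose_unit",
        "is_biologic",
        "is_biosimilar",
    ),
    "encounters": (
        "patient_id",
        "date",
        "care_type",
        "length_of_stay_days",
        "cost_gbp",
    ),
    "truth": ("patient_id", "period_index", "status"),
}

BOOL_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "prescriptions": ("is_biologic", "is_biosimilar"),
}


def _check_columns(df: pd.DataFrame, table: str, filename: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{filename}: missing required column(s) {missing}"
        )


def write_table(df: pd.DataFrame, path: Path, table: str) -> Path:
    _check_columns(df, table, path.name)
    out = df.copy()
    for col in DATE_COLUMNS[table]:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{path.name}: file not found in {path.parent}")
    df = pd.read_csv(path)
    _check_columns(df, table, path.name)
    for col in DATE_COLUMNS[table]:
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    for col in BOOL_COLUMNS.get(table, ()):
        df[col] = df[col].astype(bool)
    return df


def write_dataset(tables: Dict[str, pd.DataFrame], directory) -> Dict[str, Path]:
    """Write the linked tables to ``directory`` as CSV; returns the paths.

    ``tables`` maps table name (patients/prescriptions/encounters/truth) to a
    schema-conformant DataFrame; ``truth`` is optional.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for table, df in tables.items():
        if table not in REQUIRED_COLUMNS:
            raise SchemaError(f"unknown table {table!r}")
        paths[table] = write_table(df, directory / f"{table}.csv", table)
    return paths


def read_dataset(directory) -> Dict[str, pd.DataFrame]:
    """Read patients/prescriptions/encounters (and truth when present)."""
    directory = Path(directory)
    tables = {}
    for table in ("patients", "prescriptions", "encounters"):
        tables[table] = read_table(directory / f"{table}.csv", table)
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        tables["truth"] = read_table(truth_path, "truth")
    return tables
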