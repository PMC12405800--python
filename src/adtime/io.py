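"""Reading and writing the shared long-format tables.

One schema serves every modality: ``subject_id, age, t_years, value,
modality`` (comma-delimited, header mandatory, full-precision floats).
Covariates live in a second table keyed by ``subject_id``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import InputDataError

LONG_COLUMNS = ["subject_id", "age", "t_years", "value", "modality"]


def write_long_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise InputDataError(f"long table missing columns: {missing}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_long_table(path, modality: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise InputDataError(f"{path}: long table missing columns: {missing}")
    if len(df) == 0:
        raise InputDataError(f"{path}: empty table")
    if modality is not None:
        df = df[df["modality"] == modality]
        if len(df) == 0:
            raise InputDataError(f"{path}: no rows with modality {modality!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"missing input file: {path}")
    return pd.read_csv(path)
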