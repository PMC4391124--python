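"""CSV readers/writers for cohort and accelerometer tables.

Interchange format: UTF-8 CSV, '.' decimal, empty cell = missing. The
cohort header must carry the columns documented in
:data:`REQUIRED_COHORT_COLUMNS`; unknown columns are preserved untouched.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger("frailscreen")

REQUIRED_COHORT_COLUMNS = (
    "id", "gender", "age", "height_cm", "weight_kg", "bmi",
    "grip1_left", "grip2_left", "grip1_right", "grip2_right",
    "walk_time_s", "weight_loss", "exhaustion_q1", "exhaustion_q2", "mmse",
)

REQUIRED_ACCEL_COLUMNS = ("participant_id", "day_index", "wear_minutes", "aee")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the documented schema."""
    df = pd.read_csv(path, dtype={"id": str, "gender": str})
    _check_columns(df, REQUIRED_COHORT_COLUMNS, "cohort table")
    numeric = [c for c in REQUIRED_COHORT_COLUMNS if c not in ("id", "gender")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparseable value in column {col!r}: {exc}") from exc
    if df.empty:
        log.warning("cohort table %s has no data rows", path)
    log.info("read %d cohort rows from %s", len(df), path)
    return df


def read_accel(path) -> pd.DataFrame:
    """Read an accelerometer daily-record CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, REQUIRED_ACCEL_COLUMNS, "accelerometer table")
    for col in ("day_index", "wear_minutes", "aee"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparseable value in column {col!r}: {exc}") from exc
    log.info("read %d accelerometer rows from %s", len(df), path)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as CSV (deterministic formatting)."""
    df.to_csv(path, index=False, na_rep="NA")
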