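"""Cohort schema: column conventions and record-level validation.

A cohort is carried as a :class:`pandas.DataFrame` with one row per subject
and the columns listed in :data:`COHORT_COLUMNS`.  Encodings are fixed:
``sex`` is 1 for male and 0 for female, ``psh`` (parental or sibling history
of diabetes) and ``diabetes`` are 0/1 integers.  Continuous measurements are
in clinical units (years, kg/m^2, cm, mmHg, mmol/L).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Continuous covariates, in canonical order.
COVARIATES = ["age", "bmi", "waist", "sbp", "dbp", "glu", "chol", "tg", "hdl", "ldl"]

#: Full cohort column set (canonical order, matches the CSV header).
COHORT_COLUMNS = ["id", "age", "sex", "bmi", "waist", "sbp", "dbp",
                  "glu", "chol", "tg", "hdl", "ldl", "psh", "diabetes"]

#: Follow-up table columns.
FOLLOWUP_COLUMNS = ["id", "incident_diabetes", "years_observed"]

#: The nine risk variables the shipped model is built on.
RISK_VARIABLES = ["age", "sex", "bmi", "waist", "chol", "tg", "hdl", "dbp", "psh"]

#: Physiologic floors used for truncation and validation.
FLOORS = {
    "age": 20.0,
    "bmi": 13.0,
    "waist": 50.0,
    "sbp": 70.0,
    "dbp": 40.0,
    "glu": 2.5,
    "chol": 1.5,
    "tg": 0.05,
    "hdl": 0.3,
    "ldl": 0.3,
}

SEX_MALE = 1
SEX_FEMALE = 0

#: Fasting glucose at or above this level counts as prevalent diabetes.
DIABETES_GLU_THRESHOLD = 7.0


class SchemaError(ValueError):
    """A cohort table is structurally unusable (missing columns, bad dtypes)."""


def validate_cohort(df: pd.DataFrame, require_sex: bool = True) -> None:
    """Raise :class:`SchemaError` if ``df`` is not a valid cohort table.

    Checks column presence, sex/psh encodings and the record invariants
    (age >= 20, strictly positive continuous measurements).
    """
    required = set(COHORT_COLUMNS) if require_sex else set(COHORT_COLUMNS) - {"sex"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        return
    if not df["sex"].isin([SEX_MALE, SEX_FEMALE]).all():
        raise SchemaError("sex must be encoded 1 (male) / 0 (female)")
    for col in ("psh", "diabetes"):
        if not df[col].isin([0, 1]).all():
            raise SchemaError(f"{col} must be encoded 0/1")
    bad = row_violations(df)
    if bad.any():
        idx = list(df.index[bad][:5])
        raise SchemaError(
            f"{int(bad.sum())} rows violate record invariants (first offenders: {idx})"
        )


def row_violations(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of rows that violate subject-record invariants."""
    bad = np.zeros(len(df), dtype=bool)
    for col in COVARIATES:
        x = pd.to_numeric(df[col], errors="coerce")
        bad |= ~np.isfinite(x.to_numpy(dtype=float))
        bad |= x.to_numpy(dtype=float) <= 0
    if "age" in df:
        bad |= pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float) < 20
    return bad


def nondiabetic_mask(df: pd.DataFrame) -> pd.Series:
    """Subjects free of a diabetes history and with fasting glucose < 7.0 mmol/L."""
    return (df["diabetes"] == 0) & (df["glu"] < DIABETES_GLU_THRESHOLD)
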