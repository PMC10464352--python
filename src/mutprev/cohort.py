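"""Cohort table loading and validation.

The packaged fixture is a 60-subject retrospective bronchoscopy case-control
cohort (30 lung-cancer cases, 30 non-cancer controls; one control's
biomarker is "Not measured" and is excluded from cohort statistics, leaving
59 analyzable subjects).  Columns: demographics, smoking history, histology,
a demographic risk score column, the per-subject TP53 mutation prevalence
(mutations per 193 analyzable bp), and the enrollment protocol id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import packaged_cohort_path

REQUIRED_COLUMNS = ("sample", "cancer_status", "pack_years", "sex", "age",
                    "smoking_status", "tp53_prevalence")


class CohortSchemaError(ValueError):
    pass


def load_cohort_table(path=None) -> pd.DataFrame:
    """Load and validate a cohort CSV (defaults to the packaged fixture).

    "Not measured" biomarker entries become NaN; blank pack-years for never
    smokers are stored as 0.  Row-level validation failures are collected
    and reported together with their row numbers.
    """
    if path is None:
        path = packaged_cohort_path()
    df = pd.read_csv(path, dtype={"protocol_id": str, "patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {', '.join(missing)}")

    errors: list[str] = []
    prev = pd.to_numeric(
        df["tp53_prevalence"].replace("Not measured", np.nan), errors="coerce")
    unparsed = df["tp53_prevalence"].notna() & prev.isna() & \
        (df["tp53_prevalence"].astype(str).str.strip() != "Not measured")
    for i in df.index[unparsed]:
        errors.append(f"row {i + 2}: unparseable tp53_prevalence "
                      f"{df.loc[i, 'tp53_prevalence']!r}")
    df["tp53_prevalence"] = prev

    age = pd.to_numeric(df["age"], errors="coerce")
    for i in df.index[age.isna()]:
        errors.append(f"row {i + 2}: malformed age {df.loc[i, 'age']!r}")
    df["age"] = age

    py = pd.to_numeric(df["pack_years"], errors="coerce")
    never = df["smoking_status"].astype(str).str.strip() == "Never"
    py = py.where(~(py.isna() & never), 0.0)
    for i in df.index[py.isna()]:
        errors.append(f"row {i + 2}: malformed pack_years "
                      f"{df.loc[i, 'pack_years']!r}")
    df["pack_years"] = py

    bad_status = ~df["cancer_status"].isin(["CA", "NC"])
    for i in df.index[bad_status]:
        errors.append(f"row {i + 2}: cancer_status must be CA or NC, got "
                      f"{df.loc[i, 'cancer_status']!r}")
    if errors:
        raise CohortSchemaError("; ".join(errors))

    if "risk_score_x100" in df.columns:
        # demographic risk probability, printed x100; normalize to [0,1]
        rs = pd.to_numeric(df["risk_score_x100"], errors="coerce")
        df["prs_con"] = rs / 100.0
    return df


def analyzable_subjects(df: pd.DataFrame) -> pd.DataFrame:
    """Subjects with a measured biomarker (the cohort analysis set)."""
    return df.dropna(subset=["tp53_prevalence"]).copy()
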