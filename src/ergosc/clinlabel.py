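"""Clinical indices and five-group study labeling.

Groups are ``control``, ``overweight``, ``obesity``, ``mets`` (metabolic
syndrome, IDF definition), and ``dm_no_dr`` (diabetes without retinopathy).
Glycemia cuts follow the 1999/2006 WHO criteria: normoglycemia below
6.1 mmol/l and diabetes at or above 7.0 mmol/l (126 mg/dl, conversion factor
18.0 mg/dl per mmol/l).  BMI classes: overweight 25-29.99, obesity >= 30.
MetS requires central obesity (BMI > 30 or waist >= 94 cm male / >= 80 cm
female) plus at least two of: raised triglycerides, reduced HDL, raised blood
pressure, raised fasting glucose, at the canonical IDF thresholds (the study
cites the IDF definition without numbers; thresholds are configurable).

Label precedence: dm_no_dr > mets > obesity > overweight > control.
Subjects with fasting glucose in 6.1-6.9 mmol/l and no other findings fall
through to the BMI rules and are tagged ``intermediate`` by
:func:`glycemia_category`.

Metadata rows are plain mappings (dict / ``pandas.Series``) with snake_case
keys; :data:`TABLE1_COLUMN_MAP` translates to the clinical table headers for
CSV interchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "GROUPS",
    "MGDL_PER_MMOL",
    "TABLE1_COLUMN_MAP",
    "MetSThresholds",
    "derive_indices",
    "assign_group",
    "glycemia_category",
    "label_table",
]

GROUPS = ("control", "overweight", "obesity", "mets", "dm_no_dr")

MGDL_PER_MMOL = 18.0  # glucose

#: snake_case field -> clinical table column header
TABLE1_COLUMN_MAP = {
    "age": "Age (years)",
    "weight": "Body weight (Kg)",
    "waist": "Waist circumference (cm)",
    "hip": "Hip circumference (cm)",
    "bmi": "BMI (Kg/m^2)",
    "glucose": "Glycemia (mg/dl)",
    "hba1c": "HbA1c (%)",
    "insulin": "Insulinemia (uUI/ml)",
    "homa_i": "HOMA-I",
    "tg": "TG",
    "ct": "CT (mg/dl)",
    "hdl": "HDL (mg/dl)",
    "ldl": "LDL (mg/dl)",
    "vldl": "VLDL (mg/dl)",
    "creatinine": "Creatinine (mg/dl)",
    "sbp": "Systolic blood pressure (mmHg)",
    "dbp": "Diastolic blood pressure (mmHg)",
}

_REQUIRED = ("bmi", "waist", "sex", "glucose", "tg", "hdl", "sbp", "dbp")


@dataclass(frozen=True)
class MetSThresholds:
    """Configurable criteria thresholds (defaults: IDF / WHO)."""

    tg_mgdl: float = 150.0
    hdl_male_mgdl: float = 40.0
    hdl_female_mgdl: float = 50.0
    sbp_mmhg: float = 130.0
    dbp_mmhg: float = 85.0
    glucose_mgdl: float = 100.0
    waist_male_cm: float = 94.0
    waist_female_cm: float = 80.0
    bmi_central: float = 30.0  # central obesity when BMI strictly above
    glucose_dm_mmol: float = 7.0
    glucose_normo_mmol: float = 6.1


DEFAULT_THRESHOLDS = MetSThresholds()


def derive_indices(meta: Mapping) -> dict:
    """Complete a metadata row with BMI, HOMA-I, and the atherogenic index.

    BMI = weight / height^2; HOMA-I = glucose[mg/dl] * insulin[uUI/ml] / 405;
    atherogenic index = log10(TG / HDL).
    """
    out = dict(meta)
    height = out.get("height")
    weight = out.get("weight")
    if height is not None and weight is not None:
        if height <= 0:
            raise ValueError("height must be positive")
        out["bmi"] = weight / height**2
    if out.get("glucose") is not None and out.get("insulin") is not None:
        out["homa_i"] = out["glucose"] * out["insulin"] / 405.0
    if out.get("tg") is not None and out.get("hdl") is not None:
        if out["hdl"] <= 0 or out["tg"] <= 0:
            raise ValueError("TG and HDL must be positive for the atherogenic index")
        out["atherogenic_index"] = math.log10(out["tg"] / out["hdl"])
    return out


def _central_obesity(meta: Mapping, thr: MetSThresholds) -> bool:
    waist_cut = thr.waist_male_cm if meta["sex"] == "male" else thr.waist_female_cm
    return meta["bmi"] > thr.bmi_central or meta["waist"] >= waist_cut


def count_mets_factors(meta: Mapping, thr: MetSThresholds = DEFAULT_THRESHOLDS) -> int:
    """Number of the four IDF component factors a row presents."""
    hdl_cut = thr.hdl_male_mgdl if meta["sex"] == "male" else thr.hdl_female_mgdl
    return sum(
        (
            meta["tg"] >= thr.tg_mgdl,
            meta["hdl"] < hdl_cut,
            meta["sbp"] >= thr.sbp_mmhg or meta["dbp"] >= thr.dbp_mmhg,
            meta["glucose"] >= thr.glucose_mgdl,
        )
    )


def glycemia_category(glucose_mgdl: float, thr: MetSThresholds = DEFAULT_THRESHOLDS) -> str:
    if glucose_mgdl >= thr.glucose_dm_mmol * MGDL_PER_MMOL:
        return "diabetes"
    if glucose_mgdl >= thr.glucose_normo_mmol * MGDL_PER_MMOL:
        return "intermediate"
    return "normo"


def assign_group(meta: Mapping, thresholds: MetSThresholds = DEFAULT_THRESHOLDS) -> str:
    """Assign the single study group label for a completed metadata row."""
    missing = [f for f in _REQUIRED if meta.get(f) is None]
    if missing:
        raise ValueError(f"missing required fields: {missing}")
    if bool(meta.get("diabetes_dx")) or meta["glucose"] >= thresholds.glucose_dm_mmol * MGDL_PER_MMOL:
        return "dm_no_dr"
    if _central_obesity(meta, thresholds) and count_mets_factors(meta, thresholds) >= 2:
        return "mets"
    if meta["bmi"] >= 30.0:
        return "obesity"
    if meta["bmi"] >= 25.0:
        return "overweight"
    return "control"


def label_table(
    df: pd.DataFrame, thresholds: MetSThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Append ``group`` and ``glycemia`` columns to a metadata table."""
    out = df.copy()
    completed = [derive_indices(row) for _, row in df.iterrows()]
    out["group"] = [assign_group(row, thresholds) for row in completed]
    out["glycemia"] = [glycemia_category(row["glucose"], thresholds) for row in completed]
    for key in ("bmi", "homa_i", "atherogenic_index"):
        if all(key in row for row in completed):
            out[key] = [row[key] for row in completed]
    return out
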