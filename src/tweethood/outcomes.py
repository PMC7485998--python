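"""Cardiometabolic outcome definitions.

BMI is weight (kg) over squared height (m); the four derived outcomes are:

* obesity — BMI >= 30 kg/m^2 (inclusive)
* hypertension — mean systolic BP > 130 mm Hg (strict) or mean diastolic
  BP > 80 mm Hg (strict), or self-reported antihypertensive medication
* diabetes — glycohemoglobin (HbA1c) >= 6.5% (inclusive) or self-reported
  diagnosis

The mixed strictness (inclusive BMI and HbA1c cuts, strict BP cuts) is
deliberate and covered by boundary tests.  Missing inputs propagate: no
outcome is fabricated when its inputs are absent.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_bmi",
    "define_obesity",
    "define_hypertension",
    "define_diabetes",
    "derive_outcomes",
]

OBESITY_BMI_CUT = 30.0
SBP_CUT = 130.0
DBP_CUT = 80.0
HBA1C_CUT = 6.5


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2."""
    if not (weight_kg > 0 and height_cm > 0):
        raise ValueError(f"weight and height must be positive, got {weight_kg}, {height_cm}")
    return weight_kg / (height_cm / 100.0) ** 2


def define_obesity(bmi: float | None) -> bool | None:
    """Obesity is BMI >= 30, inclusive; None when BMI is missing."""
    if bmi is None or (isinstance(bmi, float) and math.isnan(bmi)):
        return None
    return bmi >= OBESITY_BMI_CUT


def define_hypertension(
    sbp_readings: Sequence[float] | None,
    dbp_readings: Sequence[float] | None,
    htn_medication: bool | None,
) -> bool | None:
    """Elevated mean BP (strict >130 systolic or >80 diastolic) or medication.

    Means are taken over however many readings exist.  Returns None only
    when no reading and no medication flag is available.
    """
    sbp = [x for x in (sbp_readings or []) if x is not None and not math.isnan(x)]
    dbp = [x for x in (dbp_readings or []) if x is not None and not math.isnan(x)]
    if not sbp and not dbp and htn_medication is None:
        return None
    if htn_medication:
        return True
    elevated = False
    if sbp:
        elevated = elevated or (sum(sbp) / len(sbp) > SBP_CUT)
    if dbp:
        elevated = elevated or (sum(dbp) / len(dbp) > DBP_CUT)
    return elevated


def define_diabetes(hba1c: float | None, selfreport: bool | None) -> bool | None:
    """HbA1c >= 6.5% (inclusive) or self-reported diagnosis."""
    hba1c_missing = hba1c is None or (isinstance(hba1c, float) and math.isnan(hba1c))
    if hba1c_missing and selfreport is None:
        return None
    if selfreport:
        return True
    if hba1c_missing:
        return bool(selfreport) if selfreport is not None else None
    return hba1c >= HBA1C_CUT


def derive_outcomes(individuals: pd.DataFrame) -> pd.DataFrame:
    """Append bmi / obesity / hypertension / diabetes columns to a table.

    Expects columns weight_kg, height_cm, sbp_1..sbp_k, dbp_1..dbp_k,
    htn_medication, hba1c, diabetes_selfreport; missing measures may be NaN.
    Derived boolean columns use pandas nullable booleans so missingness
    survives the round trip to CSV.
    """
    out = individuals.copy()
    w = out["weight_kg"].to_numpy(dtype=float)
    h = out["height_cm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = np.where((w > 0) & (h > 0), w / (h / 100.0) ** 2, np.nan)
    out["bmi"] = bmi
    out["obesity"] = pd.array(
        [define_obesity(b if not np.isnan(b) else None) for b in bmi], dtype="boolean"
    )
    sbp_cols = sorted(c for c in out.columns if c.startswith("sbp_"))
    dbp_cols = sorted(c for c in out.columns if c.startswith("dbp_"))
    sbp_mean = out[sbp_cols].mean(axis=1, skipna=True) if sbp_cols else pd.Series(np.nan, index=out.index)
    dbp_mean = out[dbp_cols].mean(axis=1, skipna=True) if dbp_cols else pd.Series(np.nan, index=out.index)
    med = out["htn_medication"] if "htn_medication" in out else pd.Series(pd.NA, index=out.index)
    med = med.astype("boolean")
    elevated = (sbp_mean > SBP_CUT) | (dbp_mean > DBP_CUT)  # NaN means compare False
    htn = pd.array(
        np.where(med.fillna(False), True, elevated.to_numpy()), dtype="boolean"
    )
    all_missing = sbp_mean.isna() & dbp_mean.isna() & med.isna()
    htn[all_missing.to_numpy()] = pd.NA
    out["hypertension"] = htn
    sr = out.get("diabetes_selfreport", pd.Series(pd.NA, index=out.index)).astype("boolean")
    a1c = pd.to_numeric(out.get("hba1c", pd.Series(np.nan, index=out.index)), errors="coerce")
    dia = pd.array(
        np.where(sr.fillna(False), True, (a1c >= HBA1C_CUT).to_numpy()), dtype="boolean"
    )
    dia[(a1c.isna() & sr.isna()).to_numpy()] = pd.NA
    out["diabetes"] = dia
    return out
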