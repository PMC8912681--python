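"""CSV input/output with explicit reject accounting.

The participant CSV schema (one row per participant) is fixed:

    id, sex, age_years, weight_kg, height_cm,
    tri_sf_1..4, calf_sf_1..4,
    adp_mass_kg, adp_vol1_L, adp_vol2_L, adp_vol3_L, adp_tgv_L,
    dxa_lm_kg, dxa_bmc_g, dxa_fm_kg,
    d2o_bottle_empty_g, d2o_bottle_d2o_g, d2o_bottle_d2o_water_g,
    d2o_bottle_drunk_g, d2o_ap_pre_pct, d2o_ap_post_pct,
    mri_n_voxels, mri_voxel_vol_L

The first five columns are mandatory; method columns may be empty where a
method was not performed. Rows failing basic invariants are collected into
a rejects table, never silently dropped. Report-style outputs round to 4
decimals; machine-readable outputs keep full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple, Union

import pandas as pd

from .datatypes import Sex
from .simulate import COHORT_COLUMNS

MANDATORY_COLUMNS = ["id", "sex", "age_years", "weight_kg", "height_cm"]
ESTIMATE_COLUMNS = ["participant_id", "method", "fm_kg", "ffm_kg", "pct_fat", "flags"]


def read_participants(path: Union[str, Path]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a participant CSV.

    Returns ``(accepted, rejects)``. Rejects carry the row index, the
    participant id where parseable, and the reason. A missing mandatory
    column raises immediately, naming the column.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    reasons = []
    keep = []
    for idx, row in df.iterrows():
        reason = None
        try:
            sex = str(row["sex"])
            if sex not in (Sex.FEMALE.value, Sex.MALE.value):
                reason = f"sex: unrecognized value {sex!r}"
            elif not (float(row["weight_kg"]) > 0):
                reason = f"weight_kg: non-positive value {row['weight_kg']}"
            elif not (float(row["height_cm"]) > 0):
                reason = f"height_cm: non-positive value {row['height_cm']}"
            elif not (float(row["age_years"]) > 0):
                reason = f"age_years: non-positive value {row['age_years']}"
        except (TypeError, ValueError) as exc:
            reason = f"unparseable cell: {exc}"
        if reason is None:
            keep.append(idx)
        else:
            reasons.append({"row": idx, "id": row.get("id", ""), "reason": reason})
    accepted = df.loc[keep].reset_index(drop=True)
    rejects = pd.DataFrame(reasons, columns=["row", "id", "reason"])
    return accepted, rejects


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a raw-measurement cohort in the documented column order."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def write_estimates(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[ESTIMATE_COLUMNS].to_csv(path, index=False)


def read_estimates(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"estimates file missing columns: {', '.join(missing)}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return df


def write_report(df: pd.DataFrame, path: Union[str, Path], decimals: int = 4) -> None:
    """Human-facing CSV report rounded to a fixed number of decimals."""
    df.round(decimals).to_csv(path, index=False)
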