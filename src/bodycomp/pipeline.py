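"""Per-participant estimation pipeline: raw measurement row -> tidy estimates.

One participant row follows the documented CSV schema (see
:mod:`bodycomp.io`); each clinical method with complete raw data yields one
:class:`CompositionEstimate`. The 4-C reference row is assembled from the
same raw columns the instrument methods use: ADP body volume, deuterium
total body water, and DXA bone mineral content. A participant whose
deuterium session trips any dose-outlier rule contributes neither a D2O nor
a 4-C row, mirroring the exclusion accounting of a real study.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from . import fourc, instruments
from .constants import ConstantsTable
from .datatypes import (
    AdpSession,
    CompositionEstimate,
    DeuteriumSession,
    FourCInputs,
    Method,
    MriVoxelSummary,
    Sex,
)

SF_REPLICATE_COLS = {
    "triceps": ["tri_sf_1", "tri_sf_2", "tri_sf_3", "tri_sf_4"],
    "calf": ["calf_sf_1", "calf_sf_2", "calf_sf_3", "calf_sf_4"],
}
ADP_VOL_COLS = ["adp_vol1_L", "adp_vol2_L", "adp_vol3_L"]


def _present(row, col) -> bool:
    v = row.get(col)
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def _vals(row, cols) -> list:
    return [float(row[c]) for c in cols if _present(row, c)]


def estimate_participant(
    row: dict, constants: Optional[ConstantsTable] = None
) -> Tuple[List[CompositionEstimate], List[Tuple[str, str, str]]]:
    """All method estimates for one raw participant row.

    Returns ``(estimates, issues)`` where each issue is a
    ``(participant_id, method, flag)`` triple explaining a skipped or
    degraded estimate. Nothing is silently dropped.
    """
    constants = constants or ConstantsTable.default()
    pid = str(row["id"])
    sex = Sex(row["sex"])
    age = float(row["age_years"])
    weight = float(row["weight_kg"])

    estimates: List[CompositionEstimate] = []
    issues: List[Tuple[str, str, str]] = []

    # --- skinfolds -------------------------------------------------------
    tri = _vals(row, SF_REPLICATE_COLS["triceps"])
    calf = _vals(row, SF_REPLICATE_COLS["calf"])
    if tri and calf:
        flags = []
        if len(tri) < 4 or len(calf) < 4:
            flags.append("SF_REPLICATES_LT_4")
        pct = instruments.slaughter_percent_fat(
            sex,
            instruments.mean_skinfold_site(tri),
            instruments.mean_skinfold_site(calf),
        )
        fm = instruments.fat_mass_from_percent(min(max(pct, 0.0), 100.0), weight)
        estimates.append(CompositionEstimate(pid, Method.SF, fm, weight - fm, pct,
                                             tuple(flags)))

    # --- ADP -------------------------------------------------------------
    bv_corrected = None
    vols = _vals(row, ADP_VOL_COLS)
    if len(vols) >= 2 and _present(row, "adp_tgv_L"):
        mass = float(row["adp_mass_kg"]) if _present(row, "adp_mass_kg") else weight
        try:
            selected = instruments.select_body_volume(vols)
        except ValueError as exc:
            issues.append((pid, Method.ADP.value, str(exc)))
        else:
            bv_corrected = instruments.corrected_body_volume(selected, float(row["adp_tgv_L"]))
            density = instruments.body_density(mass, bv_corrected)
            pct = instruments.adp_percent_fat(density, sex, age, constants)
            fm = pct / 100.0 * weight
            estimates.append(CompositionEstimate(pid, Method.ADP, fm, weight - fm, pct))

    # --- DXA -------------------------------------------------------------
    if _present(row, "dxa_lm_kg") and _present(row, "dxa_bmc_g") and _present(row, "dxa_fm_kg"):
        fm = float(row["dxa_fm_kg"])
        ffm = instruments.dxa_ffm(float(row["dxa_lm_kg"]), float(row["dxa_bmc_g"]))
        estimates.append(CompositionEstimate(pid, Method.DXA, fm, ffm,
                                             fourc.percent_fat(fm, weight)))

    # --- deuterium dilution ---------------------------------------------
    tbw_L = tbw_kg = None
    d2o_cols = ["d2o_bottle_empty_g", "d2o_bottle_d2o_g", "d2o_bottle_d2o_water_g",
                "d2o_bottle_drunk_g", "d2o_ap_pre_pct", "d2o_ap_post_pct"]
    if all(_present(row, c) for c in d2o_cols):
        session = DeuteriumSession(
            bottle_empty_g=float(row["d2o_bottle_empty_g"]),
            bottle_d2o_g=float(row["d2o_bottle_d2o_g"]),
            bottle_d2o_water_g=float(row["d2o_bottle_d2o_water_g"]),
            bottle_drunk_g=float(row["d2o_bottle_drunk_g"]),
            ap_pre_pct=float(row["d2o_ap_pre_pct"]),
            ap_post_pct=float(row["d2o_ap_post_pct"]),
        )
        dose_flags = instruments.dose_outlier_flags(session, weight)
        if dose_flags:
            for f in sorted(fl.value for fl in dose_flags):
                issues.append((pid, Method.D2O.value, f))
        else:
            dose = instruments.d2o_dose_g(session)
            tbw_kg, tbw_L = instruments.tbw_from_dilution(session, dose)
            ffm = instruments.ffm_from_tbw(tbw_kg, sex, age, constants)
            fm = weight - ffm
            estimates.append(CompositionEstimate(pid, Method.D2O, fm, ffm,
                                                 fourc.percent_fat(fm, weight)))

    # --- MRI -------------------------------------------------------------
    if _present(row, "mri_n_voxels") and _present(row, "mri_voxel_vol_L"):
        summary = MriVoxelSummary(
            n_fat_voxels=int(row["mri_n_voxels"]),
            voxel_volume_L=float(row["mri_voxel_vol_L"]),
            adipose_density_kg_per_L=constants.adipose_density_kg_per_L,
        )
        fm = instruments.mri_fat_mass(summary)
        estimates.append(CompositionEstimate(pid, Method.MRI, fm, weight - fm,
                                             fourc.percent_fat(fm, weight)))

    # --- 4-C reference ---------------------------------------------------
    if bv_corrected is not None and tbw_L is not None and _present(row, "dxa_bmc_g"):
        inputs = FourCInputs(bv_L=bv_corrected, tbw_L=tbw_L,
                             bmc_g=float(row["dxa_bmc_g"]), weight_kg=weight)
        res = fourc.fourc_result(inputs)
        estimates.append(CompositionEstimate(pid, Method.FOURC, res.fm_kg, res.ffm_kg,
                                             res.pct_fat))
    elif bv_corrected is None or tbw_L is None:
        issues.append((pid, Method.FOURC.value, "MISSING_COMPONENT"))

    return estimates, issues


def estimate_cohort(
    cohort: pd.DataFrame, constants: Optional[ConstantsTable] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy estimates for a whole cohort frame in the documented CSV schema.

    Returns ``(estimates, issues)``: estimates with columns
    participant_id, method, fm_kg, ffm_kg, pct_fat, flags; issues with
    participant_id, method, flag.
    """
    constants = constants or ConstantsTable.default()
    est_rows = []
    issue_rows = []
    for row in cohort.to_dict("records"):
        ests, issues = estimate_participant(row, constants)
        for e in ests:
            est_rows.append({
                "participant_id": e.participant_id,
                "method": e.method.value,
                "fm_kg": e.fm_kg,
                "ffm_kg": e.ffm_kg,
                "pct_fat": e.pct_fat,
                "flags": ";".join(e.flags),
            })
        issue_rows.extend(
            {"participant_id": p, "method": m, "flag": f} for p, m, f in issues)
    estimates = pd.DataFrame(
        est_rows, columns=["participant_id", "method", "fm_kg", "ffm_kg", "pct_fat", "flags"])
    issues = pd.DataFrame(issue_rows, columns=["participant_id", "method", "flag"])
    return estimates, issues
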