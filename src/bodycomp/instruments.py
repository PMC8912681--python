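"""Per-instrument conversions from raw measurements to body composition.

Implements the measurement chain of each clinical method:

* skinfolds: replicate means -> Slaughter two-site percent fat -> fat mass;
* ADP: raw volume selection -> TGV-corrected body volume -> whole-body
  density -> percent fat through child-specific (c1, c2) constants;
* DXA: fat-free mass as lean soft tissue plus bone mineral content;
* deuterium dilution: bottle-weight dose accounting, dose-outlier
  screening, plateau dilution-space total body water, hydration-coefficient
  conversion to fat-free mass;
* MRI: fat-voxel count times voxel volume times adipose density.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Optional, Sequence

from .constants import ConstantsTable
from .datatypes import (
    CALIPER_MAX_MM,
    DeuteriumSession,
    MriVoxelSummary,
    Sex,
)

# Slaughter two-site (triceps + calf) equation coefficients, %fat = m*sum + b
SLAUGHTER_COEFFS = {
    Sex.MALE: (0.735, 1.0),
    Sex.FEMALE: (0.610, 5.1),
}

D2O_MOLECULAR_WEIGHT = 20.0
WATER_MOLECULAR_WEIGHT = 18.02
PROTON_EXCHANGE_CORRECTION = 1.04
WATER_DENSITY_36C_KG_PER_L = 0.99371

#: fraction of thoracic gas volume added back to the raw ADP volume reading
TGV_CORRECTION_FRACTION = 0.40


def mean_skinfold_site(readings_mm: Sequence[float]) -> float:
    """Mean of 1-4 replicate caliper readings (mm) at one site."""
    readings = list(readings_mm)
    if not readings:
        raise ValueError("no readings")
    if len(readings) > 4:
        raise ValueError("at most 4 replicate readings per site")
    for r in readings:
        if not (0 < r <= CALIPER_MAX_MM):
            raise ValueError(f"reading {r} mm outside caliper scale (0, {CALIPER_MAX_MM}]")
    return float(sum(readings)) / len(readings)


def slaughter_percent_fat(sex: Sex, triceps_mm: float, calf_mm: float) -> float:
    """Percent body fat from the sex-specific two-site Slaughter equation.

    Males: %fat = 0.735*(triceps + calf) + 1.0
    Females: %fat = 0.610*(triceps + calf) + 5.1
    """
    if triceps_mm < 0 or calf_mm < 0:
        raise ValueError("site means must be non-negative")
    slope, intercept = SLAUGHTER_COEFFS[Sex(sex)]
    return slope * (triceps_mm + calf_mm) + intercept


def fat_mass_from_percent(pct_fat: float, weight_kg: float) -> float:
    """Fat mass (kg) as the fat fraction times body weight."""
    if not (0 <= pct_fat <= 100):
        raise ValueError(f"pct_fat {pct_fat} outside [0, 100]")
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return pct_fat / 100.0 * weight_kg


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    height_m = height_cm / 100.0
    return weight_kg / height_m**2


def select_body_volume(
    volume_readings_L: Sequence[float], agreement_threshold_L: float = 0.150
) -> float:
    """Select the agreed ADP body volume from 2-3 raw readings.

    Two readings within the agreement threshold are averaged. If the first
    two disagree, a third is required and the closest agreeing pair is
    averaged; with two equally close agreeing pairs the pair containing the
    earliest reading wins (deterministic tie-break).
    """
    readings = [float(v) for v in volume_readings_L]
    if len(readings) not in (2, 3):
        raise ValueError("expected 2 or 3 volume readings")
    if len(readings) == 2:
        if abs(readings[0] - readings[1]) <= agreement_threshold_L:
            return (readings[0] + readings[1]) / 2.0
        raise ValueError("third reading required: first two readings disagree")
    pairs = [(i, j) for i in range(3) for j in range(i + 1, 3)]
    agreeing = [
        (abs(readings[i] - readings[j]), (i, j))
        for i, j in pairs
        if abs(readings[i] - readings[j]) <= agreement_threshold_L
    ]
    if not agreeing:
        raise ValueError("no agreeing pair within threshold")
    # min diff first; ties broken by earliest reading index
    _, (i, j) = min(agreeing, key=lambda t: (t[0], t[1]))
    return (readings[i] + readings[j]) / 2.0


def corrected_body_volume(
    raw_volume_L: float, tgv_L: float, tgv_fraction: float = TGV_CORRECTION_FRACTION
) -> float:
    """Raw chamber volume corrected for thoracic gas volume (BOD POD convention)."""
    if raw_volume_L <= 0:
        raise ValueError("raw volume must be positive")
    if tgv_L < 0:
        raise ValueError("tgv_L must be non-negative")
    return raw_volume_L + tgv_fraction * tgv_L


def body_density(body_mass_kg: float, body_volume_L: float) -> float:
    """Whole-body density (kg/L) = mass / volume."""
    if body_mass_kg <= 0 or body_volume_L <= 0:
        raise ValueError("mass and volume must be positive")
    return body_mass_kg / body_volume_L


def adp_percent_fat(
    density_kg_per_L: float,
    sex: Optional[Sex] = None,
    age_years: Optional[float] = None,
    constants: Optional[ConstantsTable] = None,
    *,
    c1: Optional[float] = None,
    c2: Optional[float] = None,
) -> float:
    """Percent fat from whole-body density, %FM = (c1/Db - c2)*100.

    The (c1, c2) pair is looked up from a :class:`ConstantsTable` by sex and
    age, or passed explicitly (e.g. the adult Siri pair 4.95/4.50).
    """
    if density_kg_per_L <= 0:
        raise ValueError("density must be positive")
    if c1 is None or c2 is None:
        if sex is None or age_years is None:
            raise ValueError("either (c1, c2) or (sex, age_years) must be given")
        constants = constants or ConstantsTable.default()
        c1, c2 = constants.adp_constants(sex, age_years)
    return (c1 / density_kg_per_L - c2) * 100.0


def dxa_ffm(lean_soft_tissue_kg: float, bmc_g: float) -> float:
    """DXA fat-free mass (kg) = lean soft tissue + bone mineral content."""
    if lean_soft_tissue_kg < 0 or bmc_g < 0:
        raise ValueError("DXA components must be non-negative")
    return lean_soft_tissue_kg + bmc_g / 1000.0


def d2o_dose_g(session: DeuteriumSession) -> float:
    """Consumed deuterium dose (g) from the four bottle weighings.

    dose = (weighed D2O) * (consumed fraction of bottle content)
         = (bottle_d2o - bottle_empty)
           * (bottle_d2o_water - bottle_drunk) / (bottle_d2o_water - bottle_empty)
    """
    denom = session.bottle_d2o_water_g - session.bottle_empty_g
    if denom <= 0:
        raise ValueError("empty bottle record: no content was weighed")
    weighed = session.bottle_d2o_g - session.bottle_empty_g
    consumed_fraction = (session.bottle_d2o_water_g - session.bottle_drunk_g) / denom
    return weighed * consumed_fraction


class DoseFlag(str, Enum):
    """Outlier screens for a deuterium dose; any flag voids the session."""

    IMPOSSIBLE_BOTTLE_WEIGHT = "IMPOSSIBLE_BOTTLE_WEIGHT"  # bottle lighter than empty after drinking
    RESIDUAL_GT_1G = "RESIDUAL_GT_1G"                      # > 1 g left in the bottle
    DOSE_OFF_TARGET = "DOSE_OFF_TARGET"                    # weighed dose off 0.05 g/kg by > 15%


def dose_outlier_flags(session: DeuteriumSession, weight_kg: float) -> set:
    """Classify a deuterium session against the three printed outlier rules."""
    flags = set()
    if session.bottle_drunk_g < session.bottle_empty_g:
        flags.add(DoseFlag.IMPOSSIBLE_BOTTLE_WEIGHT)
    if session.bottle_drunk_g - session.bottle_empty_g > 1.0:
        flags.add(DoseFlag.RESIDUAL_GT_1G)
    target = session.target_dose_g_per_kg * weight_kg
    weighed = session.bottle_d2o_g - session.bottle_empty_g
    if target > 0 and abs(weighed - target) / target > 0.15:
        flags.add(DoseFlag.DOSE_OFF_TARGET)
    return flags


def tbw_from_dilution(session: DeuteriumSession, dose_g: float) -> tuple:
    """Total body water from deuterium plateau dilution.

    TBW(kg) = [dose(g) * (concentration/20) * 18.02 / (AP_post - AP_pre)]
              * 1e-3 / 1.04
    TBW(L) = TBW(kg) / 0.99371

    The 1.04 corrects for proton exchange with non-aqueous hydrogen; 0.99371
    kg/L is the density of water at 36 C.
    """
    if dose_g <= 0:
        raise ValueError("dose_g must be positive")
    delta_ap = session.ap_post_pct - session.ap_pre_pct
    if delta_ap <= 0:
        raise ValueError("no enrichment: AP_post must exceed AP_pre")
    tbw_kg = (
        dose_g
        * (session.concentration_pct / D2O_MOLECULAR_WEIGHT)
        * WATER_MOLECULAR_WEIGHT
        / delta_ap
    ) * 1e-3 / PROTON_EXCHANGE_CORRECTION
    tbw_L = tbw_kg / WATER_DENSITY_36C_KG_PER_L
    return tbw_kg, tbw_L


def ffm_from_tbw(
    tbw_kg: float,
    sex: Optional[Sex] = None,
    age_years: Optional[float] = None,
    constants: Optional[ConstantsTable] = None,
    *,
    coefficient: Optional[float] = None,
) -> float:
    """Fat-free mass from total body water via the hydration coefficient."""
    if tbw_kg <= 0:
        raise ValueError("tbw_kg must be positive")
    if coefficient is None:
        if sex is None or age_years is None:
            raise ValueError("either coefficient or (sex, age_years) must be given")
        constants = constants or ConstantsTable.default()
        coefficient = constants.hydration_coefficient(sex, age_years)
    if coefficient <= 0:
        raise ValueError("hydration coefficient must be positive")
    return tbw_kg / coefficient


def mri_fat_mass(summary: MriVoxelSummary) -> float:
    """Total fat mass (kg) from counted fat voxels."""
    return summary.n_fat_voxels * summary.voxel_volume_L * summary.adipose_density_kg_per_L
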