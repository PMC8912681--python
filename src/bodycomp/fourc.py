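"""The 4-component reference model.

Partitions body weight into fat, water, mineral, and residual protein using
body volume (ADP), total body water (deuterium dilution), and bone mineral
content (DXA):

    FM(kg) = 2.7474*BV(L) - 0.7145*TBW(L) + 1.4599*BMC(g)/1000 - 2.0503*weight(kg)
    FFM(kg) = weight - FM

The map is linear in (BV, TBW, BMC, weight), which makes stratum means of
fat mass identical to fat mass at stratum-mean inputs — a useful pipeline
self-check.
"""

from __future__ import annotations

from typing import Union

from .datatypes import FourCInputs, FourCResult
from .instruments import WATER_DENSITY_36C_KG_PER_L

# Fuller-type coefficients on (BV in L, TBW in L, BMC in kg, weight in kg)
FOURC_BV = 2.7474
FOURC_TBW = 0.7145
FOURC_BMC = 1.4599
FOURC_WEIGHT = 2.0503


def fuller_fat_mass(bv_L: float, tbw_L: float, bmc_g: float, weight_kg: float) -> float:
    """Raw linear 4-C map; no physiologic validation (identity tests rely on this)."""
    return (
        FOURC_BV * bv_L
        - FOURC_TBW * tbw_L
        + FOURC_BMC * bmc_g / 1000.0
        - FOURC_WEIGHT * weight_kg
    )


def fourc_fat_mass(inputs: FourCInputs, tbw_in_kg: bool = False) -> float:
    """4-C fat mass (kg) from validated inputs.

    ``tbw_in_kg`` is a sensitivity switch: when True the ``tbw_L`` field is
    interpreted as kg and converted to liters first. Default is liters, the
    unit the reference equation is written in.
    """
    tbw_L = inputs.tbw_L / WATER_DENSITY_36C_KG_PER_L if tbw_in_kg else inputs.tbw_L
    return fuller_fat_mass(inputs.bv_L, tbw_L, inputs.bmc_g, inputs.weight_kg)


def ffm_from_weight_fm(weight_kg: float, fm_kg: float) -> float:
    """Fat-free mass as weight minus fat mass."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return weight_kg - fm_kg


def percent_fat(fm_kg: float, weight_kg: float) -> float:
    """Percent of body weight that is fat."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    return 100.0 * fm_kg / weight_kg


def hydration_percent(tbw_kg: float, ffm_kg: float) -> float:
    """Hydration of fat-free mass, 100*TBW/FFM."""
    if ffm_kg <= 0:
        raise ValueError("ffm_kg must be positive")
    return 100.0 * tbw_kg / ffm_kg


def fourc_result(inputs: FourCInputs, tbw_in_kg: bool = False) -> FourCResult:
    """Full 4-C output: FM, FFM, %fat, and hydration of FFM."""
    fm = fourc_fat_mass(inputs, tbw_in_kg=tbw_in_kg)
    ffm = ffm_from_weight_fm(inputs.weight_kg, fm)
    tbw_kg = inputs.tbw_L if tbw_in_kg else inputs.tbw_L * WATER_DENSITY_36C_KG_PER_L
    return FourCResult(
        fm_kg=fm,
        ffm_kg=ffm,
        pct_fat=percent_fat(fm, inputs.weight_kg),
        hydration_pct=hydration_percent(tbw_kg, ffm) if ffm > 0 else float("nan"),
    )
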