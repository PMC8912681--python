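"""Domain types for pediatric body-composition assessment.

Each type carries the raw measurements of one clinical method for one
participant, with the physical invariants of the instrument enforced at
construction time. Units are fixed at the interface: masses in kg, volumes
in L, bone mineral content in g, skinfolds in mm, isotopic enrichment in
atom percent. Unit conversions are explicit operations, never implicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Method(str, Enum):
    """Body-composition estimation methods covered by the pipeline."""

    SF = "SF"        # skinfold thickness (Slaughter two-site equations)
    ADP = "ADP"      # air-displacement plethysmography
    DXA = "DXA"      # dual X-ray absorptiometry
    D2O = "D2O"      # deuterium oxide dilution
    MRI = "MRI"      # magnetic resonance imaging voxel counting
    FOURC = "FOURC"  # 4-component reference model


class AgeGroup(str, Enum):
    CHILDREN = "children"      # 4 to <11 years
    ADOLESCENTS = "adolescents"  # 11 to <19 years


def age_group_of(age_years: float) -> AgeGroup:
    return AgeGroup.CHILDREN if age_years < 11.0 else AgeGroup.ADOLESCENTS


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class AnthropometryRecord:
    """Identity and basic anthropometry of one participant."""

    participant_id: str
    sex: Sex
    age_years: float
    weight_kg: float
    height_cm: float
    circumferences_cm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        _require(self.weight_kg > 0, "weight_kg must be positive")
        _require(self.height_cm > 0, "height_cm must be positive")
        _require(self.age_years > 0, "age_years must be positive")
        if not (4.0 <= self.age_years < 19.0):
            warnings.warn(
                f"age {self.age_years:.1f} y outside the 4-19 y population "
                "the conversion constants were derived for",
                stacklevel=2,
            )


CALIPER_MAX_MM = 80.0


@dataclass(frozen=True)
class SkinfoldSet:
    """Replicate triceps and calf caliper readings (mm).

    The protocol takes two readings per site on each body side (four per
    site); fewer replicates are accepted and flagged downstream.
    """

    triceps_mm: tuple
    calf_mm: tuple

    def __post_init__(self) -> None:
        for site, readings in (("triceps", self.triceps_mm), ("calf", self.calf_mm)):
            _require(1 <= len(readings) <= 4, f"{site}: expected 1-4 replicate readings")
            for r in readings:
                _require(0 < r <= CALIPER_MAX_MM,
                         f"{site} reading {r} mm outside caliper scale (0, {CALIPER_MAX_MM}]")


@dataclass(frozen=True)
class AdpSession:
    """One BOD POD session: body mass, raw volume readings, thoracic gas volume."""

    body_mass_kg: float
    volume_readings_L: tuple
    tgv_L: float

    def __post_init__(self) -> None:
        _require(self.body_mass_kg > 0, "body_mass_kg must be positive")
        _require(len(self.volume_readings_L) in (2, 3),
                 "expected 2 or 3 raw volume readings")
        for v in self.volume_readings_L:
            _require(v > 0, "volume readings must be positive")
        _require(self.tgv_L >= 0, "tgv_L must be non-negative")


@dataclass(frozen=True)
class DxaScan:
    """Whole-body DXA components. Regional values are stored but unused."""

    lean_soft_tissue_kg: float
    bmc_g: float
    fat_mass_kg: float
    regional: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.lean_soft_tissue_kg >= 0, "lean_soft_tissue_kg must be >= 0")
        _require(self.bmc_g >= 0, "bmc_g must be >= 0")
        _require(self.fat_mass_kg >= 0, "fat_mass_kg must be >= 0")


@dataclass(frozen=True)
class DeuteriumSession:
    """Bottle weighings and saliva enrichments for one deuterium dilution.

    Bottle weights (g) are taken empty, after adding the D2O dose, after
    adding tap water, and after the participant drank. Enrichments are atom
    percent of deuterium in pre- and post-dose saliva.
    """

    bottle_empty_g: float
    bottle_d2o_g: float
    bottle_d2o_water_g: float
    bottle_drunk_g: float
    ap_pre_pct: float
    ap_post_pct: float
    concentration_pct: float = 99.9
    target_dose_g_per_kg: float = 0.05

    def __post_init__(self) -> None:
        _require(self.bottle_d2o_g >= self.bottle_empty_g,
                 "bottle_d2o_g must not be below bottle_empty_g")
        _require(self.bottle_d2o_water_g >= self.bottle_d2o_g,
                 "bottle_d2o_water_g must not be below bottle_d2o_g")
        _require(self.concentration_pct > 0, "concentration_pct must be positive")


@dataclass(frozen=True)
class MriVoxelSummary:
    """Fat-voxel count and voxel geometry from a whole-body MRI segmentation."""

    n_fat_voxels: int
    voxel_volume_L: float
    adipose_density_kg_per_L: float = 0.92

    def __post_init__(self) -> None:
        _require(self.n_fat_voxels >= 0, "n_fat_voxels must be >= 0")
        _require(self.voxel_volume_L > 0, "voxel_volume_L must be positive")
        _require(0.8 < self.adipose_density_kg_per_L < 1.1,
                 "adipose density outside plausible (0.8, 1.1) kg/L")


@dataclass(frozen=True)
class CompositionEstimate:
    """Fat mass / fat-free mass / percent fat attributed to one method."""

    participant_id: str
    method: Method
    fm_kg: float
    ffm_kg: float
    pct_fat: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))


@dataclass(frozen=True)
class FourCInputs:
    """Inputs to the 4-component reference model."""

    bv_L: float       # body volume from ADP
    tbw_L: float      # total body water from deuterium dilution
    bmc_g: float      # bone mineral content from DXA
    weight_kg: float

    def __post_init__(self) -> None:
        _require(self.bv_L > 0, "bv_L must be positive")
        _require(self.tbw_L > 0, "tbw_L must be positive")
        _require(self.bmc_g > 0, "bmc_g must be positive")
        _require(self.weight_kg > 0, "weight_kg must be positive")
        density = self.weight_kg / self.bv_L
        if not (0.9 < density < 1.15):
            warnings.warn(
                f"implied whole-body density {density:.3f} kg/L outside "
                "physiologic (0.9, 1.15)", stacklevel=2,
            )


@dataclass(frozen=True)
class FourCResult:
    fm_kg: float
    ffm_kg: float
    pct_fat: float
    hydration_pct: float  # 100 * TBW(kg) / FFM(kg)

    def __post_init__(self) -> None:
        if math.isfinite(self.hydration_pct) and not (50 < self.hydration_pct < 90):
            warnings.warn(
                f"hydration {self.hydration_pct:.1f}% outside physiologic (50, 90)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PairedSeries:
    """Two same-length series of the same quantity measured by two methods."""

    method_values: tuple
    reference_values: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "method_values", tuple(float(v) for v in self.method_values))
        object.__setattr__(self, "reference_values", tuple(float(v) for v in self.reference_values))
        _require(len(self.method_values) == len(self.reference_values),
                 "method and reference series must have equal length")
        _require(len(self.method_values) >= 2, "need at least 2 pairs")
        for v in self.method_values + self.reference_values:
            _require(math.isfinite(v), "series contain non-finite values")

    @property
    def n(self) -> int:
        return len(self.method_values)
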