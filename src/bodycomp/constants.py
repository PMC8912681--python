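"""Age- and sex-specific conversion constants.

The density-to-fat-fraction constants for children (the c1/c2 pair of
%FM = (c1/Db - c2)*100) and the hydration coefficient of fat-free mass
(TBW/FFM) both change with maturation. They are configuration, not code:
the packaged defaults in ``data/constants.yaml`` are Lohman-style
child-specific tables, and any study can ship its own file with the same
schema.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .datatypes import Sex


@dataclass(frozen=True)
class AgeBand:
    """Half-open age band [age_min, age_max) carrying a payload of values."""

    age_min: float
    age_max: float
    values: dict

    def contains(self, age_years: float) -> bool:
        return self.age_min <= age_years < self.age_max


class ConstantsTable:
    """Lookup of ADP density constants and hydration coefficients by sex and age.

    Bands are half-open ``[age_min, age_max)`` and must tile the supported
    range without overlap so that every (sex, age) query resolves to exactly
    one band.
    """

    def __init__(
        self,
        adp_density_constants: dict,
        hydration_coefficients: dict,
        adipose_density_kg_per_L: float = 0.92,
    ) -> None:
        self._adp = {Sex(s): self._build_bands(rows, ("c1", "c2"))
                     for s, rows in adp_density_constants.items()}
        self._hydration = {Sex(s): self._build_bands(rows, ("coefficient",))
                           for s, rows in hydration_coefficients.items()}
        if not (0.8 < adipose_density_kg_per_L < 1.1):
            raise ValueError("adipose density outside plausible (0.8, 1.1) kg/L")
        self.adipose_density_kg_per_L = float(adipose_density_kg_per_L)
        for bands in self._adp.values():
            for b in bands:
                if b.values["c1"] <= 0 or b.values["c2"] <= 0:
                    raise ValueError("ADP density constants must be positive")
        for bands in self._hydration.values():
            for b in bands:
                if not (0.60 < b.values["coefficient"] < 0.85):
                    raise ValueError(
                        f"hydration coefficient {b.values['coefficient']} outside (0.60, 0.85)")

    @staticmethod
    def _build_bands(rows, keys) -> list:
        bands = sorted(
            (AgeBand(float(r["age_min"]), float(r["age_max"]),
                     {k: float(r[k]) for k in keys}) for r in rows),
            key=lambda b: b.age_min,
        )
        for lo, hi in zip(bands, bands[1:]):
            if lo.age_max > hi.age_min:
                raise ValueError(
                    f"overlapping age bands [{lo.age_min}, {lo.age_max}) and "
                    f"[{hi.age_min}, {hi.age_max})")
        return bands

    @staticmethod
    def _lookup(bands: list, age_years: float, what: str) -> dict:
        hits = [b for b in bands if b.contains(age_years)]
        if len(hits) != 1:
            raise LookupError(f"no unique {what} band for age {age_years:.2f} y")
        return hits[0].values

    def adp_constants(self, sex: Sex, age_years: float) -> tuple:
        """(c1, c2) of the density equation %FM = (c1/Db - c2)*100."""
        v = self._lookup(self._adp[Sex(sex)], age_years, "ADP-constant")
        return v["c1"], v["c2"]

    def hydration_coefficient(self, sex: Sex, age_years: float) -> float:
        """Assumed TBW/FFM ratio (dimensionless fraction)."""
        v = self._lookup(self._hydration[Sex(sex)], age_years, "hydration")
        return v["coefficient"]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ConstantsTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            adp_density_constants=raw["adp_density_constants"],
            hydration_coefficients=raw["hydration_coefficients"],
            adipose_density_kg_per_L=raw.get("adipose_density_kg_per_L", 0.92),
        )

    @classmethod
    def default(cls) -> "ConstantsTable":
        """Packaged Lohman-style defaults (see data/constants.yaml)."""
        ref = importlib.resources.files("bodycomp").joinpath("data/constants.yaml")
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)
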