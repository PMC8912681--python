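"""Synthetic age/sex-stratified cohorts with controlled instrument errors.

The generator works in two stages:

1. :func:`generate_truth` draws per-participant truth — weight, height,
   age, and 4-C fat fraction — from truncated correlated normal marginals
   per stratum, then derives the remaining truth quantities so that the 4-C
   forward map reproduces the drawn fat mass exactly: TBW through the
   hydration coefficient, BMC as a configurable fraction of FFM, and body
   volume by inverting the 4-C equation.

2. :func:`apply_instrument_errors` perturbs each method's fat mass as
   ``observed = true + bias + slope*true + Normal(0, sd)`` and back-solves
   the raw measurements (skinfold replicates, ADP volume readings, bottle
   weights and enrichments, DXA components, voxel counts) so that running
   the estimation pipeline on the emitted CSV reproduces the intended
   observed value. Back-solving raw data rather than emitting fat mass
   directly keeps the estimators themselves inside every end-to-end test.

Method errors are drawn independently per method (their joint distribution
is configurable only through this module's code; nothing in the emulated
study constrains it).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import fourc, instruments
from .agreement import bland_altman, simple_linear_regression
from .constants import ConstantsTable
from .datatypes import AgeGroup, Method, PairedSeries, Sex

AGE_BOUNDS = {AgeGroup.CHILDREN: (4.0, 11.0), AgeGroup.ADOLESCENTS: (11.0, 19.0)}

# physiologic truncation bounds for the drawn marginals
WEIGHT_BOUNDS_KG = (10.0, 130.0)
HEIGHT_BOUNDS_CM = (85.0, 205.0)
FAT_FRACTION_BOUNDS = (0.05, 0.55)

# correlation of (age, weight, height, fat fraction) within a stratum;
# the weight-fat entry is replaced by the stratum's size_fatness_corr
_BASE_CORR = np.array([
    [1.0, 0.8, 0.8, 0.0],
    [0.8, 1.0, 0.7, 0.5],
    [0.8, 0.7, 1.0, 0.2],
    [0.0, 0.5, 0.2, 1.0],
])


@dataclass(frozen=True)
class StratumSpec:
    """Marginal means/SDs of one age-sex stratum of the emulated cohort."""

    sex: Sex
    age_group: AgeGroup
    n: int
    age_mean: float
    age_sd: float
    weight_mean_kg: float
    weight_sd_kg: float
    height_mean_cm: float
    height_sd_cm: float
    fat_fraction_mean: float
    fat_fraction_sd: float
    size_fatness_corr: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "age_group", AgeGroup(self.age_group))
        if self.n < 3:
            raise ValueError("stratum n must be >= 3")
        for sd in (self.age_sd, self.weight_sd_kg, self.height_sd_cm, self.fat_fraction_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if not (0.03 < self.fat_fraction_mean < 0.55):
            raise ValueError("fat fraction mean outside (0.03, 0.55)")


@dataclass(frozen=True)
class MethodError:
    """Error structure of one method: observed = true + bias + slope*true + noise."""

    constant_bias_kg: float = 0.0
    proportional_slope: float = 0.0
    residual_sd_kg: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd_kg < 0:
            raise ValueError("residual_sd_kg must be >= 0")


@dataclass(frozen=True)
class ErrorModelSpec:
    per_method: Dict[str, MethodError] = field(default_factory=dict)

    def get(self, method: Union[Method, str]) -> MethodError:
        key = Method(method).value
        return self.per_method.get(key, MethodError())


TRUTH_COLUMNS = [
    "id", "sex", "age_years", "weight_kg", "height_cm",
    "true_fm_kg", "true_ffm_kg", "true_fat_fraction",
    "true_tbw_kg", "true_tbw_L", "true_bmc_g", "true_bv_L", "true_tgv_L",
]


def _truncated_mvn(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    corr: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    max_rounds: int = 200,
) -> np.ndarray:
    """Rejection-sample n draws of a correlated normal inside a box."""
    cov = corr * np.outer(sds, sds)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(means)))
    out = np.empty((0, len(means)))
    for _ in range(max_rounds):
        need = n - len(out)
        if need <= 0:
            break
        draw = means + rng.standard_normal((max(2 * need, 16), len(means))) @ chol.T
        ok = np.all((draw >= lows) & (draw <= highs), axis=1)
        out = np.vstack([out, draw[ok]])
    if len(out) < n:
        raise RuntimeError("truncated sampling failed: bounds too tight for the spec")
    return out[:n]


def generate_truth(
    specs: Sequence[StratumSpec],
    seed: Union[int, np.random.Generator],
    constants: Optional[ConstantsTable] = None,
    bmc_ffm_fraction: float = 0.048,
    tgv_weight_fraction: float = 0.05,
) -> pd.DataFrame:
    """Seeded truth table for a multi-stratum cohort.

    Fat mass, FFM, TBW (via the hydration coefficient), BMC (as a fraction
    of FFM) and body volume (4-C inverse) are derived from the drawn
    (age, weight, height, fat fraction) so that
    ``fuller_fat_mass(true_bv, true_tbw_L, true_bmc, weight) == true_fm``
    to machine precision.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constants = constants or ConstantsTable.default()
    frames = []
    for k, spec in enumerate(specs):
        corr = _BASE_CORR.copy()
        corr[1, 3] = corr[3, 1] = spec.size_fatness_corr
        age_lo, age_hi = AGE_BOUNDS[spec.age_group]
        draws = _truncated_mvn(
            rng, spec.n,
            means=np.array([spec.age_mean, spec.weight_mean_kg,
                            spec.height_mean_cm, spec.fat_fraction_mean]),
            sds=np.array([spec.age_sd, spec.weight_sd_kg,
                          spec.height_sd_cm, spec.fat_fraction_sd]),
            corr=corr,
            lows=np.array([age_lo, WEIGHT_BOUNDS_KG[0], HEIGHT_BOUNDS_CM[0],
                           FAT_FRACTION_BOUNDS[0]]),
            highs=np.array([age_hi - 1e-9, WEIGHT_BOUNDS_KG[1], HEIGHT_BOUNDS_CM[1],
                            FAT_FRACTION_BOUNDS[1]]),
        )
        age, weight, height, fat_frac = draws.T
        fm = fat_frac * weight
        ffm = weight - fm
        hydr = np.array([constants.hydration_coefficient(spec.sex, a) for a in age])
        tbw_kg = hydr * ffm
        tbw_L = tbw_kg / instruments.WATER_DENSITY_36C_KG_PER_L
        bmc_g = bmc_ffm_fraction * ffm * 1000.0
        # invert the 4-C map for the body volume consistent with the drawn FM
        bv = (fm + fourc.FOURC_TBW * tbw_L - fourc.FOURC_BMC * bmc_g / 1000.0
              + fourc.FOURC_WEIGHT * weight) / fourc.FOURC_BV
        bad = np.nonzero(bv <= 0)[0]
        if bad.size:
            raise ValueError(f"infeasible spec: non-positive body volume at draw {bad[0]}")
        prefix = f"{spec.sex.value[0].upper()}{spec.age_group.value[0].upper()}{k}"
        frames.append(pd.DataFrame({
            "id": [f"{prefix}-{i:03d}" for i in range(spec.n)],
            "sex": spec.sex.value,
            "age_years": age,
            "weight_kg": weight,
            "height_cm": height,
            "true_fm_kg": fm,
            "true_ffm_kg": ffm,
            "true_fat_fraction": fat_frac,
            "true_tbw_kg": tbw_kg,
            "true_tbw_L": tbw_L,
            "true_bmc_g": bmc_g,
            "true_bv_L": bv,
            "true_tgv_L": tgv_weight_fraction * weight,
        }))
    return pd.concat(frames, ignore_index=True)[TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# back-solving raw measurements

_MAX_RETRIES = 100


def _backsolve_sf(pct: float, sex: Sex) -> Optional[dict]:
    slope, intercept = instruments.SLAUGHTER_COEFFS[sex]
    sf_sum = (pct - intercept) / slope
    site = sf_sum / 2.0
    if not (0.5 <= site <= instruments.CALIPER_MAX_MM):
        return None
    # replicate jitter that averages out exactly (caliper precision scale)
    d = 0.2
    reps = [site + d, site - d, site + d / 2, site - d / 2]
    if any(not (0 < r <= instruments.CALIPER_MAX_MM) for r in reps):
        return None
    return {
        "tri_sf_1": reps[0], "tri_sf_2": reps[1], "tri_sf_3": reps[2], "tri_sf_4": reps[3],
        "calf_sf_1": reps[0], "calf_sf_2": reps[1], "calf_sf_3": reps[2], "calf_sf_4": reps[3],
    }


def _backsolve_adp(pct: float, weight: float, tgv: float, sex: Sex, age: float,
                   constants: ConstantsTable) -> Optional[dict]:
    c1, c2 = constants.adp_constants(sex, age)
    density = c1 / (pct / 100.0 + c2)
    if not (0.9 < density < 1.15):
        return None
    bv = weight / density
    raw = bv - instruments.TGV_CORRECTION_FRACTION * tgv
    if raw <= 0:
        return None
    d = 0.010  # 10 mL split between the two readings, mean exact
    return {
        "adp_mass_kg": weight,
        "adp_vol1_L": raw + d, "adp_vol2_L": raw - d, "adp_vol3_L": np.nan,
        "adp_tgv_L": tgv,
    }


def _backsolve_dxa(fm_obs: float, weight: float, bmc_g: float) -> Optional[dict]:
    if fm_obs < 0:
        return None
    lm = weight - fm_obs - bmc_g / 1000.0
    if lm <= 0:
        return None
    return {"dxa_lm_kg": lm, "dxa_bmc_g": bmc_g, "dxa_fm_kg": fm_obs}


def _backsolve_d2o(fm_obs: float, weight: float, hydration: float) -> Optional[dict]:
    ffm = weight - fm_obs
    if ffm <= 0:
        return None
    tbw_kg = hydration * ffm
    dose_weighed = 0.05 * weight  # exactly on target
    empty = 20.00
    residual = 0.30  # grams left in the bottle, under the 1 g rule
    d2o = empty + dose_weighed
    d2o_water = d2o + 50.0
    drunk = empty + residual
    consumed = dose_weighed * (d2o_water - drunk) / (d2o_water - empty)
    delta_ap = (
        consumed * (99.9 / instruments.D2O_MOLECULAR_WEIGHT)
        * instruments.WATER_MOLECULAR_WEIGHT
    ) * 1e-3 / instruments.PROTON_EXCHANGE_CORRECTION / tbw_kg
    ap_pre = 0.0149  # natural abundance, atom percent
    return {
        "d2o_bottle_empty_g": empty,
        "d2o_bottle_d2o_g": d2o,
        "d2o_bottle_d2o_water_g": d2o_water,
        "d2o_bottle_drunk_g": drunk,
        "d2o_ap_pre_pct": ap_pre,
        "d2o_ap_post_pct": ap_pre + delta_ap,
    }


def _backsolve_mri(fm_obs: float, voxel_vol_L: float, density: float) -> Optional[dict]:
    if fm_obs < 0:
        return None
    n_vox = int(round(fm_obs / (voxel_vol_L * density)))
    return {"mri_n_voxels": n_vox, "mri_voxel_vol_L": voxel_vol_L}


COHORT_COLUMNS = [
    "id", "sex", "age_years", "weight_kg", "height_cm",
    "tri_sf_1", "tri_sf_2", "tri_sf_3", "tri_sf_4",
    "calf_sf_1", "calf_sf_2", "calf_sf_3", "calf_sf_4",
    "adp_mass_kg", "adp_vol1_L", "adp_vol2_L", "adp_vol3_L", "adp_tgv_L",
    "dxa_lm_kg", "dxa_bmc_g", "dxa_fm_kg",
    "d2o_bottle_empty_g", "d2o_bottle_d2o_g", "d2o_bottle_d2o_water_g",
    "d2o_bottle_drunk_g", "d2o_ap_pre_pct", "d2o_ap_post_pct",
    "mri_n_voxels", "mri_voxel_vol_L",
]


def apply_instrument_errors(
    truth: pd.DataFrame,
    errors: ErrorModelSpec,
    seed: Union[int, np.random.Generator],
    constants: Optional[ConstantsTable] = None,
    mri_voxel_volume_L: float = 1.35e-5,
) -> pd.DataFrame:
    """Raw-measurement cohort whose pipeline estimates carry the given errors.

    For each instrument method the observed fat mass is the truth plus the
    method's constant bias, proportional component, and Gaussian residual;
    the raw columns are then back-solved so the estimation pipeline returns
    exactly that observed value (MRI is quantized to whole voxels). A draw
    whose back-solve violates a raw-measurement invariant is redrawn
    (bounded retries) before giving up.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constants = constants or ConstantsTable.default()
    rows = []
    for rec in truth.to_dict("records"):
        sex = Sex(rec["sex"])
        age = float(rec["age_years"])
        weight = float(rec["weight_kg"])
        true_fm = float(rec["true_fm_kg"])
        hydration = constants.hydration_coefficient(sex, age)
        row = {
            "id": rec["id"], "sex": sex.value, "age_years": age,
            "weight_kg": weight, "height_cm": rec["height_cm"],
        }

        def observed(method: Method) -> float:
            e = errors.get(method)
            noise = rng.normal(0.0, e.residual_sd_kg) if e.residual_sd_kg > 0 else 0.0
            return true_fm + e.constant_bias_kg + e.proportional_slope * true_fm + noise

        def solve(method: Method, fn) -> dict:
            for _ in range(_MAX_RETRIES):
                out = fn(observed(method))
                if out is not None:
                    return out
            raise RuntimeError(f"back-solve failed for {method.value} at {rec['id']}")

        row.update(solve(Method.SF,
                         lambda fm: _backsolve_sf(100.0 * fm / weight, sex)))
        row.update(solve(Method.ADP,
                         lambda fm: _backsolve_adp(100.0 * fm / weight, weight,
                                                   float(rec["true_tgv_L"]), sex, age,
                                                   constants)))
        row.update(solve(Method.DXA,
                         lambda fm: _backsolve_dxa(fm, weight, float(rec["true_bmc_g"]))))
        row.update(solve(Method.D2O,
                         lambda fm: _backsolve_d2o(fm, weight, hydration)))
        row.update(solve(Method.MRI,
                         lambda fm: _backsolve_mri(fm, mri_voxel_volume_L,
                                                   constants.adipose_density_kg_per_L)))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_cohort(
    specs: Sequence[StratumSpec],
    errors: ErrorModelSpec,
    seed: int,
    constants: Optional[ConstantsTable] = None,
    **kwargs,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: one seed -> (raw cohort frame, truth frame)."""
    rng = np.random.default_rng(seed)
    constants = constants or ConstantsTable.default()
    truth_kwargs = {k: kwargs[k] for k in ("bmc_ffm_fraction", "tgv_weight_fraction")
                    if k in kwargs}
    truth = generate_truth(specs, rng, constants, **truth_kwargs)
    err_kwargs = {k: kwargs[k] for k in ("mri_voxel_volume_L",) if k in kwargs}
    cohort = apply_instrument_errors(truth, errors, rng, constants, **err_kwargs)
    return cohort, truth


def default_scenario(
    path: Optional[Union[str, Path]] = None,
) -> Tuple[List[StratumSpec], ErrorModelSpec, dict]:
    """The packaged study-shaped scenario (four strata summing to 288).

    Returns ``(strata, errors, options)``; options carries the generator
    knobs (size-fatness correlation, BMC fraction, TGV fraction, MRI voxel
    volume).
    """
    if path is None:
        ref = importlib.resources.files("bodycomp").joinpath("data/scenario.yaml")
        with importlib.resources.as_file(ref) as p:
            raw = yaml.safe_load(Path(p).read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    options = raw.get("options", {})
    corr = options.get("size_fatness_corr", 0.5)
    strata = [StratumSpec(size_fatness_corr=corr, **s) for s in raw["strata"]]
    errors = ErrorModelSpec(per_method={
        m: MethodError(**vals) for m, vals in raw["errors"].items()})
    return strata, errors, options


@dataclass(frozen=True)
class RecoveryResult:
    """Injected-error recovery against the truth columns."""

    bias_est: float
    bias_sd: float
    slope_est: float
    slope_p: float
    intercept_est: float
    n: int


def recover_error_model(
    estimates: pd.DataFrame, truth: pd.DataFrame, method: Union[Method, str],
    value: str = "fm_kg",
) -> RecoveryResult:
    """Recover a method's injected error parameters from pipeline output.

    Pairs the method's pipeline estimates with the hidden truth, then takes
    the Bland-Altman bias of (estimate - truth) and the OLS of the
    differences on the true fat mass — whose slope and intercept estimate
    the injected proportional slope and constant bias directly and without
    attenuation (regressing on the pair average instead would mix the
    method's own residual into the regressor).
    """
    m = Method(method).value
    est = estimates.loc[estimates["method"] == m].set_index("participant_id")[value]
    tru = truth.set_index("id")["true_fm_kg"]
    joined = pd.concat([est.rename("obs"), tru.rename("true")], axis=1).dropna()
    pairs = PairedSeries(method_values=tuple(joined["obs"]),
                         reference_values=tuple(joined["true"]))
    ba = bland_altman(pairs)
    diffs = joined["obs"].to_numpy() - joined["true"].to_numpy()
    fit = stats.linregress(joined["true"].to_numpy(), diffs)
    return RecoveryResult(
        bias_est=ba.bias, bias_sd=ba.sd,
        slope_est=float(fit.slope), slope_p=float(fit.pvalue),
        intercept_est=float(fit.intercept), n=len(joined),
    )
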