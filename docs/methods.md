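# Methods

This note documents the models implemented in `bodycomp`, the assumptions
behind them, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Measurement models

**Skinfolds.** Site means are the arithmetic mean of 1–4 replicate caliper
readings (the protocol takes four: two per body side). Estimates built from
fewer than four replicates carry an `SF_REPLICATES_LT_4` flag rather than
being rejected; real datasets commonly lose replicates. The two-site
Slaughter equations are affine in the triceps+calf sum and the male/female
lines cross at 32.8 mm; the implementation covers only the two-site
triceps+calf forms (not the ≥35 mm or trunk-site variants). Percent fat is
clamped to [0, 100] only when converting to fat mass, never inside the
equation itself.

**ADP.** Two raw volume readings within 150 mL are averaged; otherwise a
third reading is required and the closest agreeing pair wins, with ties
broken toward the pair containing the earliest reading (deterministic and
permutation-stable in the value it returns). The selected volume is
corrected for thoracic gas volume as BV = V_raw + 0.40·TGV — the standard
plethysmographic correction; TGV itself is an input (predicted or
measured), never computed here. Density converts to percent fat through
age/sex-banded (c1, c2) constants. The packaged table is Lohman-style; the
exact constants used by any given pediatric software build are proprietary,
so they are configuration (`data/constants.yaml`), and the test suite
passes synthetic constants wherever correctness must not depend on the
defaults. Age bands are half-open `[min, max)` and must tile 4–19 y, so
every query resolves uniquely.

**DXA.** FFM = lean soft tissue + BMC/1000. DXA's fat mass comes from the
scan rather than from weight − FFM, so FM + FFM need not equal scale
weight for this method; percent fat is reported against scale weight.

**Deuterium dilution.** The consumed dose is the weighed isotope times the
consumed fraction of the bottle content, from four weighings. The three
outlier rules are implemented exactly as printed: bottle lighter than empty
after drinking; more than 1 g residual; weighed dose deviating more than
15% (relative) from the 0.05 g/kg target. Any flag voids the session: the
participant contributes neither a D2O nor a 4-C estimate, and the exclusion
is reported, mirroring explicit exclusion accounting in real studies. The
TBW formula is implemented exactly as printed (the 10⁻³ g→kg factor applied
before dividing by the 1.04 proton-exchange correction — the arrangement is
associative, so this is a documentation point, not a numerical one);
dimensionally, dose(g)·18.02/20 is grams of equivalent water, ΔAP in % makes
the quotient grams of body water, 10⁻³ converts to kg. TBW in liters
divides by 0.99371 kg/L (water at 36 °C). FFM = TBW/hydration coefficient
with the same configurable age/sex table convention as ADP.

**MRI.** Fat mass is voxel count × voxel volume × adipose density
(default 0.92 kg/L, configurable). Only this arithmetic is in scope —
acquisition and segmentation are upstream of the package.

**4-C model.** FM = 2.7474·BV − 0.7145·TBW + 1.4599·BMC/1000 −
2.0503·weight with BV in liters, TBW in liters, BMC in grams. TBW enters in
liters by default; a `tbw_in_kg` switch supports sensitivity checks. The
map is linear, which gives two free self-checks used in the tests:
homogeneity/additivity against a brute-force re-evaluation, and equality of
stratum-mean FM with FM at stratum-mean inputs (to 1e-9). In the pipeline
the 4-C inputs come from the same raw columns the instrument methods use
(ADP volume, D2O enrichment, DXA BMC), as in a real study.

## Agreement statistics

Differences are always method − reference. The Bland–Altman limits of
agreement default to bias ± 2.0·SD because the emulated protocol prints
±2 SD; 1.96 is available by argument. Pearson CIs use the Fisher
z-transform with SE 1/√(n−3); Lin's CCC uses population (1/n) moments per
Lin's original definition with the Lin (1989) Z-transform variance for its
CI; regression CIs use t quantiles with n−2 df (the emulated report does
not state its choice; t is the conventional small-sample default). The
calibration regression always regresses method on reference. A paired t
with zero-variance nonzero differences is reported as p = 0 with a
`constant-difference` flag instead of dividing by zero. No multiple-testing
correction is applied anywhere, matching the emulated analysis. The design
sample-size rule is n = ceil(((z₁₋α/₂+z_power)/atanh ρ)² + 3) against a
zero-correlation null; at ρ = 0.90, α = 0.05, power 0.80 it gives 7
participants per age-year/sex stratum.

Comparison tables are computed per sex × age-group cell (children 4–10 y,
adolescents 11–18 y) plus the total; cells with fewer than 3 complete pairs
are emitted with an `insufficient-n` flag, never dropped silently.

## Synthetic cohort

The generator emulates a 288-participant cross-sectional pediatric cohort
in four strata (63 / 54 / 92 / 79; female/male × children/adolescents)
whose marginal means and SDs for age, weight, height and 4-C fat fraction
match the emulated study's descriptive table. Draws come from truncated
correlated normals; truncation bounds are physiologic (weight 10–130 kg,
height 85–205 cm, fat fraction 0.05–0.55, age within the group's bounds).
The within-stratum correlation structure is not derivable from published
summaries, so it is a modeling choice: age–size 0.8, weight–height 0.7, and
weight–fat-fraction 0.5 by default (configurable per stratum).

Truth derivations: FM = fat fraction × weight; TBW = hydration
coefficient × FFM (same table the estimator uses, so the zero-error round
trip is exact); BMC = 0.048 × FFM (a simulation convenience tuned to give
table-scale stratum BMC means, not a physiological claim); TGV = 0.05 ×
weight; BV by inverting the 4-C equation so the forward map returns the
drawn FM to machine precision.

Instrument errors follow `observed FM = true FM + bias + slope·true FM +
N(0, sd)` independently per method (the joint error distribution across
methods is unreported in the emulated study; independence is the default).
Raw measurements are then back-solved through each estimation chain —
skinfold sums through the Slaughter inverse, volumes through the density
equation, bottle weights and enrichments through the dilution formulas, DXA
components by partitioning observed FFM — so the estimators themselves sit
inside every end-to-end test. MRI voxel counts are integers, so MRI is
reproduced only to voxel quantization (≤ ~10⁻⁴ kg at the default
1.35×10⁻⁵ L voxel). A draw whose back-solve would violate a raw-measurement
invariant (e.g. a percent fat below the Slaughter intercept) is redrawn up
to 100 times, then raises. Default error parameters are table-scale:
biases/slopes from the emulated total-sample Bland–Altman regressions and
residual SDs from the printed difference SDs (an upper bound, since the
printed SD includes the proportional component).

**Parameter recovery.** Recovery tests compare pipeline estimates against
the hidden truth columns: the Bland–Altman bias of (estimate − truth)
recovers an injected constant bias, and OLS of the differences on true FM
recovers the injected proportional slope without attenuation. Regressing on
the pair average instead (the reporting-convention proportional-bias
statistic) mixes the method's own residual into the regressor and shrinks
an injected slope of −0.1 to ≈ −0.02…−0.06 depending on the reference's
noise — a known property of difference-vs-average regression, which is why
recovery is defined against truth while the reporting statistic keeps the
conventional difference-vs-average form.

What passing tests show: the conversion chains are arithmetically correct,
the statistics match independent direct-summation oracles to 1e-10, and
injected error structure survives the full raw-data round trip at study
scale. What they do not show: anything about real instrument physics —
the generator has Gaussian, method-independent errors, no replicate-level
measurement noise beyond exact-mean jitter, no missingness mechanism, and
no MRI subsample selection.

## Numerical and scale choices

Simulation-based tests use n = 288 cohorts and 200 Monte-Carlo seeds — the
emulated study's size, and enough for the binomial pass-rate assertions
(≥95% significance, ≥99% bias coverage) to be stable across seeds; the full
suite runs in well under a minute. Degenerate inputs are errors, not NaNs:
zero-variance series, empty reading lists, non-positive masses. CSV reports
round to 4 decimals; machine-readable outputs keep full precision. All
randomness flows through `numpy.random.default_rng(seed)`; identical seeds
give byte-identical cohort CSVs.

## Known limitations

- The packaged (c1, c2) and hydration tables are plausible Lohman-style
  defaults, not the proprietary constants of any specific device software.
- DXA percent fat is referenced to scale weight, not scan mass.
- The 4-C estimate inherits correlated error from ADP/D2O/DXA inputs, so
  method-vs-4-C biases in simulated comparison tables differ slightly from
  the injected method-vs-truth parameters; this is realistic and intended.
- Only the two-site pediatric skinfold equations are provided.
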