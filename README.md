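# bodycomp

Body-composition assessment in children and adolescents: per-instrument
estimation of fat mass (FM), fat-free mass (FFM) and percent fat, the
4-component (4-C) reference model, and the full method-agreement battery
used to compare clinical techniques against that reference.

The package is aimed at researchers running pediatric body-composition
method-comparison studies: it converts raw instrument measurements
(skinfold caliper replicates, BOD POD volume readings, DXA components,
deuterium-dilution bottle weights and saliva enrichments, MRI fat-voxel
counts) into per-method composition estimates, and quantifies how well each
method agrees with the 4-C criterion. A seeded synthetic-cohort generator
with a configurable measurement-error model stands in for real participant
data, so the whole pipeline is runnable and testable end to end.

## The models

**Skinfolds** (two-site Slaughter equations, triceps + calf sum *s* in mm):

    males:   %FM = 0.735 s + 1.0
    females: %FM = 0.610 s + 5.1        FM = %FM/100 × weight

**ADP**: raw chamber volumes are reduced by the 150 mL agreement rule,
corrected for thoracic gas volume (BV = V_raw + 0.40·TGV), converted to
whole-body density D_b = mass/BV, then %FM = (c1/D_b − c2)·100 with
age- and sex-specific (c1, c2) from a configurable Lohman-style table.

**DXA**: FFM = lean soft tissue + BMC/1000; FM is taken from the scan.

**Deuterium dilution**: consumed dose from four bottle weighings, three
printed outlier rules (impossible bottle weight, >1 g residual, dose off
the 0.05 g/kg target by >15%), then plateau total body water

    TBW(kg) = dose·(conc/20)·18.02 / ΔAP · 10⁻³ / 1.04,   TBW(L) = TBW(kg)/0.99371

and FFM = TBW/hydration-coefficient (age/sex table).

**MRI**: FM = n_fat_voxels × voxel volume × adipose density (0.92 kg/L).

**4-C reference** (BV in L, TBW in L, BMC in g, weight in kg):

    FM = 2.7474·BV − 0.7145·TBW + 1.4599·BMC/1000 − 2.0503·weight,  FFM = weight − FM

**Agreement battery** (each method vs. 4-C, FM or FFM): Pearson r with
Fisher-z CI, Lin's concordance correlation coefficient with the Lin (1989)
CI, OLS calibration regression, paired t-test, and Bland–Altman bias with
±2 SD limits of agreement plus a proportional-bias regression of the
differences (method − reference) on the pair averages.

## Worked example

```bash
bodycomp run-all --seed 1 --out out/
```

simulates a 288-participant cohort (four age/sex strata), estimates all six
methods per participant, and writes Table-style agreement reports. The
total-sample FM comparison from that exact command:

```
method group  n_pairs  pearson_r   ccc   bias  loa_low  loa_high  prop_bias_slope  prop_bias_p
   ADP total      288      0.973 0.966 -0.833   -4.085     2.420           -0.033        0.016
   D2O total      288      0.982 0.964  1.220   -1.969     4.410            0.101        0.000
   DXA total      288      0.923 0.817  3.593   -1.962     9.147            0.008        0.731
   MRI total      288      0.880 0.753  3.959   -2.811    10.729           -0.056        0.064
    SF total      288      0.903 0.896  0.641   -5.420     6.703           -0.087        0.001
```

Read it as a method-comparison table: every method correlates strongly with
the 4-C reference (r ≥ 0.88) yet they are not interchangeable — DXA and MRI
over-read FM by ≈3.6–4.0 kg on average, ADP under-reads by ≈0.8 kg, and the
significant negative proportional-bias slope for SF (−0.087, p = 0.001)
means skinfolds increasingly under-read fat in fatter participants, while
D2O shows the opposite trend. These patterns are exactly the error
structure the default simulation scenario injects, recovered through the
full raw-measurement → estimation → statistics chain.

Library use mirrors the CLI:

```python
from bodycomp import default_scenario, simulate_cohort, estimate_cohort, comparison_table

strata, errors, opts = default_scenario()
cohort, truth = simulate_cohort(strata, errors, seed=1)
estimates, issues = estimate_cohort(cohort)
table = comparison_table(estimates, cohort, grouping="sex_age")
```

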