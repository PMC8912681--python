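"""Unit and property tests for the per-instrument measurement conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bodycomp import (
    ConstantsTable,
    DeuteriumSession,
    DoseFlag,
    MriVoxelSummary,
    Sex,
    adp_percent_fat,
    bmi,
    body_density,
    corrected_body_volume,
    d2o_dose_g,
    dose_outlier_flags,
    dxa_ffm,
    fat_mass_from_percent,
    ffm_from_tbw,
    mean_skinfold_site,
    mri_fat_mass,
    select_body_volume,
    slaughter_percent_fat,
    tbw_from_dilution,
)

import _oracles


class TestSkinfolds:
    @pytest.mark.parametrize("readings, expected", [
        ([10, 10, 10, 10], 10.0),
        ([8, 9, 10, 13], 10.0),
        ([12.2], 12.2),
    ])
    def test_site_mean(self, readings, expected):
        assert mean_skinfold_site(readings) == pytest.approx(expected)

    def test_site_mean_rejects_bad_input(self):
        with pytest.raises(ValueError, match="no readings"):
            mean_skinfold_site([])
        with pytest.raises(ValueError):
            mean_skinfold_site([85.0])  # beyond the caliper scale
        with pytest.raises(ValueError):
            mean_skinfold_site([10, 10, 10, 10, 10])

    @pytest.mark.parametrize("sex, sf_sum, expected", [
        (Sex.FEMALE, 32.3, 24.8),   # stratum-mean skinfold sum, 1 dp
        (Sex.MALE, 22.1, 17.2),
        (Sex.MALE, 0.0, 1.0),       # intercept
        (Sex.FEMALE, 10.0, 11.2),
    ])
    def test_slaughter_two_site(self, sex, sf_sum, expected):
        pct = slaughter_percent_fat(sex, sf_sum / 2, sf_sum / 2)
        assert round(pct, 1) == pytest.approx(expected)

    def test_slaughter_lines_cross_at_32_8_mm(self):
        """0.735s + 1.0 = 0.610s + 5.1 at s = 32.8 mm."""
        s = 32.8
        assert slaughter_percent_fat(Sex.MALE, s / 2, s / 2) == pytest.approx(
            slaughter_percent_fat(Sex.FEMALE, s / 2, s / 2))

    @given(st.floats(0.1, 79.9), st.floats(0.01, 5.0))
    def test_slaughter_strictly_increasing(self, s, ds):
        for sex in (Sex.MALE, Sex.FEMALE):
            assert (slaughter_percent_fat(sex, (s + ds) / 2, (s + ds) / 2)
                    > slaughter_percent_fat(sex, s / 2, s / 2))

    def test_negative_site_mean_rejected(self):
        with pytest.raises(ValueError):
            slaughter_percent_fat(Sex.MALE, -1.0, 10.0)


class TestMassAndBmi:
    @pytest.mark.parametrize("pct, w, expected", [
        (0, 50, 0.0), (50, 40, 20.0), (24.8, 51.2, 12.6976),
    ])
    def test_fat_mass_from_percent(self, pct, w, expected):
        assert fat_mass_from_percent(pct, w) == pytest.approx(expected)

    def test_fat_mass_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fat_mass_from_percent(101, 50)
        with pytest.raises(ValueError):
            fat_mass_from_percent(50, 0)

    @pytest.mark.parametrize("w, h, expected", [
        (50, 200, 12.5), (26.1, 123.5, 17.11), (81, 90, 100.0),
    ])
    def test_bmi(self, w, h, expected):
        assert bmi(w, h) == pytest.approx(expected, abs=5e-3)


class TestAdpChain:
    def test_two_agreeing_readings_averaged(self):
        assert select_body_volume([20.000, 20.100]) == pytest.approx(20.050)

    def test_closest_agreeing_pair_of_three(self):
        assert select_body_volume([20.000, 20.300, 20.250]) == pytest.approx(20.275)

    def test_two_disagreeing_readings_need_a_third(self):
        with pytest.raises(ValueError, match="third reading required"):
            select_body_volume([20.0, 20.2])

    def test_no_agreeing_pair(self):
        with pytest.raises(ValueError, match="no agreeing pair"):
            select_body_volume([20.0, 20.5, 21.0])

    def test_tie_break_prefers_pair_with_earliest_reading(self):
        # pairs (0,1) and (0,2) both differ by 0.1; (0,1) wins
        assert select_body_volume([20.0, 20.1, 19.9]) == pytest.approx(20.05)

    @given(st.lists(st.floats(20.0, 21.0), min_size=3, max_size=3))
    def test_agrees_with_bruteforce_on_three_readings(self, readings):
        expected = _oracles.best_volume_pair(readings)
        if expected is None:
            with pytest.raises(ValueError):
                select_body_volume(readings)
        else:
            assert select_body_volume(readings) == pytest.approx(expected)

    def test_selection_value_is_permutation_invariant(self, rng):
        for _ in range(50):
            base = rng.uniform(20, 20.2, size=3)
            results = set()
            for perm in ([0, 1, 2], [1, 2, 0], [2, 0, 1], [2, 1, 0]):
                try:
                    results.add(round(select_body_volume(base[perm]), 12))
                except ValueError:
                    results.add("error")
            assert len(results) == 1

    @pytest.mark.parametrize("m, v, expected", [
        (50, 50, 1.0), (51.2, 49.1, 1.0428), (1, 2, 0.5),
    ])
    def test_body_density(self, m, v, expected):
        assert body_density(m, v) == pytest.approx(expected, abs=5e-5)

    def test_tgv_correction(self):
        assert corrected_body_volume(20.0, 2.0) == pytest.approx(20.8)

    def test_adp_percent_fat_siri_shape(self):
        assert adp_percent_fat(1.0, c1=4.95, c2=4.50) == pytest.approx(45.0)
        assert adp_percent_fat(1.10, c1=4.95, c2=4.50) == pytest.approx(0.0)
        # density c1/c2 is the zero-fat point for any constant pair
        assert adp_percent_fat(5.30 / 4.89, c1=5.30, c2=4.89) == pytest.approx(0.0)

    def test_adp_lookup_unresolvable_age_errors(self):
        with pytest.raises(LookupError):
            adp_percent_fat(1.05, Sex.MALE, 25.0, ConstantsTable.default())


class TestDxa:
    @pytest.mark.parametrize("lm, bmc, expected", [
        (31.8, 1900, 33.7), (16.9, 900, 17.8), (0, 0, 0.0),
    ])
    def test_ffm_is_lean_plus_bone(self, lm, bmc, expected):
        assert dxa_ffm(lm, bmc) == pytest.approx(expected)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            dxa_ffm(-1, 100)


def _session(empty=20.0, d2o=22.5, water=72.5, drunk=20.0, ap_pre=0.015, ap_post=0.025):
    return DeuteriumSession(
        bottle_empty_g=empty, bottle_d2o_g=d2o, bottle_d2o_water_g=water,
        bottle_drunk_g=drunk, ap_pre_pct=ap_pre, ap_post_pct=ap_post)


class TestDeuterium:
    @pytest.mark.parametrize("drunk, expected", [
        (20.0, 2.5),     # everything consumed
        (72.5, 0.0),     # nothing consumed
        (46.25, 1.25),   # half consumed
    ])
    def test_consumed_dose(self, drunk, expected):
        assert d2o_dose_g(_session(drunk=drunk)) == pytest.approx(expected)

    def test_empty_bottle_record_errors(self):
        s = _session(d2o=20.0, water=20.0)
        with pytest.raises(ValueError, match="empty bottle"):
            d2o_dose_g(s)

    @pytest.mark.parametrize("kwargs, weight, expected_flags", [
        ({"drunk": 19.9}, 50.0, {DoseFlag.IMPOSSIBLE_BOTTLE_WEIGHT}),
        ({"drunk": 21.5}, 50.0, {DoseFlag.RESIDUAL_GT_1G}),
        ({"drunk": 20.0}, 50.0, set()),                      # dose 2.5 g on target
        ({"d2o": 23.0, "drunk": 20.0}, 50.0, {DoseFlag.DOSE_OFF_TARGET}),  # 20% off
    ])
    def test_outlier_rules(self, kwargs, weight, expected_flags):
        assert dose_outlier_flags(_session(**kwargs), weight) == expected_flags

    def test_tbw_matches_stepwise_arithmetic(self):
        s = _session(ap_pre=0.015, ap_post=0.015 + 0.00834)
        tbw_kg, tbw_L = tbw_from_dilution(s, 2.5)
        assert tbw_kg == pytest.approx(25.95, abs=0.01)
        assert tbw_kg == pytest.approx(_oracles.tbw_kg(2.5, 99.9, s.ap_post_pct, s.ap_pre_pct))
        assert tbw_L * 0.99371 == pytest.approx(tbw_kg)

    def test_tbw_against_oracle_on_random_sessions(self, rng):
        for _ in range(100):
            dose = rng.uniform(0.5, 4.0)
            dap = rng.uniform(0.002, 0.03)
            s = _session(ap_pre=0.015, ap_post=0.015 + dap)
            tbw_kg, _ = tbw_from_dilution(s, dose)
            assert tbw_kg == pytest.approx(
                _oracles.tbw_kg(dose, 99.9, s.ap_post_pct, s.ap_pre_pct), rel=1e-12)

    def test_tbw_scaling_in_dose_and_enrichment(self):
        s1 = _session(ap_pre=0.015, ap_post=0.025)
        s2 = _session(ap_pre=0.015, ap_post=0.035)  # doubled enrichment difference
        kg1, _ = tbw_from_dilution(s1, 2.0)
        kg2, _ = tbw_from_dilution(s2, 2.0)
        kg3, _ = tbw_from_dilution(s1, 4.0)         # doubled dose
        assert kg2 == pytest.approx(kg1 / 2)
        assert kg3 == pytest.approx(kg1 * 2)

    def test_no_enrichment_errors(self):
        with pytest.raises(ValueError, match="no enrichment"):
            tbw_from_dilution(_session(ap_post=0.015), 2.5)

    def test_ffm_from_tbw(self):
        assert ffm_from_tbw(14.63, coefficient=0.732) == pytest.approx(19.99, abs=5e-3)
        assert ffm_from_tbw(12.0, coefficient=1.0) == pytest.approx(12.0)
        assert ffm_from_tbw(15.0, coefficient=0.75) > ffm_from_tbw(14.0, coefficient=0.75)


class TestMri:
    @pytest.mark.parametrize("n, vol, rho, expected", [
        (0, 0.01, 0.92, 0.0),
        (1000, 0.01, 0.92, 9.2),
    ])
    def test_fat_mass_product(self, n, vol, rho, expected):
        assert mri_fat_mass(MriVoxelSummary(n, vol, rho)) == pytest.approx(expected)

    def test_linear_in_voxel_count(self):
        one = mri_fat_mass(MriVoxelSummary(500, 0.001, 0.92))
        two = mri_fat_mass(MriVoxelSummary(1000, 0.001, 0.92))
        assert two == pytest.approx(2 * one)


class TestConstantsTable:
    def test_every_query_resolves_to_one_band(self):
        table = ConstantsTable.default()
        for sex in Sex:
            for age in np.arange(4.0, 19.0, 0.5):
                c1, c2 = table.adp_constants(sex, age)
                assert c1 > 0 and c2 > 0
                assert 0.60 < table.hydration_coefficient(sex, age) < 0.85

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConstantsTable(
                adp_density_constants={
                    "male": [{"age_min": 4, "age_max": 12, "c1": 5.3, "c2": 4.9},
                             {"age_min": 10, "age_max": 19, "c1": 5.0, "c2": 4.6}],
                    "female": [{"age_min": 4, "age_max": 19, "c1": 5.3, "c2": 4.9}]},
                hydration_coefficients={
                    "male": [{"age_min": 4, "age_max": 19, "coefficient": 0.76}],
                    "female": [{"age_min": 4, "age_max": 19, "coefficient": 0.77}]},
            )

    def test_implausible_hydration_rejected(self):
        with pytest.raises(ValueError, match="hydration"):
            ConstantsTable(
                adp_density_constants={
                    "male": [{"age_min": 4, "age_max": 19, "c1": 5.3, "c2": 4.9}],
                    "female": [{"age_min": 4, "age_max": 19, "c1": 5.3, "c2": 4.9}]},
                hydration_coefficients={
                    "male": [{"age_min": 4, "age_max": 19, "coefficient": 0.95}],
                    "female": [{"age_min": 4, "age_max": 19, "coefficient": 0.77}]},
            )
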