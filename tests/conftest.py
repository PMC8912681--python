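import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220307)


@pytest.fixture(scope="session")
def default_scenario_parts():
    from bodycomp import default_scenario

    strata, errors, options = default_scenario()
    return strata, errors, options


@pytest.fixture(scope="session")
def small_cohort():
    """A small error-free cohort plus truth, shared across tests."""
    import warnings

    from bodycomp import ErrorModelSpec, simulate_cohort
    from bodycomp.datatypes import AgeGroup, Sex
    from bodycomp.simulate import StratumSpec

    strata = [
        StratumSpec(sex=Sex.FEMALE, age_group=AgeGroup.CHILDREN, n=8,
                    age_mean=8.0, age_sd=1.5, weight_mean_kg=26.0, weight_sd_kg=5.0,
                    height_mean_cm=124.0, height_sd_cm=8.0,
                    fat_fraction_mean=0.20, fat_fraction_sd=0.05),
        StratumSpec(sex=Sex.MALE, age_group=AgeGroup.ADOLESCENTS, n=8,
                    age_mean=14.5, age_sd=1.5, weight_mean_kg=54.0, weight_sd_kg=8.0,
                    height_mean_cm=163.0, height_sd_cm=8.0,
                    fat_fraction_mean=0.18, fat_fraction_sd=0.05),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth = simulate_cohort(strata, ErrorModelSpec(), seed=7)
    return cohort, truth
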