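import numpy as np
import pytest

import synaptome_sd as sd


@pytest.fixture(scope="session")
def catalog():
    return sd.make_region_catalog()


@pytest.fixture(scope="session")
def lifetimes():
    return sd.make_lifetime_table(seed=0)


@pytest.fixture(scope="session")
def default_cohort(catalog, lifetimes):
    """One cohort at the default study conditions (SD effects injected)."""
    return sd.simulate_cohort(
        catalog, sd.CohortDesign(seed=11), sd.EffectSpec(), lifetimes)


@pytest.fixture(scope="session")
def null_cohort(catalog, lifetimes):
    """Cohort with every injected effect switched off."""
    return sd.simulate_cohort(
        catalog, sd.CohortDesign(seed=12),
        sd.EffectSpec(size_effect_d=0.0, subtype_shift_slope=0.0), lifetimes)


@pytest.fixture(scope="session")
def profiles():
    return sd.simulate_spatial_profiles(sd.CohortDesign(seed=11), sd.EffectSpec())


@pytest.fixture(scope="session")
def small_catalog():
    return sd.make_region_catalog(sd.CatalogConfig(
        area_counts={"CTX": 4, "HPF": 2, "TH": 2}))


def sd_pair_design(seed, n_sd=10, n_ctrl=8):
    """Two-group design (control + sleep-deprived) for recovery sweeps."""
    return sd.CohortDesign(groups={"ZT6": n_ctrl, "ZT6SD": n_sd}, seed=seed)
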