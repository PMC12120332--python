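import warnings

import numpy as np
import pytest
from scipy.special import logit

import smoltrak as st


@pytest.fixture(scope="session")
def flat_rate_config():
    """Every river has the same true per-km rate (0.98) over 30 km, perfect
    detection, no contaminants: the cleanest oracle conditions."""
    return st.SimConfig(
        n_rivers=2, n_fish_per_river=60, years=(2021,),
        river_distance_km=30.0,
        landscape_effects={},
        bedrock_effects={k: float(logit(0.98)) for k in ("igneous", "metamorphic", "sedimentary")},
        individual_effects={}, year_effect_sd=0.0,
        detection_prob_first=1.0, detection_prob_last=1.0, detection_prob_marine=1.0,
        duplicate_rate=0.0, out_of_window_rate=0.0, unknown_tag_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(flat_rate_config):
    return st.simulate_study(flat_rate_config)


@pytest.fixture(scope="session")
def default_study():
    """Study-like defaults at reduced size, contaminants included."""
    cfg = st.SimConfig(n_rivers=5, n_fish_per_river=40, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.simulate_study(cfg)


@pytest.fixture(scope="session")
def migration_table():
    return st.load_migration_summaries()


@pytest.fixture(scope="session")
def cohort_table():
    return st.load_cohort_summaries()
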