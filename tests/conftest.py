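import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bombus_occupancy as bo

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def toy_tables():
    """Two sites (one burned), two visits each, hand-enterable covariates."""
    sites = pd.DataFrame(
        {
            "site_id": ["A", "B"],
            "burn_status": [1, 0],
            "canopy_openness": [0.6, 0.2],
        }
    )
    visits = pd.DataFrame(
        {
            "site_id": ["A", "A", "B", "B"],
            "visit_index": [1, 2, 1, 2],
            "floral_abundance": [10, 30, 0, 5],
            "floral_richness": [3, 5, 0, 1],
            "trap_hours": [300.0, 400.0, 350.0, 450.0],
            "julian_day": [160, 200, 165, 205],
        }
    )
    return sites, visits


@pytest.fixture
def toy_survey(toy_tables):
    sites, visits = toy_tables
    values = np.zeros((2, 2, 2), dtype=np.int8)
    values[0, 0, 0] = 1  # species x at site A, visit 1
    mask = np.ones((2, 2), dtype=bool)
    tensor = bo.DetectionTensor(values, mask, ["x", "y"])
    return bo.SurveyData(sites, visits, tensor)


@pytest.fixture
def small_sim():
    """A small simulated survey with known truth (10 species, 26 sites)."""
    config = bo.ScenarioConfig(seed=123)
    survey, z, truth = bo.simulate_survey(config)
    return survey, z, truth


def make_params(n_occ=5, n_species=2, n_det=6, **kw):
    """All-zero parameter state of the given shape, overridable by keyword."""
    base = dict(
        psi0=0.0,
        psi_coefs=np.zeros(n_occ),
        psi_species=np.zeros(n_species),
        sigma_species=1.0,
        p0=0.0,
        p_coefs=np.zeros(n_det),
    )
    base.update(kw)
    return bo.ParamState(**base)
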