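import warnings

import numpy as np
import pandas as pd
import pytest

from brainvar import synthetic_cohorts as sc
from brainvar.core_io import default_catalog

# stage-2 covariates are nested in cohort in most fixtures; the resulting
# single-level-covariate warnings are expected
warnings.filterwarnings("ignore", message="covariate .* has a single level")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def one_cohort_config(
    seed=0,
    n=2000,
    d=0.5,
    log_vr=0.3,
    vr_age_slope=0.0,
    rho_male=0.4,
    rho_female=0.4,
    female_fraction=0.5,
    noise="normal",
):
    """Single-cohort subcortical config with uniform effect sizes."""
    return sc.SimulationConfig(
        seed=seed,
        cohorts=[sc.CohortSpec("c0", n, 1.0, 90.0, female_fraction)],
        class_params={
            "subcortical_volume": sc.ClassParams(
                sex_mean_d=d,
                sex_log_vr=log_vr,
                vr_age_slope=vr_age_slope,
                rho_male=rho_male,
                rho_female=rho_female,
            )
        },
        noise=noise,
    )


@pytest.fixture
def small_table(catalog):
    """Tiny handwritten subject table with two subcortical measures."""
    from brainvar.core_io import SubjectTable

    data = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "cohort": ["a", "a", "a", "b", "b", "b"],
            "sex": ["M", "F", "M", "F", "M", "F"],
            "age": [10.0, 12.0, 30.0, 45.0, 60.0, 75.0],
            "field_strength": ["3T"] * 6,
            "software_version": ["v6.0"] * 6,
            "lh_thalamus_vol": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "rh_thalamus_vol": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
        }
    )
    return SubjectTable(data, catalog)
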