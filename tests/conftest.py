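import numpy as np
import pandas as pd
import pytest

from heartage.pipeline import prepare_scored_cohort
from heartage.simulate import default_config, generate_cohort


def make_profile_row(i=0, sex="male", **overrides):
    """One schema-complete cohort row with neutral defaults."""
    row = {
        "id": f"p{i:03d}",
        "sex": sex,
        "age": 45.0,
        "height_cm": 170.0,
        "weight_kg": 70.0,
        "waist_cm": 85.0,
        "sbp_mmHg": 125.0,
        "dbp_mmHg": 82.0,
        "total_chol_mgdl": 195.0,
        "hdl_mgdl": 52.0,
        "ldl_mgdl": np.nan,
        "tg_mgdl": 110.0,
        "glucose_mgdl": 95.0,
        "smoker": False,
        "bp_treated": False,
        "glucose_treated": False,
        "physically_active": True,
        "med_diet_score": 8,
        "alcohol_units_week": 0.0,
        "social_class": "II",
        "education": "high_school",
    }
    row.update(overrides)
    return row


@pytest.fixture
def small_cohort_df():
    return pd.DataFrame([make_profile_row(i) for i in range(3)])


@pytest.fixture(scope="session")
def scored_cohort():
    """A moderate synthetic cohort, scored and indexed, shared across tests.

    Uses a strong latent loading so the rare high-ALLY outcome is populated
    enough for ROC/regression shape checks at this size.
    """
    cfg = default_config(n_male=8000, n_female=8000, latent_effect=0.8)
    table = generate_cohort(cfg, seed=11)
    return prepare_scored_cohort(table)
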