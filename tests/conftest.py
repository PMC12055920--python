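import numpy as np
import pandas as pd
import pytest

from rptlab.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-participant synthetic cohort shared across integration tests."""
    return generate_cohort(GeneratorConfig(n_participants=60, seed=11))


@pytest.fixture()
def clean_ratings():
    """One complete participant: 6 categories x 8 pictures, varied ratings."""
    rng = np.random.default_rng(3)
    rows = []
    cats = ["sports", "disasters", "cute_animals", "aggressive_animals",
            "nature", "bathing_suits"]
    for c in cats:
        for j in range(8):
            rows.append({"participant_id": "p1", "cohort": "test", "category": c,
                         "picture_id": f"{c}_{j}",
                         "rating": int(rng.integers(-3, 4))})
    return pd.DataFrame(rows)
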