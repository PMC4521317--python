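import numpy as np
import pandas as pd
import pytest

from icuinfo import default_icu_specs, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One standard 5000-patient synthetic cohort, shared across tests."""
    specs, config = default_icu_specs(n_patients=5000, seed=20240901)
    return generate_cohort(config, specs), specs, config


@pytest.fixture()
def tiny_obs():
    """Hand-written observations: 3 patients, 2 days, 2 variables."""
    rows = []
    for pid, day, var, values in [
        ("a", 1, "x", [1.0, 2.0, 10.0]),
        ("a", 2, "x", [4.0]),
        ("a", 1, "y", [1.0, 2.0, 3.0, 10.0]),
        ("b", 1, "x", [3.0]),
        ("b", 2, "x", [5.0, 7.0]),
        ("c", 1, "x", [8.0]),
    ]:
        rows += [
            {"patient_id": pid, "day": day, "variable": var, "value": v} for v in values
        ]
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
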