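import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (4 classes x 10 units x 4 groups), seed 42."""
    from dgephys.synthetic import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def default_cohort_features(default_cohort):
    """Feature table extracted from the default cohort."""
    from dgephys.pipeline import dataset_from_cohort, features_table

    return features_table(dataset_from_cohort(default_cohort))


def make_train(isis_ms, duration_s=None):
    """Build a SpikeTrain from a list of ISIs in ms (first spike at 10 ms)."""
    from dgephys.features import SpikeTrain

    times = 0.010 + np.concatenate([[0.0], np.cumsum(np.asarray(isis_ms, dtype=float))]) / 1000.0
    if duration_s is None:
        duration_s = float(times[-1] + 1.0)
    return SpikeTrain(times_s=times, duration_s=duration_s)


@pytest.fixture
def behavior_fixture_table():
    """Hand-computed behavioral fixture covering boundaries."""
    return pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "a3", "a4", "a5"],
            "group": ["Sus", "Res", "ND", "Sus", "Res"],
            "defeated": [True, True, False, True, True],
            "phase1_s": [50.0, 60.0, 40.0, 0.0, 80.0],
            "phase2_s": [25.0, 60.0, 80.0, 30.0, 120.0],
            "sucrose_ml": [3.0, 2.0, 4.0, 1.0, 0.0],
            "water_ml": [1.0, 2.0, 0.0, 3.0, 0.0],
        }
    )
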