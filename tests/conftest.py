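import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from copestyle.data_model import BEHAVIOR_TRAITS, ObservationTable, TraitSpec
from copestyle.synthetic_data import SimulationDesign, simulate_study

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def plain_trait():
    """Raw-scale trait with a mean-only fixed effect."""
    return TraitSpec(name="y", transform="none", scale_to_sd=False,
                     fixed_effects=("mean",))


@pytest.fixture
def balanced_table():
    """Three individuals x two trials with a closed-form REML solution:
    group means 2/3/7, MSB = 14, MSW = 2 -> V_I = 6, V_R = 2."""
    df = pd.DataFrame({
        "individual_id": ["A", "A", "B", "B", "C", "C"],
        "trial_number": [1, 2, 1, 2, 1, 2],
        "y": [1.0, 3.0, 2.0, 4.0, 6.0, 8.0],
    })
    return ObservationTable(df)


@pytest.fixture(scope="session")
def behavior_table():
    """One simulated 20 x 5 behavioral dataset under the default truth."""
    return simulate_study(SimulationDesign(traits=BEHAVIOR_TRAITS, seed=42))


@pytest.fixture(scope="session")
def full_table():
    """Behavior + emergence + hormones, default design."""
    return simulate_study(SimulationDesign(seed=11))
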