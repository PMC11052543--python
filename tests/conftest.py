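import numpy as np
import pandas as pd
import pytest

from amha import (AMHaParameters, CutoffPolicy, ScenarioConfig, SocialNetwork,
                  StatePanel, generate_scenario)
from amha.calibration import SocialRate


def make_panel(rows):
    """Panel from (person_id, wave, year, sex, age, drinks) tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "wave", "midpoint_year",
                                     "sex", "age", "drinks_per_week"])
    return StatePanel(df)


@pytest.fixture
def policy():
    return CutoffPolicy()


@pytest.fixture
def path_panel():
    """3-node path a-b-c over two waves; b moves M -> H."""
    return make_panel([
        ("a", 0, 2000, "female", 40, 0.0),
        ("b", 0, 2000, "male", 40, 5.0),
        ("c", 0, 2000, "male", 40, 20.0),
        ("a", 1, 2004, "female", 44, 0.0),
        ("b", 1, 2004, "male", 44, 20.0),
        ("c", 1, 2004, "male", 44, 20.0),
    ]).classify()


@pytest.fixture
def path_network():
    return SocialNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def simple_params():
    """Small parameter set with a couple of social terms, per 4 years."""
    alpha = {("A", "M"): 0.10, ("A", "H"): 0.01, ("M", "A"): 0.08,
             ("M", "H"): 0.06, ("H", "A"): 0.02, ("H", "M"): 0.20}
    beta = {("M", "H"): {"H": SocialRate(0.04)},
            ("M", "A"): {"A": SocialRate(0.02)},
            ("H", "A"): {"A": SocialRate(0.01)}}
    return AMHaParameters(alpha=alpha, beta=beta, reference_period_years=4.0)


@pytest.fixture(scope="session")
def small_scenario():
    """Medium synthetic scenario shared by read-only tests."""
    return generate_scenario(ScenarioConfig(n_persons=1200, n_waves=5, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
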