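import numpy as np
import pandas as pd
import pytest

from distcue import design as dz
from distcue import cohort as ch


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pain_design_with_cues():
    """One full expectation-task design (pain half) with generated cues."""
    rng = np.random.default_rng(777)
    des = dz.generate_cues_for_design(dz.enumerate_design("expectation", rng), rng)
    return des[des["modality"] == "pain"].reset_index(drop=True)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 4-participant synthetic cohort (M2 observers), shared across tests."""
    cfg = ch.CohortConfig(n_participants=4, seed=2024)
    return ch.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def symmetric_cue_values():
    """A pairwise-symmetric 10-value cue (paired deviations about the mean)."""
    center = 50.0
    devs = np.array([2.0, 5.0, 9.0, 14.0, 20.0])
    return np.concatenate([center - devs, center + devs])


def make_perception_trials(n=24, seed=0, rating=None):
    """Minimal ordered cued-perception trial table for direct model tests."""
    rng = np.random.default_rng(seed)
    mods = np.repeat(["pain", "vision"], n // 2)
    df = pd.DataFrame({
        "block": np.repeat(np.arange(1, n // 12 + 2), 12)[:n],
        "mini_block": 1,
        "trial": np.arange(1, n + 1),
        "modality": mods[:n],
        "intensity_level": rng.choice([2, 4], size=n),
        "expectation": rng.uniform(20, 80, size=n),
    })
    if rating is not None:
        df["perception_rating"] = rating
    return df
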