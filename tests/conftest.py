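import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from sexpanel.sim import BatchSpec, PlantedTruth, SimConfig, simulate_cohorts


@pytest.fixture(scope="session")
def two_group_sim():
    """Single-batch male tumor vs non-tumor cohort with strong planted signal."""
    truth = PlantedTruth(
        male_specific={f"g{i:05d}": (3.0 if i % 2 == 0 else -3.0) for i in range(20)}
    )
    cfg = SimConfig(
        n_genes=400,
        batch_specs=(BatchSpec("b1", {("male", "tumor"): 40, ("male", "non-tumor"): 40}),),
        planted=truth,
        batch_effect_sigma=0.0,
        seed=11,
    )
    return simulate_cohorts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {"s1": [10, 20, 5], "s2": [12, 18, 6], "s3": [8, 25, 4]},
        index=["g1", "g2", "g3"],
    )
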